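"""Per-gene differential activity, joint DE/tDGE classification, and
contingency tests.

Differential expression on the activity ratio is rank-based: a
two-sided Mann-Whitney test per gene with a log2 ratio-of-means effect
size (pseudocount = half the minimum positive group mean), BH-FDR
across tested genes, and significance tiers at p < 0.05 (p_sig) and
q < 0.05 (q_sig). The ratio is not a count, so a negative-binomial
count model is not applicable here; a count-based DE on the MT layer
can be plugged in externally and joined on gene id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMetadata
from .quantify import ActivityMatrix
from ._stats import rank_compare


def differential_expression(act: ActivityMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Rank-based per-gene HC vs PD differential activity.

    Genes with zero activity in every sample are excluded before
    testing. Adds ``group_label`` (PD iff log2fc > 0, HC iff < 0) and
    ``significance_tier`` in {q_sig, p_sig, ns}.
    """
    values = act.values
    nonzero = (values.fillna(0.0) != 0).any(axis=1)
    tested = values.loc[nonzero]
    out = rank_compare(tested, meta.table)
    out = out.rename(columns={"log2fc": "log2fc_expression"})
    out["group_label"] = np.where(out["log2fc_expression"] > 0, "PD",
                                  np.where(out["log2fc_expression"] < 0, "HC", "none"))
    out["significance_tier"] = "ns"
    out.loc[out["p"] < 0.05, "significance_tier"] = "p_sig"
    out.loc[out["q"] < 0.05, "significance_tier"] = "q_sig"
    return out


def joint_classification(de: pd.DataFrame, log2fc_tdge: pd.Series,
                         hub_genes=()) -> dict:
    """Cross-classify genes by expression sign, tDGE sign, hub status, tier.

    Genes whose tDGE log2FC is missing (or whose expression log2FC is
    exactly zero) are "unclassifiable" and reported separately; counted
    bins plus unclassifiable genes partition the DE gene set exactly.
    """
    hub = set(hub_genes)
    tab = de.copy()
    tab["log2fc_tdge"] = log2fc_tdge.reindex(tab.index)
    tab["hub_flag"] = [g in hub for g in tab.index]
    classifiable = (
        tab["log2fc_tdge"].notna()
        & (tab["log2fc_expression"] != 0)
        & (tab["log2fc_tdge"] != 0)
    )
    tab["tdge_direction"] = np.where(tab["log2fc_tdge"] > 0, "up", "down")
    binned = tab[classifiable]
    counts = (
        binned.groupby(["group_label", "tdge_direction", "hub_flag",
                        "significance_tier"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return {
        "table": tab,
        "counts": counts,
        "n_unclassifiable": int((~classifiable).sum()),
    }


def proportion_tests(table) -> dict:
    """Fisher exact and chi-square p-values for a 2x2 count table.

    Fisher is the two-sided hypergeometric-sum test; chi-square uses no
    continuity correction by default and is missing-coded when a margin
    is zero (expected counts undefined).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("proportion tests need a 2x2 table")
    if not np.allclose(t, np.round(t)) or (t < 0).any():
        raise ValueError("table must hold non-negative integers")
    odds, fisher_p = stats.fisher_exact(t, alternative="two-sided")
    margins_ok = t.sum(axis=0).min() > 0 and t.sum(axis=1).min() > 0
    if margins_ok:
        chi2, chi_p, _, _ = stats.chi2_contingency(t, correction=False)
    else:
        chi2, chi_p = np.nan, np.nan
    return {
        "odds_ratio": float(odds),
        "fisher_p": float(fisher_p),
        "chi2": float(chi2) if np.isfinite(chi2) else np.nan,
        "chi2_p": float(chi_p) if np.isfinite(chi_p) else np.nan,
    }
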