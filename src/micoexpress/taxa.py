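"""Taxon-resolved activity: tensor construction, differential MTA,
ordination with factor fitting.

The taxon-gene tensor allocates each KO's activity ratio to the taxa
expressing it in proportion to their MT TPM share, i.e. the value for
(taxon t, KO k, sample s) is MT_TPM(t,k,s) / MG_TPM(k,s). Summing the
tensor over taxa therefore reproduces the KO-level activity matrix
exactly, while the within-KO taxon shares — the only thing the
diversity statistics consume — equal the MT TPM shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import quantify
from .io import FeatureAnnotation, GeneFeatureTable, SampleMetadata
from ._stats import group_split, rank_compare

logger = logging.getLogger(__name__)


@dataclass
class TaxonGeneTensor:
    """Normalized expression per (taxon, KO, sample), long format.

    ``long`` has columns taxon, ko, sample, value (non-negative).
    ``rank`` is "genus" or "species". Rows for the pooled
    "unclassified" bin are kept but excluded from diversity statistics
    by default.
    """

    long: pd.DataFrame
    rank: str
    provenance: str = "mt_tpm_share_over_ko_mg_tpm"

    def to_matrix(self) -> pd.DataFrame:
        """(taxon, ko) x sample wide matrix (missing -> 0)."""
        return self.long.pivot_table(
            index=["taxon", "ko"], columns="sample", values="value", fill_value=0.0
        )

    def marginal_ko(self) -> pd.DataFrame:
        """Sum over taxa -> KO x sample activity matrix."""
        return self.long.groupby(["ko", "sample"])["value"].sum().unstack("sample", fill_value=0.0)

    def taxa(self, include_unclassified: bool = False) -> list[str]:
        labels = self.long["taxon"].unique().tolist()
        if not include_unclassified:
            labels = [t for t in labels if t != "unclassified"]
        return sorted(labels)


def build_tensor(mg: GeneFeatureTable, mt: GeneFeatureTable,
                 ann: FeatureAnnotation, rank: str = "species") -> TaxonGeneTensor:
    """Build the (taxon, KO, sample) activity tensor.

    Feature counts are turned into TPM per layer, summed to
    (taxon-at-rank, KO) on the MT side and to KO on the MG side, and
    divided. Taxa without a lineage at `rank` pool into "unclassified".
    """
    taxon = ann.taxon_at(rank)
    if (taxon.reindex(mt.features) == "unclassified").all():
        raise ValueError(f"no feature has a lineage at rank {rank!r}")
    mt_tpm = quantify.tpm(mt)
    mg_tpm = quantify.tpm(mg)
    mt_tk = quantify.aggregate_tpm(mt_tpm, ann, by=(rank, "ko"))
    mg_ko = quantify.aggregate_tpm(mg_tpm, ann, by="ko")

    ko_of_row = mt_tk.index.get_level_values(1)
    mg_aligned = mg_ko.reindex(ko_of_row)
    mg_arr = mg_aligned.to_numpy(dtype=float)
    mt_arr = mt_tk.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(mg_arr > 0, mt_arr / np.where(mg_arr > 0, mg_arr, 1.0), np.nan)
    vals[(mg_arr == 0) & (mt_arr == 0)] = 0.0
    # MT>0 with zero MG for the whole KO: undefined activity, dropped
    n_undef = int(np.isnan(vals).sum())
    if n_undef:
        logger.info("%d tensor entries undefined (MT>0, MG=0), dropped", n_undef)

    wide = pd.DataFrame(vals, index=mt_tk.index, columns=mt_tk.columns)
    long = wide.reset_index()
    long.columns = ["taxon", "ko", *wide.columns]
    long = long.melt(id_vars=["taxon", "ko"], var_name="sample", value_name="value")
    long = long.dropna(subset=["value"])
    long = long[long["value"] != 0.0].reset_index(drop=True)
    return TaxonGeneTensor(long, rank)


def taxon_activity(mg: GeneFeatureTable, mt: GeneFeatureTable,
                   ann: FeatureAnnotation, rank: str = "genus") -> pd.DataFrame:
    """Taxon-level MTA: MT TPM / MG TPM aggregated at `rank` (taxa x samples).

    The input to differential MTA at genus or species level; 0/0 -> 0,
    MT>0/MG=0 -> NaN (missing-coded).
    """
    mt_t = quantify.aggregate_tpm(quantify.tpm(mt), ann, by=rank)
    mg_t = quantify.aggregate_tpm(quantify.tpm(mg), ann, by=rank)
    mg_t = mg_t.reindex(mt_t.index).fillna(0.0)
    mt_arr = mt_t.to_numpy(dtype=float)
    mg_arr = mg_t.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(mg_arr > 0, mt_arr / np.where(mg_arr > 0, mg_arr, 1.0), np.nan)
    vals[(mg_arr == 0) & (mt_arr == 0)] = 0.0
    return pd.DataFrame(vals, index=mt_t.index, columns=mt_t.columns)


def differential_mta(values: pd.DataFrame, meta: SampleMetadata,
                     min_prevalence: float = 0.5) -> pd.DataFrame:
    """Two-sided Mann-Whitney HC vs PD per unit with BH-FDR.

    Units (taxa, or taxon x KO rows) below `min_prevalence` detection
    are excluded before testing, so they never enter the FDR family.
    """
    detected = (values > 0) & values.notna()
    import math

    n_needed = math.ceil(min_prevalence * values.shape[1])
    tested = values.loc[detected.sum(axis=1) >= n_needed]
    if tested.empty:
        raise ValueError("no unit passes the prevalence filter")
    return rank_compare(tested, meta.table)


def ordinate_and_fit(clr_values: pd.DataFrame, meta: SampleMetadata,
                     n_perm: int = 999, n_axes: int = 2,
                     seed: int = 0) -> dict:
    """PCA of CLR-transformed activity + environmental factor fit.

    Scores come from the SVD of the sample x feature matrix after
    feature centering. The group factor's goodness of fit is
    r2 = 1 - SS_within / SS_total on the first `n_axes` score columns,
    with a permutation p-value from `n_perm` label shuffles:
    p = (1 + #{r2_perm >= r2_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    groups = meta.table.loc[clr_values.columns, "group"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("factor fitting needs two groups")
    x = clr_values.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s  # samples x components
    n_axes = min(n_axes, scores.shape[1])
    sub = scores[:, :n_axes]

    r2_obs = _factor_r2(sub, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _factor_r2(sub, perm) >= r2_obs:
            count += 1
    pval = (1 + count) / (1 + n_perm)
    explained = (s**2) / np.sum(s**2) if np.sum(s**2) > 0 else s * 0
    return {
        "scores": pd.DataFrame(
            scores[:, : max(n_axes, 2)],
            index=clr_values.columns,
            columns=[f"PC{i + 1}" for i in range(max(n_axes, 2))],
        ),
        "explained_variance_ratio": explained[: max(n_axes, 2)],
        "r2": r2_obs,
        "p": pval,
        "n_perm": n_perm,
    }


def _factor_r2(scores: np.ndarray, groups: np.ndarray) -> float:
    grand = scores.mean(axis=0)
    ss_total = np.sum((scores - grand) ** 2)
    if ss_total == 0:
        return 0.0
    ss_within = 0.0
    for g in np.unique(groups):
        sub = scores[groups == g]
        ss_within += np.sum((sub - sub.mean(axis=0)) ** 2)
    return float(1.0 - ss_within / ss_total)
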