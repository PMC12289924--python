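"""Cross-feeding correlation analysis between gene blocks.

Correlates every gene of one process block (e.g. bacterial
microcompartment / eut / pdu genes) with every gene of another (e.g.
flagellar assembly) across samples using Spearman correlation, counts
significant positive correlations before and after BH-FDR, supports
restriction to a configured list of genera, and sums process-level
expression per genus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .taxa import TaxonGeneTensor
from ._stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ProcessGeneLists:
    """Curated KO lists per biological process + selected genera."""

    processes: dict[str, list[str]]  # e.g. {"BMC": [...], "FA": [...]}
    selected_genera: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, members in self.processes.items():
            if not members:
                raise ValueError(f"process {name!r} has an empty gene list")


def block_correlations(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """All-pairs Spearman correlations between two gene blocks.

    `a` and `b` are genes x samples with identical sample columns.
    Returns the pair table (gene_a, gene_b, rho, p, q) and the counts
    of positive correlations significant before (p < 0.05) and after
    (q < 0.05) BH correction. Pairs involving a constant vector are
    missing-coded and excluded from the FDR family.
    """
    shared = [s for s in a.columns if s in set(b.columns)]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples")
    xa = a[shared].to_numpy(dtype=float)
    xb = b[shared].to_numpy(dtype=float)
    n = len(shared)
    ra = _rank_rows(xa)
    rb = _rank_rows(xb)
    const_a = np.all(xa == xa[:, :1], axis=1)
    const_b = np.all(xb == xb[:, :1], axis=1)
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    rb_c = rb - rb.mean(axis=1, keepdims=True)
    num = ra_c @ rb_c.T
    denom = np.sqrt(
        np.outer((ra_c**2).sum(axis=1), (rb_c**2).sum(axis=1))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / denom, np.nan)
    rho[const_a, :] = np.nan
    rho[:, const_b] = np.nan
    np.clip(rho, -1.0, 1.0, out=rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0

    pairs = pd.DataFrame(
        {
            "gene_a": np.repeat(list(a.index), len(b.index)),
            "gene_b": np.tile(list(b.index), len(a.index)),
            "rho": rho.ravel(),
            "p": p.ravel(),
        }
    )
    pairs["q"] = bh_adjust(pairs["p"])
    pos = pairs["rho"] > 0
    counts = {
        "n_pairs": len(pairs),
        "n_positive_p05": int((pos & (pairs["p"] < 0.05)).sum()),
        "n_positive_q05": int((pos & (pairs["q"] < 0.05)).sum()),
    }
    return {"pairs": pairs, "counts": counts}


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def filter_by_taxa(tensor: TaxonGeneTensor, genera) -> pd.DataFrame:
    """Expression restricted to listed genera, summed per (KO, sample).

    Genera absent from the tensor are dropped with a warning; an empty
    selection is an error.
    """
    genera = list(genera)
    if not genera:
        raise ValueError("empty genus list")
    present = set(tensor.long["taxon"].unique())
    keep = [g for g in genera if g in present]
    for g in genera:
        if g not in keep:
            logger.warning("genus %r absent from tensor: dropped", g)
    if not keep:
        raise ValueError("no listed genus present in the tensor")
    sub = tensor.long[tensor.long["taxon"].isin(keep)]
    return sub.groupby(["ko", "sample"])["value"].sum().unstack("sample",
                                                                fill_value=0.0)


def process_blocks(expr: pd.DataFrame, lists: ProcessGeneLists) -> dict[str, pd.DataFrame]:
    """Slice a KO x sample matrix into the configured process blocks."""
    out = {}
    for name, members in lists.processes.items():
        rows = [k for k in members if k in expr.index]
        out[name] = expr.loc[rows]
    return out


def process_sums(tensor: TaxonGeneTensor, lists: ProcessGeneLists) -> pd.DataFrame:
    """Sum of normalized expression per (genus, process, sample)."""
    rows = []
    long = tensor.long
    genera = sorted(t for t in long["taxon"].unique() if t != "unclassified")
    samples = sorted(long["sample"].unique())
    for name, members in lists.processes.items():
        member_set = set(members)
        sub = long[long["ko"].isin(member_set)]
        summed = sub.groupby(["taxon", "sample"])["value"].sum()
        for genus in genera:
            for s in samples:
                rows.append({
                    "genus": genus,
                    "process": name,
                    "sample": s,
                    "expression_sum": float(summed.get((genus, s), 0.0)),
                })
    return pd.DataFrame(rows)
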