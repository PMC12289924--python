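"""Preranked gene-set enrichment of network modules.

Genes are ranked per module by module membership (kME: correlation of
the gene's expression profile with the module eigengene). The
enrichment score is the classic weighted Kolmogorov-Smirnov running
sum: walking down the ranking, hits increment by |stat|^w normalized
over hit stats, misses decrement by 1/(N - N_hit); ES is the running
sum's maximum deviation from zero. The null is gene-label permutation
(random sets of the same size); p-values are sign-stratified with the
standard permutation floor, and NES divides ES by the mean |ES| of
same-sign permutations. BH-FDR runs across the whole
(module x pathway) family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .network import UNASSIGNED, ModulePartition
from ._stats import bh_adjust

logger = logging.getLogger(__name__)


def rank_genes(expr: pd.DataFrame, partition: ModulePartition,
               module: str) -> pd.Series:
    """All network genes ranked by kME to `module`, descending.

    Ties are broken by gene id so the ranking is deterministic.
    """
    if module not in partition.eigengenes.columns:
        raise KeyError(f"unknown module {module!r}")
    e = partition.eigengenes[module].to_numpy()
    arr = expr.to_numpy(dtype=float)
    e_c = e - e.mean()
    a_c = arr - arr.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum(axis=1) * (e_c**2).sum())
    with np.errstate(invalid="ignore"):
        kme = np.where(denom > 0, a_c @ e_c / denom, 0.0)
    s = pd.Series(kme, index=expr.index, name="kME")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def enrichment_score(ranked_stats: np.ndarray, hit_mask: np.ndarray,
                     weight: float = 1.0) -> float:
    """Weighted KS enrichment score for a ranked list and hit indicator."""
    stats_abs = np.abs(ranked_stats) ** weight
    n = len(ranked_stats)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0
    hit_sum = stats_abs[hit_mask].sum()
    if hit_sum == 0:
        steps = np.where(hit_mask, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(hit_mask, stats_abs / hit_sum, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _es_null(ranked_stats: np.ndarray, set_size: int, n_perm: int,
             weight: float, rng: np.random.Generator) -> np.ndarray:
    n = len(ranked_stats)
    out = np.empty(n_perm)
    for b in range(n_perm):
        hit = np.zeros(n, dtype=bool)
        hit[rng.choice(n, size=set_size, replace=False)] = True
        out[b] = enrichment_score(ranked_stats, hit, weight)
    return out


def gsea_preranked(ranking: pd.Series, members, n_perm: int = 999,
                   weight: float = 1.0, min_size: int = 5,
                   seed: int = 0) -> dict | None:
    """Preranked GSEA of one gene set against one ranking.

    Returns dict(es, nes, p, size) or None when the overlap with the
    ranking is below `min_size`. The permutation null shuffles gene
    labels (random same-size sets); p is computed among same-sign
    permuted scores so that null p-values are uniform, with floor
    1/(n_perm + 1).
    """
    members = set(members)
    genes = list(ranking.index)
    hit = np.array([g in members for g in genes])
    size = int(hit.sum())
    if size < min_size:
        logger.info("gene set overlap %d < %d: skipped", size, min_size)
        return None
    stats_arr = ranking.to_numpy(dtype=float)
    es = enrichment_score(stats_arr, hit, weight)
    rng = np.random.default_rng(seed)
    null = _es_null(stats_arr, size, n_perm, weight, rng)
    same_sign = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, dtype=bool)
    n_same = int(same_sign.sum())
    n_ge = int((np.abs(null[same_sign]) >= abs(es)).sum())
    p = (1 + n_ge) / (1 + n_same) if n_same else 1.0
    mean_same = np.abs(null[same_sign]).mean() if n_same else np.nan
    nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
    return {"es": es, "nes": float(nes), "p": float(p), "size": size,
            "n_perm": n_perm}


def module_enrichment(expr: pd.DataFrame, partition: ModulePartition,
                      sets: GeneSetCollection, n_perm: int = 999,
                      weight: float = 1.0, min_size: int = 5,
                      seed: int = 0) -> pd.DataFrame:
    """GSEA of every pathway against every module's kME ranking.

    BH q runs across all retained (module, pathway) pairs.
    """
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(
        len(partition.eigengenes.columns) * max(len(sets), 1)
    )
    i = 0
    for module in partition.eigengenes.columns:
        ranking = rank_genes(expr, partition, module)
        for name, members in sets.sets.items():
            res = gsea_preranked(ranking, members, n_perm=n_perm, weight=weight,
                                 min_size=min_size,
                                 seed=int(seeds[i].generate_state(1)[0] % (2**31)))
            i += 1
            if res is None:
                continue
            rows.append({"module": module, "pathway": name, **res})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"])
    return out


def unannotated_accounting(partition: ModulePartition,
                           sets: GeneSetCollection) -> dict:
    """Per-module count/fraction of genes in no pathway set."""
    annotated = sets.annotated_genes() if len(sets) else frozenset()
    rows = []
    for m in sorted(partition.labels.unique()):
        if m == UNASSIGNED:
            continue
        genes = partition.genes_in(m)
        n_un = sum(1 for g in genes if g not in annotated)
        rows.append({"module": m, "size": len(genes), "unannotated": n_un,
                     "fraction_unannotated": n_un / len(genes)})
    table = pd.DataFrame(rows).set_index("module")
    frac = table["fraction_unannotated"]
    return {
        "table": table,
        "mean_fraction": float(frac.mean()) if len(frac) else np.nan,
        "min_fraction": float(frac.min()) if len(frac) else np.nan,
        "max_fraction": float(frac.max()) if len(frac) else np.nan,
    }
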