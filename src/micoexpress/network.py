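"""Signed weighted co-expression network and module detection.

The network follows the weighted co-expression (WGCNA) construction:
signed adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^beta with Pearson
correlation across samples, topological overlap similarity, soft power
chosen as the smallest scanned power whose scale-free fit index reaches
a cutoff (0.9 by default), average-linkage clustering of 1 - TOM with
a dynamic tree cut, and iterative merging of modules whose eigengenes
are closer than a dissimilarity threshold. Module eigengenes are the
first singular vector of the standardized module expression submatrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .io import SampleMetadata
from ._stats import bh_adjust, pearson_pvalue

logger = logging.getLogger(__name__)

UNASSIGNED = "M0"


@dataclass
class CoexpressionNetwork:
    """Signed adjacency and TOM over the filtered KO genes."""

    genes: list[str]
    adjacency: np.ndarray  # symmetric, entries in [0,1], unit diagonal
    tom: np.ndarray  # symmetric, entries in [0,1], unit diagonal
    beta: int
    sft_table: pd.DataFrame

    def connectivity(self) -> pd.Series:
        """Whole-network connectivity k_i = sum_{j != i} a_ij (kTotal)."""
        k = self.adjacency.sum(axis=1) - np.diag(self.adjacency)
        return pd.Series(k, index=self.genes, name="kTotal")


@dataclass
class ModulePartition:
    """Gene -> module labels, eigengenes and trait statistics."""

    labels: pd.Series  # gene -> "M1".. / "M0"
    eigengenes: pd.DataFrame  # samples x modules
    merge_log: list = field(default_factory=list)
    trait_stats: pd.DataFrame | None = None

    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()


def signed_adjacency(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """a_ij = ((1 + cor(x_i, x_j)) / 2)^beta over gene rows of `expr`."""
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0])[:5]
        raise ValueError(f"zero-variance genes in network input: {bad}")
    cor = np.corrcoef(arr)
    np.clip(cor, -1.0, 1.0, out=cor)
    return ((1.0 + cor) / 2.0) ** beta


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j; TOM_ii = 1.
    """
    a = np.array(adjacency, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Connectivities are split into `n_bins` equal-width bins; the
    regression log10(frequency) ~ log10(mean k) over non-empty bins
    gives R^2, reported with the sign convention that a positive index
    requires a negative slope (signed fit index = -sign(slope) * R^2).
    Returns (fit_index, slope).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        n_bins = max(2, k.size // 2)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-12
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    mean_k = np.array([k[idx == b].mean() if (idx == b).any() else np.nan
                       for b in range(n_bins)])
    freq = np.array([(idx == b).sum() for b in range(n_bins)], dtype=float)
    ok = np.isfinite(mean_k) & (freq > 0) & (mean_k > 0)
    if ok.sum() < 3:
        return np.nan, np.nan
    x = np.log10(mean_k[ok])
    y = np.log10(freq[ok] / freq[ok].sum())
    if np.allclose(x, x[0]):
        return np.nan, np.nan
    res = stats.linregress(x, y)
    fit = -np.sign(res.slope) * res.rvalue**2
    return float(fit), float(res.slope)


def soft_threshold_scan(expr: pd.DataFrame, powers=None,
                        r2_cut: float = 0.9) -> tuple[int, pd.DataFrame]:
    """Scan soft powers; pick the smallest with scale-free fit >= r2_cut.

    If no scanned power reaches the cutoff, the power at the maximum
    fit is returned with a warning (mirroring the selection rule used
    for the cohort network, where 17 was the lowest power reaching
    fit 0.918 >= 0.9).
    """
    if powers is None:
        powers = list(range(1, 21))
    powers = sorted(int(p) for p in powers)
    if not powers:
        raise ValueError("empty power list")
    if expr.shape[0] < 20 or expr.shape[1] < 10:
        raise ValueError("soft threshold scan needs >= 20 genes and >= 10 samples")
    arr = expr.to_numpy(dtype=float)
    if (arr.std(axis=1) == 0).any():
        raise ValueError("constant genes in expression matrix")
    cor = np.corrcoef(arr)
    np.clip(cor, -1.0, 1.0, out=cor)
    base = (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    for p in powers:
        a = base**p
        k = a.sum(axis=1)
        fit, slope = scale_free_fit(k)
        rows.append({"power": p, "fit": fit, "slope": slope,
                     "mean_k": float(k.mean()), "median_k": float(np.median(k)),
                     "max_k": float(k.max())})
    sft = pd.DataFrame(rows)
    beta = select_power(sft, r2_cut)
    return beta, sft


def select_power(sft: pd.DataFrame, r2_cut: float) -> int:
    """Smallest power with fit >= r2_cut; else argmax fit with a warning."""
    ok = sft[sft["fit"] >= r2_cut]
    if len(ok):
        return int(ok["power"].iloc[0])
    best = sft.loc[sft["fit"].fillna(-np.inf).idxmax(), "power"]
    warnings.warn(
        f"no scanned power reaches fit {r2_cut}; using power {int(best)} "
        f"at maximum fit {sft['fit'].max():.3f}",
        stacklevel=2,
    )
    return int(best)


def build_network(expr: pd.DataFrame, power: int | None = None,
                  powers=None, r2_cut: float = 0.9) -> CoexpressionNetwork:
    """Convenience constructor: scan (or accept) the power, build A and TOM."""
    if power is None:
        power, sft = soft_threshold_scan(expr, powers=powers, r2_cut=r2_cut)
    else:
        _, sft = soft_threshold_scan(expr, powers=powers or [power], r2_cut=0.0)
        power = int(power)
    adj = signed_adjacency(expr, power)
    tom = topological_overlap(adj)
    return CoexpressionNetwork(list(expr.index), adj, tom, power, sft)


def module_eigengene(expr: pd.DataFrame, genes) -> tuple[pd.Series, float]:
    """First singular vector of the standardized module submatrix.

    Returns (eigengene over samples, explained variance share). The
    sign is oriented so the mean correlation with member gene profiles
    is positive; the vector has unit L2 norm.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("eigengene needs >= 2 genes")
    sub = expr.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).all():
        raise ValueError("degenerate module: all genes constant")
    keep = sd > 0
    sub = sub[keep]
    sub = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=0, keepdims=True)
    u, s, vt = np.linalg.svd(sub.T, full_matrices=False)  # samples x genes
    e = u[:, 0]
    explained = float(s[0] ** 2 / np.sum(s**2))
    cors = np.array([np.corrcoef(e, g)[0, 1] for g in sub])
    if cors.mean() < 0:
        e = -e
    return pd.Series(e, index=expr.columns, name="eigengene"), explained


def _collect_branches(node, min_size: int, min_gap: float, parent_height: float):
    """Recursive branch collection for the tree-variant dynamic cut.

    A branch becomes a module candidate when it is large enough and
    *distinct*: it joins the rest of the dendrogram at a height at
    least `min_gap` above its own top merge. Distinct sub-branches take
    precedence over their enclosing branch, so a tight module plus a
    few stragglers resolves to the tight core. Genes on no distinct
    branch stay unassigned.
    """
    if node.is_leaf() or node.get_count() < min_size:
        return []
    sub = (_collect_branches(node.left, min_size, min_gap, node.dist)
           + _collect_branches(node.right, min_size, min_gap, node.dist))
    if sub:
        return sub
    if parent_height - node.dist >= min_gap:
        return [node.pre_order(lambda leaf: leaf.id)]
    return []


def cut_modules(net: CoexpressionNetwork, expr: pd.DataFrame,
                min_module_size: int = 20, medissthres: float = 0.18,
                min_branch_gap: float = 0.02) -> ModulePartition:
    """Average-linkage dendrogram on 1 - TOM, dynamic cut, eigengene merge.

    A branch is a module when it holds at least `min_module_size`
    genes and joins the rest of the tree at least `min_branch_gap`
    (TOM dissimilarity units) above its own top merge; everything else
    is unassigned (M0). Modules whose eigengene dissimilarity 1 - cor
    falls below `medissthres` are merged iteratively (closest pair
    first). Final labels are ordered by size, M1 largest.
    """
    genes = list(net.genes)
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size: all unassigned",
                      stacklevel=2)
        labels = pd.Series(UNASSIGNED, index=genes)
        return ModulePartition(labels, pd.DataFrame(index=expr.columns))
    diss = 1.0 - net.tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = linkage(squareform(diss, checks=False), method="average")
    root = to_tree(z)
    # the root's "parent" sits at dissimilarity 1 (no topological
    # overlap), so a globally tight tree can itself form one module
    sentinel = max(1.0, float(z[:, 2].max()))
    branches = _collect_branches(root, min_module_size, min_branch_gap,
                                 sentinel)

    labels = pd.Series(UNASSIGNED, index=genes)
    next_id = 1
    for branch in branches:
        if len(branch) >= min_module_size:
            labels.iloc[branch] = f"tmp{next_id}"
            next_id += 1
    if next_id == 1:
        warnings.warn("no branch reaches min_module_size: all unassigned",
                      stacklevel=2)
        return ModulePartition(labels, pd.DataFrame(index=expr.columns))

    # --- iterative eigengene merging
    merge_log: list[dict] = []
    current = sorted(labels[labels != UNASSIGNED].unique())
    eig = {m: module_eigengene(expr, labels.index[labels == m])[0] for m in current}
    while len(current) > 1:
        names = list(current)
        mat = np.array([eig[m].to_numpy() for m in names])
        cor = np.corrcoef(mat)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        dissim = 1.0 - cor[i, j]
        if dissim >= medissthres:
            break
        a, b = names[i], names[j]
        labels[labels == b] = a
        merge_log.append({"kept": a, "merged": b, "dissimilarity": float(dissim)})
        current = [m for m in current if m != b]
        eig[a] = module_eigengene(expr, labels.index[labels == a])[0]
        del eig[b]

    # --- relabel by size, largest first; ties by current name
    sizes = labels[labels != UNASSIGNED].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    rename = {old: f"M{i + 1}" for i, old in enumerate(order)}
    labels = labels.map(lambda m: rename.get(m, UNASSIGNED))
    eigengenes = pd.DataFrame(
        {rename[m]: eig[m] for m in order}, index=expr.columns
    )
    for entry in merge_log:
        entry["kept"] = rename.get(entry["kept"], entry["kept"])
    return ModulePartition(labels, eigengenes, merge_log)


def module_trait(partition: ModulePartition, meta: SampleMetadata,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each module eigengene with the HC=0 / PD=1 indicator.

    Pearson r with a Student-t p-value (n - 2 df), BH q across modules,
    and a trait class: PD-associated for r > 0 with p <= alpha,
    HC-associated for r < 0 with p <= alpha, else unassociated.
    """
    samples = list(partition.eigengenes.index)
    groups = meta.table.loc[samples, "group"]
    if groups.nunique() < 2:
        raise ValueError("module-trait association needs both groups")
    indicator = (groups == "PD").astype(float).to_numpy()
    rows = []
    n = len(samples)
    for m in partition.eigengenes.columns:
        e = partition.eigengenes[m].to_numpy()
        r = float(np.corrcoef(e, indicator)[0, 1])
        p = pearson_pvalue(r, n)
        rows.append({"module": m, "r": r, "p": p})
    out = pd.DataFrame(rows).set_index("module")
    out["q"] = bh_adjust(out["p"])
    out["trait_class"] = "none"
    out.loc[(out["r"] > 0) & (out["p"] <= alpha), "trait_class"] = "PD"
    out.loc[(out["r"] < 0) & (out["p"] <= alpha), "trait_class"] = "HC"
    partition.trait_stats = out
    return out


def intramodular_connectivity(net: CoexpressionNetwork,
                              partition: ModulePartition) -> pd.Series:
    """Per-gene within-module adjacency row sum (kWithin)."""
    adj = np.array(net.adjacency, dtype=float)
    np.fill_diagonal(adj, 0.0)
    genes = list(net.genes)
    k = pd.Series(0.0, index=genes, name="kWithin")
    for m in partition.labels.unique():
        if m == UNASSIGNED:
            continue
        idx = [genes.index(g) for g in partition.genes_in(m)]
        sub = adj[np.ix_(idx, idx)]
        k.iloc[idx] = sub.sum(axis=1)
    return k
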