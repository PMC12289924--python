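"""Per-module topology metrics and their trait-class comparisons.

Intramodular connectivity is the within-module adjacency sum divided
by two; mean connectivity the average within-module edge weight.
Module diversity (mH') is the Shannon entropy (nats) of member genes'
summed raw activity. Centralities and clustering come from networkx on
a thresholded weighted graph, with distance = 1 / weight for
path-based metrics, and are averaged per module.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import UNASSIGNED, CoexpressionNetwork, ModulePartition
from .quantify import ActivityMatrix
from ._stats import bh_adjust, shannon

logger = logging.getLogger(__name__)

CENTRALITY_METRICS = (
    "clustering_coefficient",
    "degree_centrality",
    "closeness_centrality",
    "eigenvector_centrality",
    "betweenness_centrality",
)


def module_connectivity(net: CoexpressionNetwork,
                        partition: ModulePartition) -> pd.DataFrame:
    """Per-module intramodular connectivity and mean edge weight.

    intramodular = sum of the within-module adjacency matrix / 2
    (diagonal excluded); mean = intramodular / C(size, 2).
    """
    adj = np.array(net.adjacency, dtype=float)
    np.fill_diagonal(adj, 0.0)
    genes = list(net.genes)
    pos = {g: i for i, g in enumerate(genes)}
    rows = []
    for m in sorted(partition.labels.unique()):
        if m == UNASSIGNED:
            continue
        idx = [pos[g] for g in partition.genes_in(m)]
        size = len(idx)
        if size < 2:
            logger.warning("module %s has < 2 genes; connectivity set to 0", m)
            rows.append({"module": m, "size": size,
                         "intramodular_connectivity": 0.0, "mean_connectivity": 0.0})
            continue
        sub = adj[np.ix_(idx, idx)]
        intr = float(sub.sum() / 2.0)
        n_pairs = size * (size - 1) / 2
        rows.append({"module": m, "size": size,
                     "intramodular_connectivity": intr,
                     "mean_connectivity": intr / n_pairs})
    return pd.DataFrame(rows).set_index("module")


def _weighted_graph(adj: np.ndarray, genes: list[str],
                    edge_threshold: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            w = adj[i, j]
            if w > edge_threshold:
                g.add_edge(genes[i], genes[j], weight=float(w),
                           distance=1.0 / float(w))
    return g


def gene_graph_metrics(net: CoexpressionNetwork,
                       edge_threshold: float = 0.01) -> pd.DataFrame:
    """Per-gene centralities on the thresholded weighted network."""
    adj = np.array(net.adjacency, dtype=float)
    np.fill_diagonal(adj, 0.0)
    genes = list(net.genes)
    g = _weighted_graph(adj, genes, edge_threshold)
    n = len(genes)
    strength = {v: sum(d["weight"] for _, _, d in g.edges(v, data=True))
                for v in genes}
    degree_c = {v: strength[v] / (n - 1) for v in genes} if n > 1 else \
        {v: 0.0 for v in genes}
    clustering = nx.clustering(g, weight="weight")
    closeness = nx.closeness_centrality(g, distance="distance")
    eigen = {v: 0.0 for v in genes}
    # eigenvector centrality: principal eigenvector of the weighted
    # adjacency, L2-normalized; defined per connected component
    # (isolates stay 0), entries taken non-negative
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        nodes = sorted(comp)
        sub = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        w, v = np.linalg.eigh(sub)
        vec = np.abs(v[:, int(np.argmax(w))])
        vec /= np.linalg.norm(vec)
        eigen.update(dict(zip(nodes, vec)))
    betweenness = nx.betweenness_centrality(g, weight="distance", normalized=True)
    return pd.DataFrame(
        {
            "clustering_coefficient": pd.Series(clustering),
            "degree_centrality": pd.Series(degree_c),
            "closeness_centrality": pd.Series(closeness),
            "eigenvector_centrality": pd.Series(eigen),
            "betweenness_centrality": pd.Series(betweenness),
        }
    ).loc[genes]


def graph_metrics(net: CoexpressionNetwork, partition: ModulePartition,
                  edge_threshold: float = 0.01) -> pd.DataFrame:
    """Module-averaged centralities (whole-network metrics, mean per module)."""
    per_gene = gene_graph_metrics(net, edge_threshold)
    labels = partition.labels.reindex(per_gene.index)
    out = per_gene.groupby(labels).mean()
    return out.loc[[m for m in out.index if m != UNASSIGNED]]


def module_diversity(act: ActivityMatrix, partition: ModulePartition) -> pd.Series:
    """Shannon entropy (nats) of member genes' summed raw activity.

    g_i is gene i's activity ratio summed over samples, renormalized to
    proportions within the module; modules with all-zero activity are
    missing-coded.
    """
    if act.state != "raw_ratio":
        raise ValueError("module diversity is defined on the raw activity ratio")
    totals = act.values.sum(axis=1, skipna=True)
    out = {}
    for m in sorted(partition.labels.unique()):
        if m == UNASSIGNED:
            continue
        genes = [g for g in partition.genes_in(m) if g in totals.index]
        g_tot = totals.reindex(genes).fillna(0.0).to_numpy()
        if g_tot.sum() <= 0:
            out[m] = np.nan
            continue
        out[m] = shannon(g_tot)
    return pd.Series(out, name="module_diversity")


def topology_table(net: CoexpressionNetwork, partition: ModulePartition,
                   act: ActivityMatrix, edge_threshold: float = 0.01) -> pd.DataFrame:
    """One row per module: size, connectivity, diversity, centralities, trait class."""
    conn = module_connectivity(net, partition)
    cent = graph_metrics(net, partition, edge_threshold)
    div = module_diversity(act, partition)
    out = conn.join(cent, how="left")
    out["module_diversity"] = div
    if partition.trait_stats is not None:
        out["trait_class"] = partition.trait_stats["trait_class"].reindex(out.index)
    else:
        out["trait_class"] = "none"
    return out


def compare_by_trait(topo: pd.DataFrame, exclude=()) -> pd.DataFrame:
    """Kruskal-Wallis of each topology metric across trait classes.

    Modules listed in `exclude` are removed before testing (the
    analysis supports re-testing without a dominant module). A metric
    whose classes do not each hold >= 2 modules is missing-coded.
    """
    tab = topo.drop(index=[m for m in exclude if m in topo.index])
    metrics = [c for c in tab.columns if c not in ("size", "trait_class")]
    rows = []
    for metric in metrics:
        groups = [g[metric].dropna().to_numpy()
                  for _, g in tab.groupby("trait_class")]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            rows.append({"metric": metric, "H": np.nan, "p": np.nan})
            continue
        if np.ptp(np.concatenate(groups)) == 0:
            # identical values everywhere: no evidence of class differences
            rows.append({"metric": metric, "H": 0.0, "p": 1.0})
            continue
        h, p = stats.kruskal(*groups)
        rows.append({"metric": metric, "H": float(h), "p": float(p)})
    return pd.DataFrame(rows).set_index("metric")


def diversity_metric_correlations(topo: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of module diversity with every other metric.

    Returns one row per metric with rho, p and BH q (family = all
    tested metrics); constant metrics are missing-coded.
    """
    if len(topo) < 4:
        raise ValueError("need >= 4 modules for metric correlations")
    div = topo["module_diversity"]
    metrics = [c for c in topo.columns
               if c not in ("module_diversity", "trait_class")]
    rows = []
    for metric in metrics:
        x = topo[metric].astype(float)
        ok = x.notna() & div.notna()
        if ok.sum() < 4 or x[ok].nunique() == 1 or div[ok].nunique() == 1:
            rows.append({"metric": metric, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(div[ok], x[ok])
        rows.append({"metric": metric, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows).set_index("metric")
    out["q"] = bh_adjust(out["p"])
    return out
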