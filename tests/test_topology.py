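import heapq

import numpy as np
import pandas as pd
import pytest

from micoexpress import topology
from micoexpress.network import CoexpressionNetwork, ModulePartition
from micoexpress.quantify import ActivityMatrix


def _net(adj):
    adj = np.asarray(adj, dtype=float)
    genes = [f"g{i}" for i in range(adj.shape[0])]
    return CoexpressionNetwork(genes, adj, adj, 6, pd.DataFrame())


def _partition(labels):
    labels = pd.Series(labels, index=[f"g{i}" for i in range(len(labels))])
    return ModulePartition(labels, pd.DataFrame())


class TestModuleConnectivity:
    def test_triangle_closed_form(self):
        net = _net(np.ones((3, 3)))
        out = topology.module_connectivity(net, _partition(["M1"] * 3))
        assert out.loc["M1", "intramodular_connectivity"] == pytest.approx(3.0)
        assert out.loc["M1", "mean_connectivity"] == pytest.approx(1.0)

    def test_empty_adjacency_gives_zero(self):
        net = _net(np.eye(4))
        out = topology.module_connectivity(net, _partition(["M1"] * 4))
        assert out.loc["M1", "intramodular_connectivity"] == 0.0

    def test_matches_bruteforce_pair_loop(self):
        rng = np.random.default_rng(0)
        a = rng.random((12, 12))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        net = _net(a)
        out = topology.module_connectivity(net, _partition(["M1"] * 12))
        brute = sum(a[i, j] for i in range(12) for j in range(i + 1, 12))
        assert out.loc["M1", "intramodular_connectivity"] == \
            pytest.approx(brute, abs=1e-12)
        assert out.loc["M1", "mean_connectivity"] == \
            pytest.approx(brute / 66, abs=1e-12)

    def test_mean_is_intramodular_over_pairs(self):
        rng = np.random.default_rng(1)
        a = rng.random((9, 9))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        out = topology.module_connectivity(_net(a),
                                           _partition(["M1"] * 5 + ["M2"] * 4))
        for m, size in (("M1", 5), ("M2", 4)):
            n_pairs = size * (size - 1) / 2
            assert out.loc[m, "mean_connectivity"] == pytest.approx(
                out.loc[m, "intramodular_connectivity"] / n_pairs)


def dijkstra_all(dist, src):
    n = dist.shape[0]
    d = np.full(n, np.inf)
    d[src] = 0.0
    heap = [(0.0, src)]
    seen = set()
    while heap:
        du, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        for v in range(n):
            w = dist[u, v]
            if np.isfinite(w) and du + w < d[v]:
                d[v] = du + w
                heapq.heappush(heap, (d[v], v))
    return d


def betweenness_bruteforce(dist):
    """Exhaustive shortest-path enumeration (Dijkstra + path counting)."""
    n = dist.shape[0]
    count = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            d = dijkstra_all(dist, s)
            if not np.isfinite(d[t]):
                continue
            # count shortest s-t paths through each node by DP over the
            # shortest-path DAG
            dt = dijkstra_all(dist, t)
            target = d[t]
            on_path = [v for v in range(n)
                       if np.isclose(d[v] + dt[v], target, atol=1e-12)]
            sigma = {v: 0.0 for v in range(n)}
            sigma[s] = 1.0
            for v in sorted(on_path, key=lambda v: d[v]):
                if v == s:
                    continue
                sigma[v] = sum(
                    sigma[u] for u in on_path
                    if np.isfinite(dist[u, v])
                    and np.isclose(d[u] + dist[u, v], d[v], atol=1e-12)
                )
            for v in on_path:
                if v in (s, t):
                    continue
                sigma_v = sigma[v] * _paths_from(dist, dt, v, t)
                count[v] += sigma_v / sigma[t]
    return count / ((n - 1) * (n - 2) / 2)


def _paths_from(dist, dt, v, t):
    if v == t:
        return 1.0
    total = 0.0
    n = dist.shape[0]
    for u in range(n):
        if np.isfinite(dist[v, u]) and np.isclose(dt[v], dist[v, u] + dt[u],
                                                  atol=1e-12):
            total += _paths_from(dist, dt, u, t)
    return total


class TestGraphMetrics:
    def test_path_graph_betweenness(self):
        a = np.zeros((4, 4))
        for i, j in ((0, 1), (1, 2), (2, 3)):
            a[i, j] = a[j, i] = 1.0
        out = topology.gene_graph_metrics(_net(a), edge_threshold=0.0)
        assert out.loc["g1", "betweenness_centrality"] == pytest.approx(2 / 3)
        assert out.loc["g0", "betweenness_centrality"] == 0.0

    def test_complete_graph_metrics(self):
        a = np.ones((5, 5))
        out = topology.gene_graph_metrics(_net(a), edge_threshold=0.0)
        np.testing.assert_allclose(out["clustering_coefficient"], 1.0)
        np.testing.assert_allclose(out["closeness_centrality"], 1.0)
        np.testing.assert_allclose(out["degree_centrality"], 1.0)
        np.testing.assert_allclose(out["betweenness_centrality"], 0.0)

    def test_betweenness_matches_bruteforce_on_random_graphs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.random((8, 8))
            a = (a + a.T) / 2
            a[a < 0.35] = 0.0  # sparse graph
            np.fill_diagonal(a, 0.0)
            out = topology.gene_graph_metrics(_net(a), edge_threshold=0.0)
            with np.errstate(divide="ignore"):
                dist = np.where(a > 0, 1.0 / a, np.inf)
            np.fill_diagonal(dist, np.inf)
            brute = betweenness_bruteforce(dist)
            np.testing.assert_allclose(out["betweenness_centrality"],
                                       brute, atol=1e-9)

    def test_eigenvector_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(11)
        a = rng.random((10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        out = topology.gene_graph_metrics(_net(a), edge_threshold=0.0)
        w, v = np.linalg.eigh(a)
        expected = np.abs(v[:, -1])
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(out["eigenvector_centrality"], expected,
                                   atol=1e-9)


class TestModuleDiversity:
    def _act(self, totals):
        vals = pd.DataFrame({"s0": totals},
                            index=[f"g{i}" for i in range(len(totals))])
        return ActivityMatrix(vals)

    def test_uniform_four_genes_is_ln4(self):
        out = topology.module_diversity(self._act([2.0, 2, 2, 2]),
                                        _partition(["M1"] * 4))
        assert out["M1"] == pytest.approx(np.log(4))

    def test_single_dominant_gene_is_zero(self):
        out = topology.module_diversity(self._act([5.0, 0, 0]),
                                        _partition(["M1"] * 3))
        assert out["M1"] == 0.0

    def test_hand_computed_proportions(self):
        out = topology.module_diversity(self._act([0.5, 0.25, 0.25]),
                                        _partition(["M1"] * 3))
        assert out["M1"] == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_module_missing_coded(self):
        out = topology.module_diversity(self._act([0.0, 0, 0]),
                                        _partition(["M1"] * 3))
        assert np.isnan(out["M1"])

    def test_bounded_by_log_size_with_equality_iff_uniform(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            totals = rng.lognormal(0, 1, 6)
            out = topology.module_diversity(self._act(totals),
                                            _partition(["M1"] * 6))
            assert 0 <= out["M1"] <= np.log(6) + 1e-9


class TestTraitComparisons:
    def _topo(self, values, classes):
        return pd.DataFrame({"metric_x": values, "trait_class": classes,
                             "size": 30},
                            index=[f"M{i + 1}" for i in range(len(values))])

    def test_identical_values_give_h_zero_p_one(self):
        topo = self._topo([1.0] * 9, ["HC", "PD", "none"] * 3)
        out = topology.compare_by_trait(topo)
        assert out.loc["metric_x", "H"] == 0.0
        assert out.loc["metric_x", "p"] == 1.0

    def test_separated_ranges_detected(self):
        topo = self._topo(
            [1, 2, 3, 4, 5, 11, 12, 13, 14, 15, 21, 22, 23, 24, 25.0],
            ["HC"] * 5 + ["PD"] * 5 + ["none"] * 5)
        out = topology.compare_by_trait(topo)
        assert out.loc["metric_x", "p"] < 0.01

    def test_excluding_a_whole_class_missing_codes(self):
        topo = self._topo([1, 2, 3, 4.0], ["HC", "HC", "PD", "PD"])
        out = topology.compare_by_trait(topo, exclude=["M3", "M4"])
        assert np.isnan(out.loc["metric_x", "p"])


class TestDiversityCorrelations:
    def _topo(self, div, metric):
        return pd.DataFrame({"module_diversity": div, "metric_x": metric,
                             "trait_class": "none"},
                            index=[f"M{i + 1}" for i in range(len(div))])

    def test_monotone_increase_gives_rho_one(self):
        out = topology.diversity_metric_correlations(
            self._topo([1, 2, 3, 4.0], [10, 20, 30, 40.0]))
        assert out.loc["metric_x", "rho"] == pytest.approx(1.0)

    def test_reversed_ranks_give_rho_minus_one(self):
        out = topology.diversity_metric_correlations(
            self._topo([1, 2, 3, 4.0], [4, 3, 2, 1.0]))
        assert out.loc["metric_x", "rho"] == pytest.approx(-1.0)

    def test_constant_metric_missing_coded(self):
        out = topology.diversity_metric_correlations(
            self._topo([1, 2, 3, 4.0], [7.0] * 4))
        assert np.isnan(out.loc["metric_x", "rho"])
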