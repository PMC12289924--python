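import numpy as np
import pandas as pd
import pytest

from micoexpress import network
from micoexpress.network import (
    CoexpressionNetwork,
    cut_modules,
    module_eigengene,
    module_trait,
    select_power,
    signed_adjacency,
    soft_threshold_scan,
    topological_overlap,
)

from conftest import make_meta


def _expr(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes,
                        columns=[f"s{j}" for j in range(arr.shape[1])])


def tom_bruteforce(a):
    """Naive O(n^3) topological overlap for the oracle comparison."""
    a = np.array(a, dtype=float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestSignedAdjacency:
    def test_perfect_correlation_closed_forms(self):
        x = np.arange(10, dtype=float)
        expr = _expr([x, x, -x])
        a = signed_adjacency(expr, beta=17)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0, abs=1e-30)

    def test_zero_correlation_value(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        y -= x * np.dot(x, y) / np.dot(x, x)  # exactly orthogonal
        a = signed_adjacency(_expr([x, y]), beta=17)
        assert a[0, 1] == pytest.approx(0.5**17, rel=1e-2)

    def test_constant_gene_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(_expr([[1, 1, 1], [1, 2, 3]]), beta=6)


class TestTopologicalOverlap:
    def test_complete_graph_is_all_ones(self):
        a = np.ones((3, 3))
        np.testing.assert_allclose(topological_overlap(a), 1.0)

    def test_empty_graph_offdiag_zero(self):
        t = topological_overlap(np.eye(4))
        assert np.all(t[~np.eye(4, dtype=bool)] == 0)

    def test_matches_bruteforce_on_random_instances(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.random((15, 15))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            np.testing.assert_allclose(topological_overlap(a),
                                       tom_bruteforce(a), atol=1e-12)


class TestSoftThreshold:
    def test_power_law_connectivity_fits_well(self):
        # k drawn so that freq(k-bin) follows k^-gamma exactly on the
        # log-log grid the fit regresses over
        ks = []
        for k in range(1, 11):
            ks.extend([float(k)] * int(round(1000 * k**-2.0)))
        fit, slope = network.scale_free_fit(np.array(ks))
        assert fit > 0.97
        assert slope < 0

    def test_r2_cut_zero_returns_smallest_power(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(size=(25, 12)))
        beta, sft = soft_threshold_scan(expr, powers=[3, 5, 9], r2_cut=0.0)
        assert beta == 3
        assert list(sft["power"]) == [3, 5, 9]

    def test_selection_rule_picks_first_crossing(self):
        # mirrors the cohort rule: fit first reaches 0.9 at power 17
        sft = pd.DataFrame({
            "power": list(range(1, 21)),
            "fit": [0.2 + 0.04 * p for p in range(1, 21)],
        })
        sft.loc[sft["power"] < 17, "fit"] = 0.5
        sft.loc[sft["power"] == 17, "fit"] = 0.918
        sft.loc[sft["power"] > 17, "fit"] = 0.95
        assert select_power(sft, r2_cut=0.9) == 17

    def test_no_crossing_warns_and_uses_argmax(self):
        sft = pd.DataFrame({"power": [1, 2, 3], "fit": [0.1, 0.4, 0.2]})
        with pytest.warns(UserWarning, match="maximum fit"):
            assert select_power(sft, r2_cut=0.9) == 2


class TestEigengene:
    def test_identical_profiles_correlate_one(self):
        prof = np.sin(np.linspace(0, 6, 30))
        expr = _expr([prof, prof * 2 + 1, prof * 0.5 - 3])
        e, explained = module_eigengene(expr, expr.index)
        for g in expr.index:
            assert np.corrcoef(e, expr.loc[g])[0, 1] == pytest.approx(1.0)
        assert explained == pytest.approx(1.0)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.normal(size=(5, 40)))
        e1, _ = module_eigengene(expr, expr.index)
        e2, _ = module_eigengene(-expr, expr.index)
        mean_cor = np.mean([np.corrcoef(e2, -expr.loc[g])[0, 1]
                            for g in expr.index])
        assert mean_cor > 0  # orientation rule restores positive mean

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.normal(size=(20, 35)))
        _, explained = module_eigengene(expr, expr.index)
        z = (expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True))
        z /= z.std(1, keepdims=True)
        w = np.linalg.eigvalsh(z @ z.T)
        assert explained == pytest.approx(w[-1] / w.sum(), abs=1e-10)


def _block_tom(sizes, within, between):
    n = sum(sizes)
    t = np.full((n, n), between)
    start = 0
    for s in sizes:
        t[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(t, 1.0)
    return t


class TestCutModules:
    def _net(self, tom):
        genes = [f"g{i:03d}" for i in range(tom.shape[0])]
        return CoexpressionNetwork(genes, tom.copy(), tom, 6, pd.DataFrame())

    def _expr_for_blocks(self, sizes, seed=0, r=0.95):
        rng = np.random.default_rng(seed)
        rows = []
        for b, s in enumerate(sizes):
            factor = rng.normal(size=60)
            for _ in range(s):
                rows.append(np.sqrt(r) * factor
                            + np.sqrt(1 - r) * rng.normal(size=60))
        arr = np.array(rows)
        return _expr(arr, genes=[f"g{i:03d}" for i in range(arr.shape[0])])

    def test_two_planted_blocks_recovered_exactly(self):
        tom = _block_tom([30, 30], 0.9, 0.05)
        expr = self._expr_for_blocks([30, 30])
        part = cut_modules(self._net(tom), expr, min_module_size=20,
                           medissthres=0.18)
        labels = part.labels
        assert labels.nunique() == 2
        assert labels.iloc[:30].nunique() == 1
        assert labels.iloc[30:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[30]

    def test_small_block_unassigned(self):
        tom = _block_tom([10], 0.9, 0.0)
        expr = self._expr_for_blocks([10])
        with pytest.warns(UserWarning):
            part = cut_modules(self._net(tom), expr, min_module_size=20,
                               medissthres=0.18)
        assert (part.labels == "M0").all()

    def test_correlated_eigengenes_merged(self):
        # two topological blocks whose expression shares one factor:
        # eigengene dissimilarity < 0.18 forces a merge
        tom = _block_tom([25, 25], 0.9, 0.05)
        rng = np.random.default_rng(5)
        factor = rng.normal(size=60)
        rows = [np.sqrt(0.95) * factor
                + np.sqrt(0.05) * rng.normal(size=60) for _ in range(50)]
        expr = _expr(np.array(rows), genes=[f"g{i:03d}" for i in range(50)])
        part = cut_modules(self._net(tom), expr,
                           min_module_size=20, medissthres=0.18)
        assert part.labels.nunique() == 1
        assert len(part.merge_log) >= 1

    def test_gene_order_permutation_relabels_only(self):
        tom = _block_tom([25, 30], 0.85, 0.03)
        expr = self._expr_for_blocks([25, 30], seed=7)
        net = self._net(tom)
        part1 = cut_modules(net, expr, 20, 0.18)
        perm = np.random.default_rng(8).permutation(tom.shape[0])
        tom_p = tom[np.ix_(perm, perm)]
        genes_p = [net.genes[i] for i in perm]
        net_p = CoexpressionNetwork(genes_p, tom_p.copy(), tom_p, 6,
                                    pd.DataFrame())
        part2 = cut_modules(net_p, expr.iloc[perm], 20, 0.18)
        from sklearn.metrics import adjusted_rand_score

        joined = pd.concat([part1.labels.rename("a"),
                            part2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0


class TestModuleTrait:
    def _partition(self, eigengenes):
        labels = pd.Series("M1", index=["g0", "g1"])
        return network.ModulePartition(labels, eigengenes)

    def test_indicator_eigengene_gives_r_one(self):
        samples = [f"s{i}" for i in range(10)]
        groups = ["HC"] * 5 + ["PD"] * 5
        meta = make_meta(samples, groups)
        e = pd.DataFrame({"M1": [0.0] * 5 + [1.0] * 5}, index=samples)
        out = module_trait(self._partition(e), meta)
        assert out.loc["M1", "r"] == pytest.approx(1.0)
        assert out.loc["M1", "p"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["M1", "trait_class"] == "PD"

    def test_t_distribution_p_value_closed_form(self):
        # r = 0.3 at n = 95: t = 3.033, two-sided p ~ 0.0031
        from micoexpress._stats import pearson_pvalue

        assert pearson_pvalue(0.3, 95) == pytest.approx(0.00315, abs=2e-4)

    def test_null_eigengene_calibration(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(40)]
        meta = make_meta(samples, ["HC"] * 20 + ["PD"] * 20)
        hits = 0
        for _ in range(200):
            e = pd.DataFrame({"M1": rng.normal(size=40)}, index=samples)
            out = module_trait(self._partition(e), meta)
            hits += out.loc["M1", "p"] < 0.05
        assert 0.02 < hits / 200 < 0.10
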