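import numpy as np
import pandas as pd
import pytest

from micoexpress import quantify, taxa
from micoexpress.io import FeatureAnnotation

from conftest import make_counts, make_meta


def _ann(mapping):
    """mapping: feature -> (ko, genus)."""
    df = pd.DataFrame(
        {
            "ko": {f: ko for f, (ko, _) in mapping.items()},
            "lineage": {
                f: f"d__B;p__P;c__C;o__O;f__F;g__{g};s__{g} sp"
                for f, (_, g) in mapping.items()
            },
        }
    )
    return FeatureAnnotation.from_frame(df)


class TestBuildTensor:
    def test_same_ko_same_genus_collapses(self):
        mg = make_counts([[10, 10], [20, 20], [5, 5]], [100, 100, 100],
                         features=["f1", "f2", "f3"])
        mt = make_counts([[4, 4], [6, 6], [1, 1]], [100, 100, 100],
                         features=["f1", "f2", "f3"], layer="MT")
        ann = _ann({"f1": ("K1", "G1"), "f2": ("K1", "G1"),
                    "f3": ("K2", "G2")})
        tensor = taxa.build_tensor(mg, mt, ann, rank="genus")
        k1 = tensor.long[tensor.long["ko"] == "K1"]
        assert set(k1["taxon"]) == {"G1"}  # two ORFs, one tensor row

    def test_same_ko_two_genera_stay_separate(self):
        mg = make_counts([[10], [20]], [100, 100], features=["f1", "f2"])
        mt = make_counts([[4], [6]], [100, 100], features=["f1", "f2"],
                         layer="MT")
        ann = _ann({"f1": ("K1", "G1"), "f2": ("K1", "G2")})
        tensor = taxa.build_tensor(mg, mt, ann, rank="genus")
        k1 = tensor.long[tensor.long["ko"] == "K1"]
        assert set(k1["taxon"]) == {"G1", "G2"}

    def test_marginalizing_taxa_reproduces_ko_activity(self, small_cohort,
                                                       small_tensor):
        c = small_cohort
        mg_tpm = quantify.aggregate_tpm(quantify.tpm(c["mg"]), c["ann"],
                                        by="ko")
        mt_tpm = quantify.aggregate_tpm(quantify.tpm(c["mt"]), c["ann"],
                                        by="ko")
        ko_act = quantify.mta_ratio(mt_tpm, mg_tpm).values
        marginal = small_tensor.marginal_ko()
        shared = marginal.index.intersection(ko_act.index)
        assert len(shared) > 50
        a = marginal.loc[shared, ko_act.columns]
        b = ko_act.loc[shared].fillna(0.0)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_unknown_rank_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            taxa.build_tensor(small_cohort["mg"], small_cohort["mt"],
                              small_cohort["ann"], rank="kingdom")


class TestDifferentialMta:
    def _values(self, rows, samples):
        return pd.DataFrame(rows, columns=samples,
                            index=[f"T{i}" for i in range(len(rows))])

    def test_single_unit_q_equals_p(self):
        samples = [f"h{i}" for i in range(5)] + [f"p{i}" for i in range(5)]
        meta = make_meta(samples, ["HC"] * 5 + ["PD"] * 5)
        vals = self._values([[1.0, 2, 3, 4, 5, 2, 3, 4, 5, 6]], samples)
        out = taxa.differential_mta(vals, meta, min_prevalence=0.5)
        assert out["q"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_low_prevalence_units_never_tested(self):
        samples = [f"h{i}" for i in range(5)] + [f"p{i}" for i in range(5)]
        meta = make_meta(samples, ["HC"] * 5 + ["PD"] * 5)
        sparse = [1.0] + [0.0] * 9
        dense = [1.0, 2, 3, 4, 5, 2, 3, 4, 5, 6]
        out = taxa.differential_mta(self._values([sparse, dense], samples),
                                    meta, min_prevalence=0.5)
        assert list(out.index) == ["T1"]

    def test_type_one_error_calibrated(self):
        samples = ([f"h{i}" for i in range(15)]
                   + [f"p{i}" for i in range(15)])
        meta = make_meta(samples, ["HC"] * 15 + ["PD"] * 15)
        hits, total = 0, 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            vals = self._values(rng.lognormal(0, 1, (400, 30)), samples)
            out = taxa.differential_mta(vals, meta, min_prevalence=0.5)
            hits += int((out["p"] < 0.05).sum())
            total += len(out)
        # the rank-sum test is slightly conservative at n = 15 + 15
        # (discrete null), so the nominal 0.05 sits near the upper side
        assert 0.02 <= hits / total < 0.075

    def test_fully_dropped_taxon_detected(self):
        # a taxon silent in every PD sample: strong rank-sum signal
        rng = np.random.default_rng(1)
        n = 40
        samples = ([f"h{i}" for i in range(n)]
                   + [f"p{i}" for i in range(n)])
        meta = make_meta(samples, ["HC"] * n + ["PD"] * n)
        silenced = np.concatenate([rng.lognormal(0, 0.3, n), np.zeros(n)])
        background = rng.lognormal(0, 0.3, 2 * n)
        out = taxa.differential_mta(self._values([silenced, background],
                                                 samples), meta, 0.5)
        assert out.loc["T0", "q"] < 0.05
        assert out.loc["T0", "median_hc"] > out.loc["T0", "median_pd"]

    def test_tiny_group_refused(self):
        samples = ["h1", "h2", "p1", "p2", "p3"]
        meta = make_meta(samples, ["HC", "HC", "PD", "PD", "PD"])
        with pytest.raises(ValueError, match=">= 3"):
            taxa.differential_mta(self._values([[1.0] * 5], samples), meta, 0.1)


class TestOrdination:
    def test_mirrored_clouds_give_r2_one_and_floor_p(self):
        n = 10
        samples = [f"h{i}" for i in range(n)] + [f"p{i}" for i in range(n)]
        meta = make_meta(samples, ["HC"] * n + ["PD"] * n)
        base = np.random.default_rng(2).normal(size=(30, n))
        # PD samples are exact mirror images: zero within-group variance
        # on the separating axis
        vals = np.concatenate([base * 0 + 5, base * 0 - 5], axis=1)
        vals += np.random.default_rng(3).normal(scale=1e-6,
                                                size=vals.shape)
        clr_vals = pd.DataFrame(vals, columns=samples)
        out = taxa.ordinate_and_fit(clr_vals, meta, n_perm=99, seed=0)
        assert out["r2"] > 0.999
        # the exact label complement reproduces r2 (swap symmetry), so
        # the permutation p can sit one step above the 1/(1+n_perm) floor
        assert out["p"] <= 2 / 100

    def test_random_labels_rarely_significant(self):
        rng = np.random.default_rng(4)
        n = 30
        vals = pd.DataFrame(rng.normal(size=(40, n)),
                            columns=[f"s{i}" for i in range(n)])
        hits = 0
        for rep in range(40):
            groups = rng.permutation(["HC"] * 15 + ["PD"] * 15)
            meta = make_meta(list(vals.columns), list(groups))
            out = taxa.ordinate_and_fit(vals, meta, n_perm=99, seed=rep)
            hits += out["p"] < 0.05
        assert hits <= 5

    def test_sample_duplication_leaves_r2_unchanged(self):
        rng = np.random.default_rng(5)
        n = 12
        samples = [f"s{i}" for i in range(n)]
        vals = pd.DataFrame(rng.normal(size=(20, n)), columns=samples)
        meta = make_meta(samples, ["HC"] * 6 + ["PD"] * 6)
        out1 = taxa.ordinate_and_fit(vals, meta, n_perm=99, seed=0)
        dup_samples = samples + [s + "b" for s in samples]
        dup = pd.concat([vals, vals.set_axis([s + "b" for s in samples],
                                             axis=1)], axis=1)
        meta2 = make_meta(dup_samples, ["HC"] * 6 + ["PD"] * 6 + ["HC"] * 6
                          + ["PD"] * 6)
        out2 = taxa.ordinate_and_fit(dup, meta2, n_perm=99, seed=0)
        assert out2["r2"] == pytest.approx(out1["r2"], abs=1e-9)

    def test_single_group_rejected(self):
        vals = pd.DataFrame(np.eye(4), columns=list("abcd"))
        meta = make_meta(list("abcd"), ["HC"] * 4)
        with pytest.raises(ValueError):
            taxa.ordinate_and_fit(vals, meta, n_perm=99)

    def test_scores_sign_invariant_to_feature_order(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(10)]
        vals = pd.DataFrame(rng.normal(size=(25, 10)), columns=samples)
        meta = make_meta(samples, ["HC"] * 5 + ["PD"] * 5)
        s1 = taxa.ordinate_and_fit(vals, meta, n_perm=99, seed=0)["scores"]
        perm = rng.permutation(25)
        s2 = taxa.ordinate_and_fit(vals.iloc[perm], meta, n_perm=99,
                                   seed=0)["scores"]
        for col in ("PC1", "PC2"):
            agree = np.allclose(s1[col], s2[col], atol=1e-8)
            flipped = np.allclose(s1[col], -s2[col], atol=1e-8)
            assert agree or flipped
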