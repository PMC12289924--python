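import numpy as np
import pandas as pd
import pytest

from micoexpress import quantify, simulate, taxa
from micoexpress.io import GeneFeatureTable, SampleMetadata


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by read-only tests."""
    cfg = simulate.SyntheticConfig(
        n_hc=20, n_pd=20, n_taxa=25, n_ko=120,
        module_sizes=[25, 25, 25], n_affected_modules=1,
        n_specialist_ko=8, seed=7,
    )
    mg, mt, ann, meta, truth = simulate.generate(cfg)
    return {"cfg": cfg, "mg": mg, "mt": mt, "ann": ann, "meta": meta,
            "truth": truth}


@pytest.fixture(scope="session")
def small_activity(small_cohort):
    c = small_cohort
    mg_tpm = quantify.aggregate_tpm(quantify.tpm(c["mg"]), c["ann"], by="ko")
    mt_tpm = quantify.aggregate_tpm(quantify.tpm(c["mt"]), c["ann"], by="ko")
    act = quantify.mta_ratio(mt_tpm, mg_tpm)
    filt, _, _ = quantify.prevalence_filter(act, 0.5)
    filled = quantify.ActivityMatrix(filt.values.fillna(0.0), filt.state)
    return filled


@pytest.fixture(scope="session")
def small_tensor(small_cohort):
    c = small_cohort
    return taxa.build_tensor(c["mg"], c["mt"], c["ann"], rank="genus")


def make_counts(counts, lengths, samples=None, layer="MG", features=None):
    """Build a GeneFeatureTable from plain arrays."""
    counts = np.atleast_2d(np.asarray(counts))
    n_feat, n_samp = counts.shape
    features = features or [f"g{i}" for i in range(n_feat)]
    samples = samples or [f"s{j}" for j in range(n_samp)]
    return GeneFeatureTable(
        pd.DataFrame(counts, index=features, columns=samples, dtype=np.int64),
        pd.Series(lengths, index=features, dtype=np.int64),
        layer,
    )


def make_meta(samples, groups):
    return SampleMetadata(pd.DataFrame({"group": groups}, index=samples))
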