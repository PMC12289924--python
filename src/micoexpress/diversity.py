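"""Ecological diversity of gene expression.

Three statistics, all on normalized (MT/MG) expression:

* tDGE (gH') — per gene and sample, the Shannon entropy (nats) of the
  expression shares of the taxa expressing that gene; 0 when a single
  taxon carries all expression.
* functional redundancy — per sample, Simpson species diversity
  D = 1 - sum p_i^2 minus Rao quadratic entropy Q = sum_ij p_i p_j d_ij
  on pairwise trait distances between species' expressed-gene profiles
  (binary Gower: mismatches over the union of expressed genes), so
  FR in [0, D].
* per-genus expressed-gene diversity — richness, Shannon and inverse
  Simpson over a genus's gene-expression proportions per sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMetadata
from .taxa import TaxonGeneTensor
from ._stats import (
    bh_adjust,
    group_split,
    half_min_positive,
    inverse_simpson,
    rank_compare,
    shannon,
)

logger = logging.getLogger(__name__)


def tdge_table(tensor: TaxonGeneTensor,
               include_unclassified: bool = False) -> pd.DataFrame:
    """tDGE per (gene, sample): genes x samples, NaN where unexpressed."""
    long = tensor.long
    if not include_unclassified:
        long = long[long["taxon"] != "unclassified"]
    expressed = long[long["value"] > 0]
    ent = (
        expressed.groupby(["ko", "sample"])["value"]
        .apply(lambda v: shannon(v.to_numpy()))
        .unstack("sample")
    )
    return ent


def tdge(tensor: TaxonGeneTensor, gene: str, sample: str) -> float:
    """tDGE of one gene in one sample (NaN if unexpressed there)."""
    sub = tensor.long
    sub = sub[(sub["ko"] == gene) & (sub["sample"] == sample)
              & (sub["taxon"] != "unclassified") & (sub["value"] > 0)]
    if sub.empty:
        return np.nan
    return shannon(sub["value"].to_numpy())


def tdge_group_compare(tdge_df: pd.DataFrame, meta: SampleMetadata,
                       ihub_genes=()) -> dict:
    """Group comparisons of gene expression diversity.

    Returns a dict with:

    * ``per_gene`` — per-gene group mean tDGE, log2FC (PD over HC,
      pseudocount = half the minimum positive tDGE), Mann-Whitney p and
      BH q (genes expressed in >= 3 samples per group);
    * ``distribution_tests`` — Mann-Whitney on gene-level mean tDGE:
      HC vs PD overall, within iHub genes, within non-iHub genes, and
      iHub vs non-iHub.
    """
    ihub = set(ihub_genes)
    per_gene = rank_compare(tdge_df, meta.table)
    eps = half_min_positive(tdge_df.to_numpy())
    per_gene["log2fc_tdge"] = np.log2(
        (per_gene["mean_pd"].fillna(0.0) + eps)
        / (per_gene["mean_hc"].fillna(0.0) + eps)
    )
    per_gene["ihub"] = [g in ihub for g in per_gene.index]

    hc, pd_ = group_split(meta.table, tdge_df.columns)
    mean_hc = tdge_df[hc].mean(axis=1)
    mean_pd = tdge_df[pd_].mean(axis=1)
    is_ihub = pd.Series([g in ihub for g in tdge_df.index], index=tdge_df.index)

    def _mw(x, y):
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if len(x) < 3 or len(y) < 3:
            return np.nan
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)

    tests = {
        "hc_vs_pd_all": _mw(mean_hc.to_numpy(), mean_pd.to_numpy()),
        "hc_vs_pd_ihub": _mw(mean_hc[is_ihub].to_numpy(), mean_pd[is_ihub].to_numpy()),
        "hc_vs_pd_non_ihub": _mw(mean_hc[~is_ihub].to_numpy(),
                                 mean_pd[~is_ihub].to_numpy()),
        "ihub_vs_non_ihub": _mw(
            pd.concat([mean_hc[is_ihub], mean_pd[is_ihub]]).to_numpy(),
            pd.concat([mean_hc[~is_ihub], mean_pd[~is_ihub]]).to_numpy(),
        ),
    }
    return {"per_gene": per_gene, "distribution_tests": tests,
            "log2fc_pseudocount": eps}


def _species_profiles(long: pd.DataFrame):
    """Per-species abundance (expression share) and binary trait profile."""
    abundance = long.groupby("taxon")["value"].sum()
    abundance = abundance[abundance > 0]
    traits = {
        t: frozenset(long.loc[(long["taxon"] == t) & (long["value"] > 0), "ko"])
        for t in abundance.index
    }
    return abundance / abundance.sum(), traits


def gower_binary(a: frozenset, b: frozenset) -> float:
    """Gower distance between binary expressed-gene profiles.

    Fraction of mismatching genes among genes expressed by either
    species (Jaccard distance); 0 for identical profiles, 1 for
    disjoint ones.
    """
    union = a | b
    if not union:
        return 0.0
    return len(a ^ b) / len(union)


def functional_redundancy(tensor: TaxonGeneTensor, sample: str,
                          include_unclassified: bool = False) -> dict:
    """Functional redundancy of one sample: FR = D - Q.

    D is the Simpson diversity of species expression shares, Q the Rao
    quadratic entropy over binary trait distances. A sample with a
    single expressing species has no between-species trait variation
    and gets FR = 0 by convention.
    """
    long = tensor.long
    long = long[long["sample"] == sample]
    if not include_unclassified:
        long = long[long["taxon"] != "unclassified"]
    p, traits = _species_profiles(long)
    species = list(p.index)
    if len(species) == 0:
        return {"simpson": np.nan, "rao_q": np.nan, "fr": np.nan, "n_species": 0}
    if len(species) == 1:
        logger.warning("sample %s has one expressing species: FR = 0", sample)
        return {"simpson": 0.0, "rao_q": 0.0, "fr": 0.0, "n_species": 1}
    pv = p.to_numpy()
    d = np.zeros((len(species), len(species)))
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            d[i, j] = d[j, i] = gower_binary(traits[species[i]], traits[species[j]])
    simpson = float(1.0 - np.sum(pv**2))
    rao_q = float(pv @ d @ pv)
    return {"simpson": simpson, "rao_q": rao_q, "fr": simpson - rao_q,
            "n_species": len(species)}


def functional_redundancy_table(tensor: TaxonGeneTensor,
                                meta: SampleMetadata | None = None) -> pd.DataFrame:
    """FR per sample (+ group column when metadata is given)."""
    samples = sorted(tensor.long["sample"].unique())
    rows = {s: functional_redundancy(tensor, s) for s in samples}
    out = pd.DataFrame(rows).T
    if meta is not None:
        out["group"] = meta.table["group"].reindex(out.index)
    return out


def fr_group_compare(fr: pd.DataFrame) -> float:
    """Mann-Whitney p for FR between HC and PD samples."""
    x = fr.loc[fr["group"] == "HC", "fr"].dropna().to_numpy(dtype=float)
    y = fr.loc[fr["group"] == "PD", "fr"].dropna().to_numpy(dtype=float)
    if len(x) < 3 or len(y) < 3:
        return np.nan
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def genus_expression_diversity(tensor: TaxonGeneTensor, meta: SampleMetadata,
                               genera=None) -> dict:
    """Expressed-gene diversity per genus and sample, with group tests.

    Per (genus, sample): richness (genes with expression > 0), Shannon
    and inverse Simpson over expression proportions. A genus silent in
    a sample gets richness 0 and missing-coded entropy indices. Group
    comparisons (Mann-Whitney HC vs PD) run per genus per index with
    BH q across the genera x indices family.
    """
    long = tensor.long
    if genera is not None:
        present = set(long["taxon"].unique())
        missing = [g for g in genera if g not in present]
        for g in missing:
            logger.warning("genus %r absent from tensor: missing-coded", g)
        keep = [g for g in genera if g in present]
    else:
        keep = [t for t in sorted(long["taxon"].unique()) if t != "unclassified"]
        missing = []
    samples = sorted(long["sample"].unique())
    rows = []
    for genus in keep:
        sub = long[(long["taxon"] == genus) & (long["value"] > 0)]
        by_sample = dict(tuple(sub.groupby("sample")))
        for s in samples:
            vals = by_sample.get(s)
            if vals is None or vals.empty:
                rows.append({"genus": genus, "sample": s, "richness": 0,
                             "shannon": np.nan, "inv_simpson": np.nan})
                continue
            v = vals["value"].to_numpy()
            rows.append({"genus": genus, "sample": s, "richness": len(v),
                         "shannon": shannon(v), "inv_simpson": inverse_simpson(v)})
    for genus in missing:
        rows.append({"genus": genus, "sample": None, "richness": np.nan,
                     "shannon": np.nan, "inv_simpson": np.nan})
    table = pd.DataFrame(rows)

    test_rows = []
    hc, pd_ = group_split(meta.table, samples)
    for genus in keep:
        sub = table[table["genus"] == genus].set_index("sample")
        for index_name in ("richness", "shannon", "inv_simpson"):
            x = sub.loc[[s for s in hc if s in sub.index], index_name].dropna()
            y = sub.loc[[s for s in pd_ if s in sub.index], index_name].dropna()
            if len(x) < 3 or len(y) < 3:
                p = np.nan
            elif x.nunique() == 1 and y.nunique() == 1 and x.iloc[0] == y.iloc[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            test_rows.append({"genus": genus, "index": index_name,
                              "median_hc": x.median() if len(x) else np.nan,
                              "median_pd": y.median() if len(y) else np.nan,
                              "p": p})
    tests = pd.DataFrame(test_rows)
    if len(tests):
        tests["q"] = bh_adjust(tests["p"])
    return {"table": table, "tests": tests}
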