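"""Synthetic paired MG/MT data with planted co-expression structure.

The generator emulates the statistical structure of a taxon-resolved
gut meta-omic cohort: taxa with log-normal relative abundances carry
KEGG orthologs (KOs) at random; KOs inside planted modules share a
per-sample latent activity factor acting multiplicatively on their
expression rate; a disease group (PD) depletes the activity of selected
modules; and a configurable list of taxa is transcriptionally silenced
in PD samples, which lowers the taxonomic diversity of gene expression
(tDGE) of the KOs those taxa carry while leaving their genomic (MG)
signal untouched. Counts on both layers are negative binomial with a
shared dispersion.

Each (taxon, KO) pair a taxon carries becomes one gene-level feature
shared between layers, with its own uniformly drawn length, mimicking
ORF-level featureCounts output after KO/taxonomy annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    FeatureAnnotation,
    GeneFeatureTable,
    GeneSetCollection,
    SampleMetadata,
)


class ConfigError(ValueError):
    """Infeasible synthetic configuration."""


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the package's benchmark cohort.

    The default configuration is a desk-scale cohort of 40 HC + 40 PD
    samples, 600 KOs carried by 40 taxa, 5 planted modules of 40 genes
    with realized within-module Pearson correlation around 0.7 on the
    activity scale, a 0.5x depletion of the first two modules'
    activity in PD, and PD-silencing (p=0.9) of five specialist taxa
    that dominate the expression of a reserved 12-KO block. The
    variance split between the shared module factor and per-gene noise
    is set so that the planted 2x depletion stays detectable at this
    cohort size; background genes keep the modules dilute, limiting
    the compositional (TPM closure) distortion of planted effects.
    """

    n_hc: int = 40
    n_pd: int = 40
    n_taxa: int = 40
    n_ko: int = 600
    carriage_prob: float = 0.15
    n_modules: int = 5
    module_sizes: list[int] | None = None
    latent_factor_sd: float = 0.45
    noise_dispersion: float = 15.0  # NB size (inverse dispersion), shared
    group_effect: float = 0.5  # multiplies affected-module activity in PD
    n_affected_modules: int = 2
    dropout_taxa: list[str] | None = None  # default: by abundance rank
    n_dropout_taxa: int = 5
    dropout_rank_offset: int = 10  # default dropout taxa: abundance ranks 11-15
    n_specialist_ko: int = 12  # KO block jointly carried by dropout taxa
    dropout_expression_boost: float = 4.0  # specialists dominate those KOs
    p_drop: float = 0.9
    depth_mg: float = 2e6
    depth_mt: float = 1e6
    length_range: tuple[int, int] = (300, 3000)
    abundance_sigma: float = 0.5
    base_expression_sd: float = 0.5
    expression_noise_sd: float = 0.17  # per-(gene, sample) log-normal noise
    module_taxa_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = [40] * self.n_modules
        self.n_modules = len(self.module_sizes)
        if sum(self.module_sizes) > self.n_ko:
            raise ConfigError("sum of module sizes exceeds the KO pool")
        for p in (self.carriage_prob, self.p_drop):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.depth_mg <= 0 or self.depth_mt <= 0:
            raise ConfigError("library depths must be positive")
        if self.group_effect <= 0:
            raise ConfigError("group_effect must be positive")
        self.n_affected_modules = min(self.n_affected_modules, self.n_modules)
        if sum(self.module_sizes) + self.n_specialist_ko > self.n_ko:
            raise ConfigError("module + specialist KOs exceed the KO pool")


@dataclass
class SyntheticTruth:
    """Ground-truth record of every planted structure."""

    gene_module: pd.Series  # KO -> "M1".. or "M0" (background)
    module_affected: pd.Series  # module -> bool (PD-depleted activity)
    true_log2fc: pd.Series  # KO -> planted log2 group effect on activity
    tdge_down: pd.Series  # KO -> True if carried by a silenced taxon
    taxon_abundance: pd.DataFrame  # taxa x samples relative abundance
    carriage: pd.DataFrame  # taxa x KO boolean
    dropout_taxa: list[str] = field(default_factory=list)

    def affected_modules(self) -> list[str]:
        return list(self.module_affected.index[self.module_affected])


def factor_sd_for_correlation(target_r: float, expression_noise_sd: float) -> float:
    """Latent factor sd giving an expected within-module correlation.

    Under the one-factor log-normal model (log rate = base + factor +
    noise), the correlation of two member genes' log rates is
    sigma_f^2 / (sigma_f^2 + sigma_e^2); inverting gives the factor sd
    for a target correlation. Count noise adds on top, so the realized
    correlation on counted data is slightly lower.
    """
    if not 0 < target_r < 1:
        raise ConfigError("target correlation must lie in (0, 1)")
    return float(expression_noise_sd * np.sqrt(target_r / (1.0 - target_r)))


def _taxon_ids(n: int) -> list[str]:
    return [f"T{i + 1:03d}" for i in range(n)]


def _ko_ids(n: int) -> list[str]:
    return [f"K{i + 1:05d}" for i in range(n)]


def generate(config: SyntheticConfig):
    """Draw one synthetic cohort.

    Returns (mg, mt, annotation, metadata, truth). Deterministic in
    ``config.seed``: the same config yields bit-identical tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    taxa = _taxon_ids(cfg.n_taxa)
    kos = _ko_ids(cfg.n_ko)
    samples = [f"HC{i + 1:03d}" for i in range(cfg.n_hc)] + [
        f"PD{i + 1:03d}" for i in range(cfg.n_pd)
    ]
    is_pd = np.array([s.startswith("PD") for s in samples])
    n_samples = len(samples)

    # --- taxon abundances: log-normal around per-taxon means
    taxon_mu = rng.normal(0.0, 1.0, size=cfg.n_taxa)
    log_ab = taxon_mu[:, None] + rng.normal(
        0.0, cfg.abundance_sigma, size=(cfg.n_taxa, n_samples)
    )
    abundance = np.exp(log_ab)
    abundance /= abundance.sum(axis=0, keepdims=True)

    # --- dropout taxa: transcriptional specialists silenced in PD.
    # Default: moderate-abundance taxa that jointly carry a reserved
    # "specialist" KO block and, via a modest expression boost,
    # collectively dominate those genes' expression — so silencing them
    # collapses those genes' tDGE — while contributing only a few
    # percent of total MT mass (limited compositional distortion)
    if cfg.dropout_taxa is not None:
        dropout = [t for t in cfg.dropout_taxa if t in taxa]
    else:
        order = np.argsort(-taxon_mu)
        lo = min(cfg.dropout_rank_offset, max(cfg.n_taxa - cfg.n_dropout_taxa, 0))
        dropout = [taxa[i] for i in order[lo:lo + cfg.n_dropout_taxa]]
    dropout_idx = np.array([taxa.index(t) for t in dropout], dtype=int)
    specialist_ko = np.arange(cfg.n_ko - cfg.n_specialist_ko, cfg.n_ko)

    # --- module membership over KOs
    module_of = pd.Series("M0", index=kos, name="module")
    pos = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        module_of.iloc[pos:pos + size] = f"M{m}"
        pos += size
    modules = [f"M{m + 1}" for m in range(cfg.n_modules)]
    affected = pd.Series(False, index=modules)
    affected.iloc[: cfg.n_affected_modules] = True

    # --- carriage: Bernoulli background; module KOs forced onto an
    # overlapping taxon subset so module activity is taxon-structured.
    # Dropout specialists carry few KOs and stay out of planted modules
    carriage = rng.random((cfg.n_taxa, cfg.n_ko)) < cfg.carriage_prob
    if dropout_idx.size:
        carriage[dropout_idx] = False
        carriage[np.ix_(dropout_idx, specialist_ko)] = True
    candidate_taxa = np.array([i for i in range(cfg.n_taxa)
                               if i not in set(dropout_idx.tolist())])
    n_module_taxa = max(3, int(round(cfg.module_taxa_fraction * cfg.n_taxa)))
    n_module_taxa = min(n_module_taxa, len(candidate_taxa))
    for m in modules:
        members = np.flatnonzero((module_of == m).to_numpy())
        taxa_idx = rng.choice(candidate_taxa, size=n_module_taxa, replace=False)
        for k in members:
            carriers = rng.choice(
                taxa_idx, size=max(2, n_module_taxa // 2), replace=False
            )
            carriage[carriers, k] = True
    # every KO carried by at least one taxon
    for k in np.flatnonzero(carriage.sum(axis=0) == 0):
        carriage[rng.integers(cfg.n_taxa), k] = True

    # --- per-sample module activity factors (log link); PD shifts the
    # factor of affected modules by log(group_effect)
    factors = rng.normal(0.0, cfg.latent_factor_sd, size=(cfg.n_modules, n_samples))
    log_rate = np.zeros((cfg.n_ko, n_samples))
    base = rng.normal(0.0, cfg.base_expression_sd, size=cfg.n_ko)
    log_rate += base[:, None]
    if cfg.expression_noise_sd > 0:
        log_rate += rng.normal(0.0, cfg.expression_noise_sd,
                               size=(cfg.n_ko, n_samples))
    for mi, m in enumerate(modules):
        members = (module_of == m).to_numpy()
        log_rate[members] += factors[mi]
        if affected[m]:
            log_rate[np.ix_(members, is_pd)] += np.log(cfg.group_effect)
    expr_rate = np.exp(log_rate)  # KO x sample

    # --- dropout silencing (MT only; MG untouched)
    silenced = np.zeros((cfg.n_taxa, n_samples), dtype=bool)
    if dropout_idx.size and cfg.p_drop > 0:
        draws = rng.random((dropout_idx.size, n_samples)) < cfg.p_drop
        silenced[np.ix_(dropout_idx, is_pd)] = draws[:, is_pd]

    # --- features: one per carried (taxon, KO), length shared by layers
    t_idx, k_idx = np.nonzero(carriage)
    feature_ids = [f"{taxa[t]}|{kos[k]}" for t, k in zip(t_idx, k_idx)]
    lengths = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1,
                           size=len(feature_ids))

    # --- NB means: MG ~ abundance x length; MT ~ abundance x rate x length
    ab_f = abundance[t_idx]  # feature x sample
    len_f = lengths[:, None].astype(float)
    mg_w = ab_f * len_f
    boost = np.where(np.isin(t_idx, dropout_idx),
                     cfg.dropout_expression_boost, 1.0)[:, None]
    mt_expr = expr_rate[k_idx] * boost * np.where(silenced[t_idx], 0.0, 1.0)
    mt_w = ab_f * mt_expr * len_f
    mg_mean = cfg.depth_mg * mg_w / mg_w.sum(axis=0, keepdims=True)
    mt_colsum = mt_w.sum(axis=0, keepdims=True)
    mt_mean = cfg.depth_mt * mt_w / np.where(mt_colsum > 0, mt_colsum, 1.0)

    size = cfg.noise_dispersion
    mg_counts = _nb_draw(rng, mg_mean, size)
    mt_counts = _nb_draw(rng, mt_mean, size)

    mg = GeneFeatureTable(
        pd.DataFrame(mg_counts, index=feature_ids, columns=samples),
        pd.Series(lengths, index=feature_ids),
        "MG",
    )
    mt = GeneFeatureTable(
        pd.DataFrame(mt_counts, index=feature_ids, columns=samples),
        pd.Series(lengths, index=feature_ids),
        "MT",
    )

    lineages = {
        t: (
            f"d__Bacteria;p__P{(i % 5) + 1};c__C{(i % 7) + 1};o__O{(i % 9) + 1};"
            f"f__F{(i % 11) + 1};g__Genus_{t};s__Genus_{t} sp{i + 1}"
        )
        for i, t in enumerate(taxa)
    }
    ann = FeatureAnnotation.from_frame(
        pd.DataFrame(
            {
                "ko": [kos[k] for k in k_idx],
                "lineage": [lineages[taxa[t]] for t in t_idx],
            },
            index=feature_ids,
        )
    )
    meta = SampleMetadata(
        pd.DataFrame({"group": ["PD" if p else "HC" for p in is_pd]}, index=samples)
    )

    true_fc = pd.Series(0.0, index=kos)
    for m in modules:
        if affected[m]:
            true_fc[module_of == m] = np.log2(cfg.group_effect)
    carried_by_dropout = carriage[dropout_idx].any(axis=0) if dropout_idx.size else \
        np.zeros(cfg.n_ko, dtype=bool)
    tdge_down = pd.Series(
        carried_by_dropout & (cfg.p_drop > 0), index=kos, name="tdge_down"
    )
    truth = SyntheticTruth(
        gene_module=module_of,
        module_affected=affected,
        true_log2fc=true_fc,
        tdge_down=tdge_down,
        taxon_abundance=pd.DataFrame(abundance, index=taxa, columns=samples),
        carriage=pd.DataFrame(carriage, index=taxa, columns=kos),
        dropout_taxa=dropout,
    )
    return mg, mt, ann, meta, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative binomial with mean `mean` and size (shape) parameter."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-KO truth table for joining against pipeline outputs."""
    effect_sign = np.sign(truth.true_log2fc).astype(int)
    return pd.DataFrame(
        {
            "module": truth.gene_module,
            "effect_sign": effect_sign,
            "true_log2fc": truth.true_log2fc,
            "tdge_direction": np.where(truth.tdge_down, "down", "none"),
        },
        index=truth.gene_module.index,
    )


def synthetic_gene_sets(
    truth: SyntheticTruth,
    coverage: float = 0.6,
    n_random_sets: int = 10,
    random_set_size: int = 15,
    seed: int = 0,
) -> GeneSetCollection:
    """Pathway-like KO sets aligned with the planted modules.

    For each planted module a "pathway" containing `coverage` of its
    members is emitted, plus `n_random_sets` random KO sets; the
    remaining KOs stay unannotated, exercising the unannotated-gene
    accounting.
    """
    rng = np.random.default_rng(seed)
    kos = list(truth.gene_module.index)
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    for m in truth.module_affected.index:
        members = [k for k in kos if truth.gene_module[k] == m]
        n_take = max(1, int(round(coverage * len(members))))
        take = rng.choice(members, size=n_take, replace=False)
        sets[f"path_{m}"] = frozenset(take)
        desc[f"path_{m}"] = f"synthetic pathway aligned with module {m}"
    for i in range(n_random_sets):
        take = rng.choice(kos, size=min(random_set_size, len(kos)), replace=False)
        sets[f"path_rand{i + 1}"] = frozenset(take)
        desc[f"path_rand{i + 1}"] = "synthetic random pathway"
    return GeneSetCollection(sets, desc)
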