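"""End-to-end orchestration: one config, seeded stages, a run manifest.

Stages run in dependency order (simulate -> quantify -> taxa ->
network -> topology -> hubs -> diversity -> differential -> enrichment
-> crossfeeding), each writing TSV/JSON outputs into the run
directory. A single global seed is expanded into independent per-stage
substreams so toggling one stage never perturbs another's randomness.
Outputs are deterministic: the same config and seed produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossfeeding, differential, diversity, enrichment, hubs, io, network, quantify, simulate, taxa, topology

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "quantify", "taxa", "network", "topology", "hubs",
    "diversity", "differential", "enrichment", "crossfeeding",
)


class ConfigError(ValueError):
    """Invalid or unknown run configuration keys."""


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run.

    Defaults follow the analysis conventions: 50% prevalence,
    minimum module size 20, eigengene merge threshold 0.18, automatic
    soft power at scale-free fit 0.9, 95th-percentile and 10% hub
    rules, alpha 0.05.
    """

    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # mg/mt/annotation/metadata/gene_sets paths
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    min_prevalence: float = 0.5
    ratio_pseudocount: float = 0.0
    rank: str = "genus"
    power: int | None = None
    powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_cut: float = 0.9
    min_module_size: int = 20
    merge_dissim: float = 0.18
    edge_threshold: float = 0.01
    edge_export_threshold: float = 0.1
    hub_percentile: float = 95.0
    imodule_fraction: float = 0.10
    alpha: float = 0.05
    n_perm_gsea: int = 499
    n_perm_ordination: int = 199
    gsea_min_size: int = 5
    processes: dict = field(default_factory=dict)
    selected_genera: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        if not 0 < cfg.min_prevalence <= 1:
            raise ConfigError("min_prevalence must lie in (0, 1]")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[idx]
        return int(child.generate_state(1)[0] % (2**31))


class PipelineRun:
    """Holds in-memory state while stages execute and writes outputs."""

    def __init__(self, config: RunConfig, outdir) -> None:
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.row_counts: dict[str, dict] = {}

    # ---- data access -------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def _write(self, df: pd.DataFrame, name: str, stage: str,
               index_label: str | None = None) -> None:
        df.to_csv(self.path(name), sep="\t", index_label=index_label,
                  float_format="%.10g")
        self.row_counts.setdefault(stage, {})[name] = int(len(df))

    # ---- stages ------------------------------------------------------
    def run_simulate(self) -> None:
        cfg = self.config
        syn_kwargs = dict(cfg.synthetic)
        syn_kwargs.setdefault("seed", cfg.stage_seed("simulate"))
        syn = simulate.SyntheticConfig(**syn_kwargs)
        mg, mt, ann, meta, truth = simulate.generate(syn)
        io.write_counts(mg, self.path("mg.tsv"))
        io.write_counts(mt, self.path("mt.tsv"))
        io.write_annotation(ann, self.path("annotation.tsv"))
        io.write_metadata(meta, self.path("metadata.tsv"))
        report = simulate.truth_report(truth)
        self._write(report, "truth.tsv", "simulate", index_label="ko")
        sets = simulate.synthetic_gene_sets(truth, seed=syn.seed)
        io.write_gene_sets(sets, self.path("gene_sets.gmt"))
        self.state.update(mg=mg, mt=mt, annotation=ann, metadata=meta,
                          truth=truth, gene_sets=sets)
        self.row_counts.setdefault("simulate", {})["features"] = len(mg.features)

    def load_inputs(self) -> None:
        paths = self.config.inputs
        mg = io.read_counts(paths["mg"], "MG")
        mt = io.read_counts(paths["mt"], "MT")
        meta = io.read_metadata(paths["metadata"])
        ann = io.read_annotation(paths["annotation"])
        mg, mt, meta = io.align_samples(mg, mt, meta)
        sets = io.read_gene_sets(paths["gene_sets"]) if "gene_sets" in paths else \
            io.GeneSetCollection({})
        self.state.update(mg=mg, mt=mt, annotation=ann, metadata=meta,
                          gene_sets=sets)

    def run_quantify(self) -> None:
        cfg = self.config
        mg, mt, ann = self.state["mg"], self.state["mt"], self.state["annotation"]
        mg_tpm = quantify.aggregate_tpm(quantify.tpm(mg), ann, by="ko")
        mt_tpm = quantify.aggregate_tpm(quantify.tpm(mt), ann, by="ko")
        act = quantify.mta_ratio(mt_tpm, mg_tpm, cfg.ratio_pseudocount)
        filtered, kept, dropped = quantify.prevalence_filter(act, cfg.min_prevalence)
        # the network input must be complete; residual missing entries
        # (MT>0/MG=0 in a retained gene) are rare mapping artifacts -> 0
        filled = quantify.ActivityMatrix(
            filtered.values.fillna(0.0), filtered.state, filtered.key,
            dict(filtered.report),
        )
        expr = quantify.power_transform(filled)
        clr_mat = quantify.clr_activity(filled)
        summary = quantify.prevalence_summary(act, self.state["metadata"])
        self._write(act.values, "activity.tsv", "quantify", index_label="ko")
        self._write(filled.values, "activity_filtered.tsv", "quantify",
                    index_label="ko")
        self._write(expr.values, "expression_transformed.tsv", "quantify",
                    index_label="ko")
        self._write(clr_mat.values, "activity_clr.tsv", "quantify",
                    index_label="ko")
        with open(self.path("quantify_summary.json"), "w") as fh:
            json.dump({
                "n_features": len(act.features),
                "n_kept": len(kept),
                "n_dropped": len(dropped),
                "n_undefined_ratio": act.report.get("n_undefined", 0),
                "n_shared_50pct": summary["n_shared_50pct"],
                "n_shared_all": summary["n_shared_all"],
            }, fh, indent=2, sort_keys=True)
        self.state.update(activity=filled, expression=expr, clr=clr_mat)

    def run_taxa(self) -> None:
        cfg = self.config
        mg, mt, ann = self.state["mg"], self.state["mt"], self.state["annotation"]
        meta = self.state["metadata"]
        tensor = taxa.build_tensor(mg, mt, ann, rank=cfg.rank)
        self._write(tensor.long, "tensor.tsv", "taxa")
        taxon_act = taxa.taxon_activity(mg, mt, ann, rank=cfg.rank)
        dm = taxa.differential_mta(taxon_act, meta, cfg.min_prevalence)
        self._write(dm, "differential_mta.tsv", "taxa", index_label="taxon")
        ord_res = taxa.ordinate_and_fit(
            self.state["clr"].values, meta, n_perm=cfg.n_perm_ordination,
            seed=cfg.stage_seed("taxa"),
        )
        self._write(ord_res["scores"], "ordination_scores.tsv", "taxa",
                    index_label="sample")
        with open(self.path("ordination.json"), "w") as fh:
            json.dump({"r2": ord_res["r2"], "p": ord_res["p"],
                       "n_perm": ord_res["n_perm"]}, fh, indent=2, sort_keys=True)
        self.state["tensor"] = tensor

    def run_network(self) -> None:
        cfg = self.config
        expr = self.state["expression"].values
        net = network.build_network(expr, power=cfg.power, powers=cfg.powers,
                                    r2_cut=cfg.r2_cut)
        partition = network.cut_modules(net, expr,
                                        min_module_size=cfg.min_module_size,
                                        medissthres=cfg.merge_dissim)
        trait = network.module_trait(partition, self.state["metadata"],
                                     alpha=cfg.alpha)
        self._write(net.sft_table, "sft_table.tsv", "network")
        io.write_modules(partition.labels, self.path("modules.tsv"))
        self._write(partition.eigengenes, "eigengenes.tsv", "network",
                    index_label="sample")
        self._write(trait, "trait_stats.tsv", "network", index_label="module")
        io.write_network(net, partition, self.path("network"),
                         threshold=cfg.edge_export_threshold)
        self.state.update(network=net, partition=partition, trait_stats=trait)

    def run_topology(self) -> None:
        cfg = self.config
        topo = topology.topology_table(
            self.state["network"], self.state["partition"],
            self.state["activity"], edge_threshold=cfg.edge_threshold,
        )
        self._write(topo, "topology.tsv", "topology", index_label="module")
        tests = topology.compare_by_trait(topo)
        self._write(tests, "topology_trait_tests.tsv", "topology",
                    index_label="metric")
        if len(topo) >= 4:
            cors = topology.diversity_metric_correlations(topo)
            self._write(cors, "topology_diversity_correlations.tsv", "topology",
                        index_label="metric")
        self.state["topology"] = topo

    def run_hubs(self) -> None:
        cfg = self.config
        net, part, trait = (self.state["network"], self.state["partition"],
                            self.state["trait_stats"])
        p95 = hubs.select_p95(net, part, trait, percentile=cfg.hub_percentile)
        imod = hubs.select_imodule(net, part, trait, fraction=cfg.imodule_fraction)
        allhubs = pd.concat([p95, imod], ignore_index=True)
        self._write(allhubs, "hubs.tsv", "hubs")
        profile = hubs.hub_pathway_profile(imod, self.state["gene_sets"])
        self._write(profile, "hub_pathways.tsv", "hubs")
        self.state.update(hubs_p95=p95, hubs_imodule=imod)

    def run_diversity(self) -> None:
        meta = self.state["metadata"]
        tensor = self.state["tensor"]
        tdge_df = diversity.tdge_table(tensor)
        self._write(tdge_df, "tdge.tsv", "diversity", index_label="ko")
        ihub = self.state.get("hubs_imodule")
        ihub_genes = list(ihub["gene"]) if ihub is not None and len(ihub) else []
        cmp = diversity.tdge_group_compare(tdge_df, meta, ihub_genes)
        self._write(cmp["per_gene"], "tdge_per_gene.tsv", "diversity",
                    index_label="ko")
        fr = diversity.functional_redundancy_table(tensor, meta)
        self._write(fr, "functional_redundancy.tsv", "diversity",
                    index_label="sample")
        gdiv = diversity.genus_expression_diversity(
            tensor, meta, self.config.selected_genera or None)
        self._write(gdiv["table"], "genus_diversity.tsv", "diversity")
        self._write(gdiv["tests"], "genus_diversity_tests.tsv", "diversity")
        with open(self.path("diversity_tests.json"), "w") as fh:
            json.dump({
                "tdge": cmp["distribution_tests"],
                "fr_hc_vs_pd_p": diversity.fr_group_compare(fr),
            }, fh, indent=2, sort_keys=True)
        self.state.update(tdge=tdge_df, tdge_compare=cmp, fr=fr)

    def run_differential(self) -> None:
        de = differential.differential_expression(self.state["activity"],
                                                  self.state["metadata"])
        self._write(de, "de.tsv", "differential", index_label="ko")
        cmp = self.state.get("tdge_compare")
        if cmp is not None:
            joint = differential.joint_classification(
                de, cmp["per_gene"]["log2fc_tdge"],
                hub_genes=list(self.state.get("hubs_imodule", pd.DataFrame(
                    columns=["gene"]))["gene"]),
            )
            self._write(joint["counts"], "joint_counts.tsv", "differential")
            self.state["joint"] = joint
        self.state["de"] = de

    def run_enrichment(self) -> None:
        cfg = self.config
        sets = self.state["gene_sets"]
        expr = self.state["expression"].values
        gsea = enrichment.module_enrichment(
            expr, self.state["partition"], sets, n_perm=cfg.n_perm_gsea,
            min_size=cfg.gsea_min_size, seed=cfg.stage_seed("enrichment"),
        )
        self._write(gsea, "gsea.tsv", "enrichment")
        acct = enrichment.unannotated_accounting(self.state["partition"], sets)
        self._write(acct["table"], "unannotated.tsv", "enrichment",
                    index_label="module")
        self.state["gsea"] = gsea

    def run_crossfeeding(self) -> None:
        cfg = self.config
        tensor = self.state["tensor"]
        sets = self.state["gene_sets"]
        if cfg.processes:
            lists = crossfeeding.ProcessGeneLists(
                {k: list(v) for k, v in cfg.processes.items()},
                cfg.selected_genera,
            )
        elif len(sets) >= 2:
            names = list(sets.sets)[:2]
            lists = crossfeeding.ProcessGeneLists(
                {n: sorted(sets.sets[n]) for n in names}, cfg.selected_genera)
        else:
            logger.warning("no process lists configured: crossfeeding skipped")
            return
        expr = tensor.marginal_ko()
        blocks = crossfeeding.process_blocks(expr, lists)
        names = list(lists.processes)
        res = crossfeeding.block_correlations(blocks[names[0]], blocks[names[1]])
        self._write(res["pairs"], "crossfeeding_correlations.tsv", "crossfeeding")
        sums = crossfeeding.process_sums(tensor, lists)
        self._write(sums, "process_sums.tsv", "crossfeeding")
        with open(self.path("crossfeeding_counts.json"), "w") as fh:
            json.dump(res["counts"], fh, indent=2, sort_keys=True)
        self.state["crossfeeding"] = res


_STAGE_OUTPUTS = {
    "simulate": ["mg.tsv", "mt.tsv", "annotation.tsv", "metadata.tsv", "truth.tsv"],
    "quantify": ["activity.tsv", "expression_transformed.tsv", "activity_clr.tsv"],
    "taxa": ["tensor.tsv", "differential_mta.tsv", "ordination.json"],
    "network": ["modules.tsv", "eigengenes.tsv", "trait_stats.tsv", "sft_table.tsv"],
    "topology": ["topology.tsv"],
    "hubs": ["hubs.tsv"],
    "diversity": ["tdge.tsv", "functional_redundancy.tsv"],
    "differential": ["de.tsv"],
    "enrichment": ["gsea.tsv", "unannotated.tsv"],
    "crossfeeding": ["process_sums.tsv"],
}


def run_all(config: RunConfig, outdir, force: bool = True) -> Path:
    """Execute every enabled stage in dependency order.

    With ``force=False`` a stage whose outputs already exist is
    skipped, but its in-memory state is still rebuilt when later
    stages need it. A manifest (config hash, seed, versions, per-stage
    row counts) is written last; stage failure halts the run with the
    stage name in the raised error.
    """
    run = PipelineRun(config, outdir)
    enabled = [s for s in STAGES if s in config.stages]
    if "simulate" not in enabled:
        run.load_inputs()
    for stage in enabled:
        outputs = [run.path(n) for n in _STAGE_OUTPUTS.get(stage, [])]
        if not force and outputs and all(p.exists() for p in outputs):
            logger.info("stage %s: outputs present, recomputing state only", stage)
        try:
            getattr(run, f"run_{stage}")()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    from . import __version__

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": enabled,
        "row_counts": run.row_counts,
    }
    with open(run.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return run.outdir
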