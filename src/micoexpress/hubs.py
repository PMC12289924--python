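"""Hub-gene selection from trait-associated modules.

Two definitions are used: (1) "p95" hubs — genes of HC- or PD-
associated modules whose whole-network connectivity reaches the 95th
percentile of the pooled connectivity distribution (type-7 linear
interpolation quantile); (2) intramodular "iHub" genes — the top 10%
of genes per trait-associated module ranked by within-module
connectivity (kWithin), with deterministic id-order tie-breaking.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .network import CoexpressionNetwork, ModulePartition, intramodular_connectivity


def _trait_modules(trait_stats: pd.DataFrame) -> list[str]:
    return list(trait_stats.index[trait_stats["trait_class"].isin(["HC", "PD"])])


def select_p95(net: CoexpressionNetwork, partition: ModulePartition,
               trait_stats: pd.DataFrame, percentile: float = 95.0) -> pd.DataFrame:
    """Pooled 95th-percentile hubs across trait-associated modules.

    The pool is every gene of every trait-associated module; the
    threshold is the type-7 empirical `percentile` of their kTotal; any
    pool gene at or above it is a hub. Counts per trait class are in
    the result's ``trait_class`` column.
    """
    modules = _trait_modules(trait_stats)
    if not modules:
        warnings.warn("no trait-associated module: empty hub set", stacklevel=2)
        return _empty_hubs()
    pool = [g for m in modules for g in partition.genes_in(m)]
    k = net.connectivity().loc[pool]
    threshold = float(np.quantile(k.to_numpy(), percentile / 100.0))
    if k.nunique() == 1:
        warnings.warn("all pool connectivities equal: every gene selected",
                      stacklevel=2)
    hubs = k[k >= threshold]
    out = pd.DataFrame(
        {
            "gene": hubs.index,
            "hub_type": "p95",
            "module": partition.labels.loc[hubs.index].to_numpy(),
            "connectivity": hubs.to_numpy(),
            "connectivity_basis": "kTotal",
        }
    )
    out["trait_class"] = trait_stats["trait_class"].reindex(out["module"]).to_numpy()
    out.attrs["threshold"] = threshold
    return out.sort_values("gene").reset_index(drop=True)


def select_imodule(net: CoexpressionNetwork, partition: ModulePartition,
                   trait_stats: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Top `fraction` most intramodularly connected genes per trait module.

    Exactly ceil(fraction x size) genes per module; ties at the cut are
    broken by gene id order so reruns are identical.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    modules = _trait_modules(trait_stats)
    if not modules:
        return _empty_hubs()
    k_within = intramodular_connectivity(net, partition)
    frames = []
    for m in modules:
        genes = partition.genes_in(m)
        n_take = math.ceil(fraction * len(genes))
        ranked = k_within.loc[genes].rename("connectivity").to_frame()
        ranked.index.name = "gene"
        ranked = ranked.reset_index().sort_values(
            ["connectivity", "gene"], ascending=[False, True], kind="mergesort"
        )
        top = ranked.head(n_take).copy()
        top["hub_type"] = "imodule"
        top["module"] = m
        top["connectivity_basis"] = "kWithin"
        top["trait_class"] = trait_stats.loc[m, "trait_class"]
        frames.append(top)
    out = pd.concat(frames, ignore_index=True)
    return out[["gene", "hub_type", "module", "connectivity",
                "connectivity_basis", "trait_class"]]


def _empty_hubs() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene", "hub_type", "module", "connectivity",
                                 "connectivity_basis", "trait_class"])


def hub_pathway_profile(hubs: pd.DataFrame,
                        sets: GeneSetCollection) -> pd.DataFrame:
    """Pathway composition of a hub set, per (module, pathway).

    A hub in several pathways counts once per pathway; hubs in no
    pathway fall into the "unannotated" bin. Proportions are within
    each module's hub count.
    """
    rows = []
    if hubs.empty:
        return pd.DataFrame(columns=["module", "pathway", "count", "proportion"])
    for m, sub in hubs.groupby("module"):
        total = len(sub)
        counts: dict[str, int] = {}
        unannotated = 0
        for gene in sub["gene"]:
            pathways = sets.members_of(gene) if len(sets) else []
            if not pathways:
                unannotated += 1
            for p in pathways:
                counts[p] = counts.get(p, 0) + 1
        for p, c in sorted(counts.items()):
            rows.append({"module": m, "pathway": p, "count": c,
                         "proportion": c / total})
        rows.append({"module": m, "pathway": "unannotated",
                     "count": unannotated, "proportion": unannotated / total})
    return pd.DataFrame(rows)
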