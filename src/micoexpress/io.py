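"""Reading, writing and validation of the pipeline's tabular formats.

Count tables follow the featureCounts dialect: a TSV whose first column
is the feature id, a ``Length`` column (case-insensitive), optional
positional columns (Chr/Start/End/Strand, ignored), and one count
column per sample. Annotations, metadata and result tables are plain
TSV; gene sets are GMT; networks are exported as weighted edge lists
and optionally GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_IGNORED_COLUMNS = {"chr", "start", "end", "strand", "geneid"}
_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """The file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """The file parsed, but its content violates a domain invariant."""


class AlignmentError(ValueError):
    """Feature or sample indices that must match do not."""


@dataclass
class GeneFeatureTable:
    """Gene-level counts for one omic layer (MG or MT).

    counts : features x samples non-negative integer matrix
    lengths : feature length in base pairs, aligned to counts.index
    layer : "MG" or "MT"
    """

    counts: pd.DataFrame
    lengths: pd.Series
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in ("MG", "MT"):
            raise ValidationError(f"unknown omic layer {self.layer!r}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dups)[:5]}")
        if (self.lengths < 1).any():
            raise ValidationError("feature lengths must be >= 1 bp")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValidationError("length missing for some features")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class FeatureAnnotation:
    """feature_id -> KO id and taxonomic lineage (genus/species derived)."""

    table: pd.DataFrame  # index feature_id; columns ko, lineage, genus, species

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureAnnotation":
        df = df.copy()
        if df.index.duplicated().any():
            raise ValidationError("duplicate feature ids in annotation")
        if "genus" not in df.columns or "species" not in df.columns:
            parsed = df["lineage"].map(parse_lineage)
            df["genus"] = [p.get("genus") for p in parsed]
            df["species"] = [p.get("species") for p in parsed]
        return cls(df)

    def taxon_at(self, rank: str) -> pd.Series:
        """Taxon label per feature at `rank`; missing labels -> 'unclassified'."""
        if rank not in ("genus", "species"):
            raise ValueError(f"rank must be genus or species, got {rank!r}")
        col = self.table[rank]
        return col.where(col.notna() & (col != ""), "unclassified")


@dataclass
class SampleMetadata:
    """Per-sample phenotype (group in {HC, PD}) and optional covariates."""

    table: pd.DataFrame  # index sample_id; column "group" plus covariates

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        bad = set(self.table["group"].unique()) - {"HC", "PD"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)


@dataclass
class GeneSetCollection:
    """Named KO gene sets (GMT semantics): set -> members, description."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members_of(self, gene: str) -> list[str]:
        return [name for name, m in self.sets.items() if gene in m]

    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.sets.values():
            out |= m
        return frozenset(out)


def parse_lineage(lineage) -> dict[str, str]:
    """Parse a semicolon-separated lineage into rank -> name.

    Accepts GTDB-style prefixed ranks ("d__Bacteria;...;s__B. obeum")
    and plain rank-by-position strings; prefixes are stripped.
    """
    out: dict[str, str] = {}
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return out
    parts = [p.strip() for p in str(lineage).split(";")]
    for i, part in enumerate(parts):
        if not part:
            continue
        rank = None
        name = part
        for j, pref in enumerate(_GTDB_PREFIXES):
            if part.startswith(pref):
                rank = _RANKS[j]
                name = part[len(pref):].strip()
                break
        if rank is None:
            if i < len(_RANKS):
                rank = _RANKS[i]
        if rank and name:
            out[rank] = name
    return out


def read_counts(path, layer: str) -> GeneFeatureTable:
    """Read a featureCounts-style TSV into a validated GeneFeatureTable."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise FormatError(f"{path}: no feature rows or sample columns")
    df = df.set_index(df.columns[0])
    length_col = None
    keep = []
    for col in df.columns:
        low = col.strip().lower()
        if low == "length":
            length_col = col
        elif low in _IGNORED_COLUMNS:
            continue
        else:
            keep.append(col)
    if length_col is None:
        raise FormatError(f"{path}: missing Length column")
    if not keep:
        raise FormatError(f"{path}: no sample columns")
    lengths = pd.to_numeric(df[length_col], errors="coerce")
    if lengths.isna().any():
        raise ValidationError(f"{path}: non-numeric lengths")
    counts = df[keep].apply(pd.to_numeric, errors="coerce")
    if counts.isna().any().any():
        raise ValidationError(f"{path}: non-numeric counts")
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError(f"{path}: non-integer counts")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique()[0]
        raise ValidationError(f"{path}: duplicate feature id {dup!r}")
    counts = counts.astype(np.int64)
    counts.index.name = None
    return GeneFeatureTable(counts, lengths.astype(np.int64).rename(None), layer)


def write_counts(table: GeneFeatureTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "Length", table.lengths)
    out.index.name = "Geneid"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> FeatureAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "ko" not in df.columns or "lineage" not in df.columns:
        raise FormatError(f"{path}: annotation needs 'ko' and 'lineage' columns")
    return FeatureAnnotation.from_frame(df)


def write_annotation(ann: FeatureAnnotation, path) -> None:
    out = ann.table.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "group" not in df.columns:
        raise FormatError(f"{path}: metadata needs a 'group' column")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name TAB description TAB member..."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with < 3 fields")
            name, description, *members = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            member_set = frozenset(m for m in members if m)
            if not member_set:
                raise ValidationError(f"{path}:{lineno}: empty member list")
            sets[name] = member_set
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gene_sets(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.sets.items():
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def align_samples(mg: GeneFeatureTable, mt: GeneFeatureTable,
                  meta: SampleMetadata):
    """Intersect samples across MG, MT and metadata; log every dropped id.

    The MT/MG ratio requires paired layers, so the intersection (never
    the union) is the analysis sample set.
    """
    shared = [s for s in mg.samples if s in set(mt.samples) and s in set(meta.samples)]
    if not shared:
        raise AlignmentError("no samples shared across MG, MT and metadata")
    for name, tab in (("MG", mg.samples), ("MT", mt.samples), ("metadata", meta.samples)):
        for s in tab:
            if s not in shared:
                logger.warning("sample %r dropped: absent from intersection (%s)", s, name)
    mg2 = GeneFeatureTable(mg.counts[shared], mg.lengths, mg.layer)
    mt2 = GeneFeatureTable(mt.counts[shared], mt.lengths, mt.layer)
    meta2 = SampleMetadata(meta.table.loc[shared])
    return mg2, mt2, meta2


def write_network(net, partition, prefix, threshold: float = 0.0,
                  graphml: bool = False) -> None:
    """Export a co-expression network as edge list (+ nodes, modules).

    Writes ``<prefix>.edges.tsv`` (undirected weighted edges with
    adjacency weight > `threshold`), ``<prefix>.nodes.tsv`` and, when a
    partition is given, ``<prefix>.modules.tsv``.
    """
    prefix = Path(prefix)
    genes = list(net.genes)
    adj = np.asarray(net.adjacency)
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            w = adj[i, j]
            if w > threshold:
                rows.append((genes[i], genes[j], w))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        f"{prefix}.edges.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene": genes}).to_csv(f"{prefix}.nodes.tsv", sep="\t", index=False)
    if partition is not None:
        write_modules(partition.labels, f"{prefix}.modules.tsv")
    if graphml:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(genes)
        g.add_weighted_edges_from(rows)
        nx.write_graphml(g, f"{prefix}.graphml")


def write_modules(labels: pd.Series, path) -> None:
    out = labels.rename("module").to_frame()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_modules(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df["module"]
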