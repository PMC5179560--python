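"""Readers, writers, and validated in-memory containers for every pipeline file.

Formats are deliberately plain: tab-separated count matrices (features x
samples), a CSV sample design table, a normalized miR-target prediction TSV,
GMT gene-set collections, and SIF / GraphML / edge-TSV network exports for
Cytoscape-style viewers.  Identifiers are case-sensitive opaque strings; no
symbol remapping is performed.  Readers validate strictly and report file
coordinates on rejection; every reader/writer pair round-trips losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
CONDITIONS = ("stress", "control")
ESTROUS_STAGES = ("estrus", "proestrus", "metestrus", "diestrus", "not_applicable")
ASSAYS = ("miR", "mRNA")


class FormatError(ValueError):
    """A file violated the expected schema; message carries file coordinates."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative integer feature x sample read-count table.

    Parameters
    ----------
    feature_ids : ordered unique feature identifiers (rows).
    sample_ids : ordered unique sample identifiers (columns).
    counts : 2-D integer array, shape ``(n_features, n_samples)``.
    assay : ``"miR"`` or ``"mRNA"``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    assay: str

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if self.assay not in ASSAYS:
            raise FormatError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"count array shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at feature {self.feature_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: Sequence[str]) -> "CountMatrix":
        """Row subset preserving this matrix's feature order."""
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return CountMatrix(
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.counts[idx, :],
            self.assay,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.assay == other.assay
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleDesign:
    """Per-library experimental design: sex, condition, estrous stage, pool size.

    Each library is a pool of ``pool_size`` animals.  Males carry estrous
    ``not_applicable``; every sex x condition cell must be non-empty.
    """

    table: pd.DataFrame  # columns: sample_id, sex, condition, estrous, pool_size

    REQUIRED = ("sample_id", "sex", "condition", "estrous", "pool_size")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        _check_unique(list(df["sample_id"]), "sample id")
        for row_i, row in df.iterrows():
            where = f"design row {row_i + 1} (sample {row['sample_id']!r})"
            if row["sex"] not in SEXES:
                raise FormatError(f"{where}: unknown sex {row['sex']!r}")
            if row["condition"] not in CONDITIONS:
                raise FormatError(f"{where}: unknown condition {row['condition']!r}")
            if row["estrous"] not in ESTROUS_STAGES:
                raise FormatError(f"{where}: unknown estrous stage {row['estrous']!r}")
            if row["sex"] == "male" and row["estrous"] != "not_applicable":
                raise FormatError(
                    f"{where}: male sample with estrous stage {row['estrous']!r}"
                )
            if int(row["pool_size"]) < 1:
                raise FormatError(f"{where}: pool_size must be positive")
        for sex in SEXES:
            for cond in CONDITIONS:
                n = int(((df["sex"] == sex) & (df["condition"] == cond)).sum())
                if n == 0:
                    raise FormatError(f"empty cell: no samples for {sex}/{cond}")
        df["pool_size"] = df["pool_size"].astype(int)
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in_cell(self, sex: str, condition: str) -> list[str]:
        mask = (self.table["sex"] == sex) & (self.table["condition"] == condition)
        return list(self.table.loc[mask, "sample_id"])

    def group_labels(self) -> pd.Series:
        """Group label ``<sex>.<condition>`` per sample, indexed by sample_id."""
        lab = self.table["sex"] + "." + self.table["condition"]
        return pd.Series(lab.values, index=self.table["sample_id"].values)

    def check_matches(self, counts: CountMatrix) -> None:
        if self.sample_ids != counts.sample_ids:
            raise FormatError(
                "design sample ids do not match count matrix sample ids: "
                f"{self.sample_ids} vs {counts.sample_ids}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleDesign):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass
class TargetPredictionTable:
    """Normalized miR-target prediction records: (mir_id, gene_id, source).

    Triples are unique; duplicates in input files are collapsed with a logged
    warning.  Downstream intersection requires >= 2 distinct sources.
    """

    records: pd.DataFrame  # columns: mir_id, gene_id, source

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in ("mir_id", "gene_id", "source") if c not in df.columns]
        if missing:
            raise FormatError(f"target table missing columns: {missing}")
        df = df.loc[:, ["mir_id", "gene_id", "source"]].reset_index(drop=True)
        n_before = len(df)
        df = df.drop_duplicates().reset_index(drop=True)
        if len(df) < n_before:
            logger.warning(
                "collapsed %d duplicate (mir, gene, source) triples", n_before - len(df)
            )
        self.records = df

    @property
    def sources(self) -> list[str]:
        return sorted(self.records["source"].unique())

    def targets_by_source(self, source: str) -> dict[str, set[str]]:
        sub = self.records[self.records["source"] == source]
        out: dict[str, set[str]] = {}
        for mir, grp in sub.groupby("mir_id"):
            out[mir] = set(grp["gene_id"])
        return out

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetPredictionTable):
            return NotImplemented
        a = self.records.sort_values(["mir_id", "gene_id", "source"]).reset_index(drop=True)
        b = other.records.sort_values(["mir_id", "gene_id", "source"]).reset_index(drop=True)
        return a.equals(b)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        self.descriptions = {n: self.descriptions.get(n, "") for n in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path, assay: str) -> CountMatrix:
    """Read a feature x sample count TSV (header = sample ids, col 0 = features)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    try:
        _check_unique(header, "sample id")
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    sample_ids = header
    feature_ids = [str(i) for i in df.index]
    counts = np.empty(df.shape, dtype=np.int64)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = values[i, j]
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at row {i + 2} "
                    f"(feature {feature_ids[i]!r}), column {sample_ids[j]!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative count {v} at row {i + 2} "
                    f"(feature {feature_ids[i]!r}), column {sample_ids[j]!r}"
                )
            counts[i, j] = v
    try:
        return CountMatrix(feature_ids, sample_ids, counts, assay)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_design(path: str | Path) -> SampleDesign:
    """Read the sample design CSV (sample_id, sex, condition, estrous, pool_size)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "sex": str, "condition": str, "estrous": str})
    try:
        return SampleDesign(df)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def read_target_predictions(path: str | Path) -> TargetPredictionTable:
    """Read a miR-target prediction TSV with columns mir_id, gene_id, source."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    try:
        return TargetPredictionTable(df)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_target_predictions(table: TargetPredictionTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member TAB member ..."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: gene set {parts[0]!r} has an empty member list"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise FormatError(
                    f"{path}:{lineno}: gene set {name!r} has an empty member list"
                )
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            members = sorted(collection.sets[name])
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

SIF_RELATIONS = {"negative": "represses", "positive": "coexpressed"}
NETWORK_FORMATS = ("SIF", "GraphML", "edge-TSV")


def write_network(network, path: str | Path, format: str = "edge-TSV") -> None:
    """Export a bipartite miR-gene network.

    SIF writes ``mir <relation> gene`` lines ("represses" for negative
    association, "coexpressed" for positive).  GraphML carries node attributes
    (kind, direction, log2FC) and the edge association sign.  edge-TSV is the
    lossless dialect read back by :func:`read_network_edges`.
    """
    path = Path(path)
    if format == "SIF":
        with open(path, "w", encoding="utf-8") as fh:
            for mir, gene, assoc in network.iter_edges():
                fh.write(f"{mir}\t{SIF_RELATIONS[assoc]}\t{gene}\n")
    elif format == "GraphML":
        _write_graphml(network, path)
    elif format == "edge-TSV":
        rows = [
            {
                "mir_id": mir,
                "gene_id": gene,
                "association": assoc,
                "mir_direction": network.mir_nodes[mir][0],
                "mir_log2fc": network.mir_nodes[mir][1],
                "gene_direction": network.gene_nodes[gene][0],
                "gene_log2fc": network.gene_nodes[gene][1],
            }
            for mir, gene, assoc in network.iter_edges()
        ]
        header = [
            "mir_id", "gene_id", "association",
            "mir_direction", "mir_log2fc", "gene_direction", "gene_log2fc",
        ]
        write_table(rows, path, columns=header)
    else:
        raise FormatError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )


def _write_graphml(network, path: Path) -> None:
    g = nx_graph(network)
    import networkx as nx

    nx.write_graphml(g, path, named_key_ids=True)


def nx_graph(network):
    """The network as a networkx Graph with node/edge attributes."""
    import networkx as nx

    g = nx.Graph()
    for mir, (direction, lfc) in network.mir_nodes.items():
        g.add_node(mir, kind="miR", direction=direction, log2fc=float(lfc))
    for gene, (direction, lfc) in network.gene_nodes.items():
        g.add_node(gene, kind="gene", direction=direction, log2fc=float(lfc))
    for mir, gene, assoc in network.iter_edges():
        g.add_edge(mir, gene, association=assoc)
    return g


def read_network_graphml(path: str | Path):
    """Re-parse a GraphML export into (node attrs, edge set) for round-trips."""
    import networkx as nx

    g = nx.read_graphml(path)
    edges = {(u, v, d["association"]) for u, v, d in g.edges(data=True)}
    return g, edges


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------


def write_table(
    rows: Iterable[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write rows as a TSV with a deterministic column order."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
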