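"""Reading and writing expression matrices and identifier mapping tables.

Expression matrices are tab-delimited text: a header row of sample
identifiers, one row per gene (or probeset), with the identifier in the
first column. Mapping tables are two-column tab-delimited files
(source identifier, target identifier). Gzipped files (``.gz``) are read
transparently. Gene identifiers are treated as opaque strings; nothing is
validated against an external database.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MappingTable",
    "ReadReport",
    "CollapseReport",
    "HierarchicalMapping",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_mapping_table",
    "collapse_probesets",
    "map_identifiers_hierarchical",
]


@dataclass
class ExpressionMatrix:
    """A genes-by-samples matrix of (log-scale) expression values.

    Parameters
    ----------
    gene_ids
        Ordered, unique row identifiers (genes or probesets), length ``m``.
    sample_ids
        Ordered, unique column identifiers, length ``n``.
    values
        ``m x n`` float array with no missing entries.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row_index(self, gene_ids) -> np.ndarray:
        """Row positions of ``gene_ids``; raises KeyError naming any absentee."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        rows = []
        for g in gene_ids:
            if g not in lookup:
                raise KeyError(f"gene {g!r} not present in matrix")
            rows.append(lookup[g])
        return np.asarray(rows, dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy(float))


@dataclass
class MappingTable:
    """A many-to-one source -> target identifier mapping with provenance.

    A source id may appear at most once; tables where a source maps to two
    different targets are malformed and rejected at construction.
    """

    mapping: dict
    name: str = "mapping"
    priority: int = 0

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)

    def __contains__(self, source) -> bool:
        return source in self.mapping

    def __getitem__(self, source):
        return self.mapping[source]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class ReadReport:
    """Rows rejected while loading a matrix (unparseable or missing cells)."""

    path: str
    n_rows_read: int
    rejected_rows: list = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_rows)


@dataclass
class CollapseReport:
    """Accounting for a probeset-to-gene collapse."""

    n_probes_in: int
    n_genes_out: int
    unmapped_probes: list = field(default_factory=list)

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped_probes)


@dataclass
class HierarchicalMapping:
    """Result of applying an ordered hierarchy of mapping tables.

    ``mapping`` is source -> target for every id resolved by some table;
    ``table_used`` records which table supplied each mapping; ``counts``
    is per-table usage; ``unmapped`` lists ids absent from every table.
    """

    mapping: dict
    table_used: dict
    counts: dict
    unmapped: list


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression_matrix(
    path,
    delimiter: str = "\t",
    id_column: str | int = 0,
) -> tuple[ExpressionMatrix, ReadReport]:
    """Load a delimited expression matrix.

    The first row must be a header of sample identifiers; ``id_column``
    names (or indexes) the gene-identifier column. Rows containing any
    value that cannot be parsed as a finite number are rejected and listed
    in the returned :class:`ReadReport` rather than imputed.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On a duplicated sample header, fewer than 2 samples, or fewer than
        2 parseable gene rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    # pandas mangles duplicated header fields; check the raw header first
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\r\n").split(delimiter)
    if isinstance(id_column, int):
        raw_samples = [c for i, c in enumerate(header) if i != id_column]
    else:
        raw_samples = [c for c in header if c != id_column]
    dup = _first_duplicate(raw_samples)
    if dup is not None:
        raise ValueError(f"duplicate sample identifier in header: {dup!r}")
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if isinstance(id_column, int):
        id_name = df.columns[id_column]
    else:
        id_name = id_column
        if id_name not in df.columns:
            raise ValueError(f"id column {id_name!r} not in header")
    sample_ids = [c for c in df.columns if c != id_name]
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise ValueError(f"duplicate sample identifier in header: {dup!r}")
    if len(sample_ids) < 2:
        raise ValueError(f"need at least 2 samples, found {len(sample_ids)}")

    gene_ids = df[id_name].to_numpy(object)
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    numeric = df[sample_ids].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = ~np.isfinite(numeric).all(axis=1)
    report = ReadReport(
        path=str(path),
        n_rows_read=len(df),
        rejected_rows=list(gene_ids[bad]),
    )
    if (~bad).sum() < 2:
        raise ValueError(
            f"fewer than 2 parseable gene rows in {path} "
            f"(rejected: {report.rejected_rows})"
        )
    matrix = ExpressionMatrix(gene_ids[~bad], np.asarray(sample_ids, object), numeric[~bad])
    return matrix, report


def write_expression_matrix(matrix: ExpressionMatrix, path, delimiter: str = "\t",
                            id_header: str = "gene_id") -> None:
    """Write a matrix in the same layout :func:`read_expression_matrix` reads."""
    df = matrix.to_dataframe()
    df.index.name = id_header
    df.to_csv(path, sep=delimiter)


def read_mapping_table(path, name: str | None = None, priority: int = 0,
                       delimiter: str = "\t") -> MappingTable:
    """Read a two-column (source, target) mapping table.

    A source id listed twice with conflicting targets makes the table
    malformed and raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"mapping table {path} needs 2 columns, has {df.shape[1]}")
    mapping: dict = {}
    for src, tgt in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if src in mapping and mapping[src] != tgt:
            raise ValueError(
                f"malformed mapping table {path}: source {src!r} maps to both "
                f"{mapping[src]!r} and {tgt!r}"
            )
        mapping[src] = tgt
    return MappingTable(mapping, name=name or path.name, priority=priority)


def collapse_probesets(
    matrix: ExpressionMatrix, probe_map: MappingTable
) -> tuple[ExpressionMatrix, CollapseReport]:
    """Average probeset rows mapping to the same gene.

    Each output row is the arithmetic mean (on the stored log scale) of the
    rows of all probes mapped to that gene. Probes absent from ``probe_map``
    are dropped and counted. Output rows are ordered by gene id so the
    result is invariant to input row order.

    Raises ``ValueError`` if no probe maps to any gene.
    """
    targets: dict = {}
    unmapped = []
    for i, probe in enumerate(matrix.gene_ids):
        if probe in probe_map:
            targets.setdefault(probe_map[probe], []).append(i)
        else:
            unmapped.append(probe)
    if not targets:
        raise ValueError("no probe maps to any gene: empty collapsed matrix")
    gene_ids = sorted(targets)
    values = np.vstack([matrix.values[targets[g]].mean(axis=0) for g in gene_ids])
    report = CollapseReport(
        n_probes_in=matrix.n_genes,
        n_genes_out=len(gene_ids),
        unmapped_probes=unmapped,
    )
    out = ExpressionMatrix(np.asarray(gene_ids, object), matrix.sample_ids.copy(), values)
    return out, report


def map_identifiers_hierarchical(
    ids, tables: list[MappingTable]
) -> HierarchicalMapping:
    """Map identifiers through an ordered hierarchy of tables.

    Each id is resolved by the FIRST table (most trusted first) in which it
    appears; later tables never override an earlier hit. Ids found in no
    table are reported unmapped.

    Raises ``ValueError`` on an empty table list.
    """
    if not tables:
        raise ValueError("empty mapping-table hierarchy")
    mapping: dict = {}
    table_used: dict = {}
    counts = {t.name: 0 for t in tables}
    unmapped = []
    for i in ids:
        for t in tables:
            if i in t:
                mapping[i] = t[i]
                table_used[i] = t.name
                counts[t.name] += 1
                break
        else:
            unmapped.append(i)
    return HierarchicalMapping(mapping, table_used, counts, unmapped)
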