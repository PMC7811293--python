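"""Readers, writers and the shared data model.

The toolkit moves four kinds of objects between its stages:

* :class:`ExpressionMatrix` — a genes × cells matrix of non-negative
  expression values (raw counts or log-normalized), with unique gene and
  cell identifiers.
* :class:`MarkerTable` — prior knowledge encoding which genes are expressed
  (+1) or known-unexpressed (−1) markers of each cell type.
* :class:`GeneNetwork` — an undirected gene–gene interaction network used to
  restrict Hopfield couplings to biologically justified edges.
* :class:`ClusterLabels` — a cell → cluster-index map.

Gene identifiers are opaque, case-sensitive strings; matching between
expression data, marker tables and networks is exact string equality.  An
optional two-column synonym file can be applied before matching (see
:func:`apply_synonyms`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("cellsort")

__all__ = [
    "ExpressionMatrix",
    "MarkerTable",
    "GeneNetwork",
    "ClusterLabels",
    "read_expression",
    "write_expression",
    "read_marker_table",
    "write_marker_table",
    "read_gene_network",
    "read_cluster_labels",
    "write_cluster_labels",
    "apply_synonyms",
    "ParseError",
    "ValidationError",
]


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


def _check_unique(names, what: str, where: str) -> None:
    s = pd.Index(names)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} in {where}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes × cells expression values with identifier bookkeeping.

    ``values`` is a :class:`pandas.DataFrame` with gene identifiers as the
    index and cell identifiers as columns.  Values must be finite and ≥ 0.
    """

    values: pd.DataFrame
    is_lognormalized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene identifiers", "expression matrix")
        _check_unique(self.values.columns, "cell identifiers", "expression matrix")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def drop_empty(self) -> "ExpressionMatrix":
        """Remove all-zero gene rows and all-zero cell columns (logged)."""
        arr = self.values
        gene_keep = arr.sum(axis=1) > 0
        cell_keep = arr.sum(axis=0) > 0
        n_g = int((~gene_keep).sum())
        n_c = int((~cell_keep).sum())
        if n_g or n_c:
            logger.info("removed %d all-zero genes and %d all-zero cells", n_g, n_c)
        return ExpressionMatrix(
            arr.loc[gene_keep, cell_keep], is_lognormalized=self.is_lognormalized
        )

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(cells)], self.is_lognormalized)


@dataclass
class MarkerTable:
    """Marker / cell-type weight matrix.

    ``entries`` is genes × cell types.  Raw tables take values in
    {−1, 0, +1}: +1 marks a gene expressed in that type (positive marker),
    −1 a gene known to be unexpressed (negative marker), 0 uninformative.
    Normalized tables (see :mod:`cellsort.markers`) hold real weights with
    the same sign pattern.
    """

    entries: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.entries.index, "gene names", "marker table")
        _check_unique(self.entries.columns, "cell-type names", "marker table")
        arr = self.entries.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("marker entries must be finite")
        if not self.normalized:
            bad = ~np.isin(arr, (-1.0, 0.0, 1.0))
            if bad.any():
                g, t = np.argwhere(bad)[0]
                raise ValidationError(
                    "raw marker entries must be -1, 0 or +1; found "
                    f"{arr[g, t]} at gene {self.entries.index[g]!r}, "
                    f"type {self.entries.columns[t]!r}"
                )
            no_pos = (arr > 0).sum(axis=0) == 0
            if no_pos.any():
                bad_types = list(self.entries.columns[no_pos])
                raise ValidationError(
                    f"cell types with no positive marker: {bad_types}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.entries.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.entries.columns)


@dataclass
class GeneNetwork:
    """Undirected gene–gene interaction network (no self-loops)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)
            warnings.warn(f"dropped {len(loops)} self-loop edges")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def adjacency(self, genes: list[str], weighted: bool = False) -> np.ndarray:
        """Symmetric adjacency over ``genes``; absent genes give zero rows."""
        n = len(genes)
        idx = {g: i for i, g in enumerate(genes)}
        a = np.zeros((n, n))
        for u, v, data in self.graph.edges(data=True):
            if u in idx and v in idx:
                w = float(data.get("weight", 1.0)) if weighted else 1.0
                a[idx[u], idx[v]] = w
                a[idx[v], idx[u]] = w
        np.fill_diagonal(a, 0.0)
        return a


class ClusterLabels(pd.Series):
    """Cell → integer cluster index; indices contiguous from 0."""

    @property
    def _constructor(self):
        return ClusterLabels

    @classmethod
    def from_mapping(cls, mapping) -> "ClusterLabels":
        s = pd.Series(mapping, dtype=int)
        labels = cls(s)
        labels.validate()
        return labels

    def validate(self) -> None:
        vals = np.sort(self.unique())
        expect = np.arange(len(vals))
        if len(vals) == 0:
            raise ValidationError("empty cluster labels")
        if not np.array_equal(vals, expect):
            raise ValidationError(
                f"cluster indices must be contiguous from 0, got {vals.tolist()}"
            )

    @property
    def n_clusters(self) -> int:
        return int(self.max()) + 1


# ---------------------------------------------------------------------------
# expression IO

def read_expression(
    path, format: str = "dense", sep: str | None = None, transpose: bool = False
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``format="dense"`` expects CSV/TSV with gene rows, a header row of cell
    identifiers and the gene identifier in the first column.
    ``format="mtx"`` expects a MatrixMarket coordinate file with ``genes.tsv``
    and ``barcodes.tsv`` sidecars in the same directory (genes in rows,
    cells in columns; pass ``transpose=True`` for the opposite layout).

    All-zero genes and all-zero cells are removed on load.
    """
    path = Path(path)
    if format == "dense":
        if sep is None:
            sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise ParseError(f"{path}: cannot parse dense matrix: {exc}") from exc
        if df.shape[1] == 0:
            raise ParseError(f"{path}: no cell columns found (malformed header?)")
        nonnum = df.columns[[not pd.api.types.is_numeric_dtype(d) for d in df.dtypes]]
        if len(nonnum):
            raise ParseError(f"{path}: non-numeric entries in columns {list(nonnum)[:5]}")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        matrix = ExpressionMatrix(df.astype(float))
    elif format == "mtx":
        genes_path = path.parent / "genes.tsv"
        barcodes_path = path.parent / "barcodes.tsv"
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"{path}: cannot parse MatrixMarket file: {exc}") from exc
        genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str)
        cells = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str)
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
        if transpose:
            dense = dense.T
        if dense.shape != (len(genes), len(cells)):
            raise ParseError(
                f"{path}: matrix is {dense.shape} but sidecars list "
                f"{len(genes)} genes and {len(cells)} barcodes"
            )
        matrix = ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=cells))
    else:
        raise ValueError(f"unknown format {format!r}")
    return matrix.drop_empty()


def write_expression(matrix: ExpressionMatrix, path, format: str = "dense") -> None:
    path = Path(path)
    if format == "dense":
        matrix.values.to_csv(path)
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values.to_numpy()))
        pd.Series(matrix.genes).to_csv(path.parent / "genes.tsv", sep="\t",
                                       header=False, index=False)
        pd.Series(matrix.cells).to_csv(path.parent / "barcodes.tsv", sep="\t",
                                       header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# marker table IO

def read_marker_table(path) -> MarkerTable:
    """Read a raw marker table (CSV, gene rows × cell-type columns).

    Genes that appear in no cell type (all-zero rows) are dropped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: cannot parse marker table: {exc}") from exc
    df.index = df.index.astype(str)
    df = df.astype(float)
    used = (df != 0).any(axis=1)
    if (~used).any():
        logger.info("dropped %d genes used by no cell type", int((~used).sum()))
    return MarkerTable(df.loc[used])


def write_marker_table(table: MarkerTable, path) -> None:
    table.entries.to_csv(path)


# ---------------------------------------------------------------------------
# network IO

def read_gene_network(path) -> GeneNetwork:
    """Read a TSV edge list (two gene columns, optional third weight column).

    Self-loop lines are dropped with a warning; duplicate and reversed
    edges collapse onto a single undirected edge.
    """
    path = Path(path)
    graph = nx.Graph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least two columns")
            u, v = parts[0], parts[1]
            if u == v:
                warnings.warn(f"{path}:{lineno}: self-loop {u!r} dropped")
                continue
            if len(parts) >= 3:
                graph.add_edge(u, v, weight=float(parts[2]))
            else:
                graph.add_edge(u, v)
    return GeneNetwork(graph)


# ---------------------------------------------------------------------------
# cluster labels IO

def read_cluster_labels(path, matrix: ExpressionMatrix | None = None) -> ClusterLabels:
    """Read a two-column CSV (cell, cluster) into :class:`ClusterLabels`."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns (cell, cluster)")
    s = pd.Series(df.iloc[:, 1].astype(int).to_numpy(),
                  index=df.iloc[:, 0].astype(str))
    labels = ClusterLabels(s)
    labels.validate()
    if matrix is not None:
        missing = set(labels.index) - set(matrix.cells)
        if missing:
            raise ValidationError(
                f"labeled cells absent from expression matrix: {sorted(missing)[:5]}"
            )
    return labels


def write_cluster_labels(labels: ClusterLabels, path) -> None:
    pd.DataFrame({"cell": labels.index, "cluster": labels.to_numpy()}).to_csv(
        path, index=False
    )


def apply_synonyms(names: list[str], synonym_path) -> list[str]:
    """Map gene names through a two-column (old, new) synonym file."""
    table = pd.read_csv(synonym_path, sep=None, engine="python", header=None)
    mapping = dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))
    return [mapping.get(n, n) for n in names]
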