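"""Readers and writers for association matrices, similarity matrices and
disease DAGs.

All on-disk formats are plain TSV:

* edge list — headerless, two columns ``(miRNA_id, disease_id)``;
* dense matrix — first row holds disease (column) identifiers, first column
  holds miRNA (row) identifiers;
* DAG — headerless ``(child, parent)`` rows; a one-column row declares an
  isolated node.

Row/column order is tracked by :class:`EntityIndex` so that every matrix in a
pipeline shares a stable indexing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EntityIndex",
    "AssociationMatrix",
    "DiseaseDAG",
    "read_associations",
    "read_similarity",
    "read_dag",
    "write_scores",
    "write_matrix",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass(frozen=True)
class EntityIndex:
    """Ordered miRNA and disease identifiers shared by all matrices.

    Row ``i`` of an association matrix corresponds to ``mirna_ids[i]``,
    column ``j`` to ``disease_ids[j]``.
    """

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "mirna_ids", tuple(_check_unique(self.mirna_ids, "miRNA")))
        object.__setattr__(self, "disease_ids", tuple(_check_unique(self.disease_ids, "disease")))

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    def mirna_pos(self, mirna_id: str) -> int:
        return self.mirna_ids.index(mirna_id)

    def disease_pos(self, disease_id: str) -> int:
        return self.disease_ids.index(disease_id)


@dataclass
class AssociationMatrix:
    """Binary bipartite adjacency Y: rows are miRNAs, columns diseases."""

    values: np.ndarray
    index: EntityIndex

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.index.n_mirna, self.index.n_disease):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match index "
                f"({self.index.n_mirna}, {self.index.n_disease})"
            )
        bad = ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary association entry {self.values[i, j]!r} at "
                f"({self.index.mirna_ids[i]}, {self.index.disease_ids[j]})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_known(self) -> int:
        return int(self.values.sum())


@dataclass
class DiseaseDAG:
    """Disease hierarchy as a child -> parent edge set, checked acyclic."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    _parents: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _children: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.nodes = frozenset(str(n) for n in self.nodes)
        self.edges = frozenset((str(c), str(p)) for c, p in self.edges)
        for c, p in self.edges:
            if c not in self.nodes or p not in self.nodes:
                raise ValueError(f"edge ({c}, {p}) references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle is not None:
            raise ValueError(f"disease hierarchy contains a cycle: {cycle}")
        self._parents = {n: set() for n in self.nodes}
        self._children = {n: set() for n in self.nodes}
        for c, p in self.edges:
            self._parents[c].add(p)
            self._children[p].add(c)

    def parents(self, node: str) -> set[str]:
        return set(self._parents[node])

    def children(self, node: str) -> set[str]:
        return set(self._children[node])

    def ancestor_closure(self, node: str) -> set[str]:
        """The node together with all its ancestors (transitive parents)."""
        if node not in self.nodes:
            raise KeyError(f"disease {node!r} not in DAG")
        closure = {node}
        stack = [node]
        while stack:
            for p in self._parents[stack.pop()]:
                if p not in closure:
                    closure.add(p)
                    stack.append(p)
        return closure


def read_associations(path, format: str = "edge_list", *, mirna_ids=None, disease_ids=None) -> AssociationMatrix:
    """Read a binary association matrix.

    Parameters
    ----------
    path
        TSV file.
    format
        ``"edge_list"`` (headerless two-column) or ``"dense"`` (labelled
        matrix).
    mirna_ids, disease_ids
        Optional explicit identifier order for edge lists; identifiers not
        listed are appended in first-appearance order.  Ignored for dense
        files, whose headers pin the order.
    """
    path = Path(path)
    if format == "edge_list":
        mirnas = list(mirna_ids or [])
        diseases = list(disease_ids or [])
        pairs = []
        with path.open() as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"{path}:{line_no}: expected 2 columns, got {len(parts)}")
                m, d = parts[0].strip(), parts[1].strip()
                if m not in mirnas:
                    mirnas.append(m)
                if d not in diseases:
                    diseases.append(d)
                pairs.append((m, d))
        index = EntityIndex(tuple(mirnas), tuple(diseases))
        values = np.zeros((index.n_mirna, index.n_disease))
        mpos = {m: i for i, m in enumerate(index.mirna_ids)}
        dpos = {d: j for j, d in enumerate(index.disease_ids)}
        for m, d in pairs:
            values[mpos[m], dpos[d]] = 1.0
        return AssociationMatrix(values, index)
    if format == "dense":
        df = _read_dense(path)
        index = EntityIndex(tuple(df.index.astype(str)), tuple(df.columns.astype(str)))
        values = df.to_numpy(dtype=float)
        return AssociationMatrix(values, index)
    raise ValueError(f"unknown format {format!r}")


def _read_dense(path) -> pd.DataFrame:
    """Dense labelled TSV with duplicate-label detection (pandas silently
    renames duplicate header entries, so check the raw header first)."""
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index.astype(str), "row")
    return df


def read_similarity(path, ids) -> np.ndarray:
    """Read a dense square similarity matrix and reconcile it.

    The file's rows/columns are reindexed to ``ids``; the result is
    symmetrized by averaging with its transpose (asymmetry beyond 1e-6 is
    logged as a warning) and the diagonal is forced to 1, since all
    downstream kernel math assumes a symmetric unit-diagonal matrix.
    """
    ids = [str(i) for i in ids]
    df = _read_dense(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = [i for i in ids if i not in df.index or i not in df.columns]
    if missing:
        raise FormatError(f"similarity file {path} is missing identifiers: {missing}")
    mat = df.loc[ids, ids].to_numpy(dtype=float)
    asym = np.abs(mat - mat.T).max() if mat.size else 0.0
    if asym > 1e-6:
        logger.warning("similarity matrix %s asymmetric by %.3g; symmetrizing", path, asym)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return mat


def read_dag(path) -> DiseaseDAG:
    """Read a child -> parent edge list into a :class:`DiseaseDAG`.

    A row with a single column declares an isolated node (a root with no
    parent and, so far, no children).
    """
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t") if p.strip()]
            if len(parts) == 1:
                nodes.add(parts[0])
            elif len(parts) == 2:
                child, parent = parts
                nodes.update((child, parent))
                edges.add((child, parent))
            else:
                raise FormatError(f"{path}:{line_no}: expected 1 or 2 columns")
    return DiseaseDAG(frozenset(nodes), frozenset(edges))


def write_matrix(values: np.ndarray, row_ids, col_ids, path) -> None:
    """Write a labelled dense matrix as TSV at full float precision."""
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_scores(scores: np.ndarray, index: EntityIndex, path) -> None:
    """Write a score matrix (miRNA rows x disease columns) as dense TSV."""
    scores = np.asarray(scores)
    if scores.shape != (index.n_mirna, index.n_disease):
        raise ValueError(f"score shape {scores.shape} does not match index")
    write_matrix(scores, index.mirna_ids, index.disease_ids, path)
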