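"""Similarity kernels for the two sides of the bipartite association network.

Four constructions live here:

* the Gaussian interaction profile (GIP) kernel, a Gaussian of the squared
  distance between binary association profiles;
* linear fusion of a supplied similarity (functional for miRNAs, semantic
  for diseases) with the GIP kernel, weighted by ``alpha``;
* disease semantic similarity from a directed acyclic hierarchy, via the
  decaying per-ancestor contribution recursion;
* the nearest-profile (NP) matrix, a sparsified kernel keeping only each
  entity's single most similar neighbour, used both as a factorization
  regularizer target and to borrow an association profile for entities with
  no known associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, DiseaseDAG

__all__ = [
    "KernelMatrix",
    "NearestProfileMatrix",
    "gip_kernel",
    "fuse_kernels",
    "semantic_contribution",
    "semantic_similarity",
    "nearest_profile_matrix",
    "np_profile",
]

_SIDES = ("mirna", "disease")
_KINDS = ("functional", "semantic", "gip", "fused", "nearest_profile_source")
_UNIT_DIAG_KINDS = ("functional", "semantic", "gip", "fused")


@dataclass
class KernelMatrix:
    """Square symmetric per-side similarity matrix.

    ``kind`` records provenance: a supplied functional/semantic matrix, a GIP
    kernel, a fused combination, or an arbitrary source for nearest-profile
    extraction.  Unit diagonal is enforced for all but the last.
    """

    values: np.ndarray
    side: str
    kind: str

    def __post_init__(self):
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("kernel matrix must be square")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("kernel matrix must be symmetric within 1e-10")
        if self.kind in _UNIT_DIAG_KINDS and n and np.abs(np.diag(self.values) - 1).max() > 1e-10:
            raise ValueError(f"{self.kind} kernel must have unit diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NearestProfileMatrix:
    """One-nonzero-per-row sparsification of a kernel (the NP matrix).

    Row i holds the source kernel value at i's most similar other entity and
    zeros elsewhere; the diagonal is all zero.
    """

    values: np.ndarray
    side: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}")


def gip_kernel(Y: AssociationMatrix | np.ndarray, side: str, gamma: float = 1.0) -> KernelMatrix:
    """Gaussian interaction profile kernel over association profiles.

    Entry (i, j) is ``exp(-gamma * ||y_i - y_j||^2)`` where ``y_i`` is row i
    of Y on the miRNA side or column i on the disease side.  The bandwidth
    ``gamma`` is used literally (default 1), with no per-profile
    normalization.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    values = Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y, dtype=float)
    profiles = values if side == "mirna" else values.T
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}")
    # ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b
    sq = np.einsum("ij,ij->i", profiles, profiles)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (profiles @ profiles.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, side=side, kind="gip")


def fuse_kernels(S: KernelMatrix, G: KernelMatrix, alpha: float) -> KernelMatrix:
    """Elementwise linear combination ``alpha*S + (1-alpha)*G``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if S.side != G.side:
        raise ValueError(f"cannot fuse kernels from different sides: {S.side} vs {G.side}")
    if S.values.shape != G.values.shape:
        raise ValueError("cannot fuse kernels of different shapes")
    return KernelMatrix(alpha * S.values + (1.0 - alpha) * G.values, side=S.side, kind="fused")


def semantic_contribution(dag: DiseaseDAG, DD: str, delta: float = 0.5) -> dict[str, float]:
    """Per-ancestor semantic contribution D1 of disease ``DD``.

    ``DD`` itself contributes 1; each ancestor d contributes
    ``delta * max(D1(child))`` over its children within DD's ancestor
    closure.  Nodes outside the closure are absent from the returned map.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError(f"delta must lie in (0, 1], got {delta}")
    if DD not in dag.nodes:
        raise KeyError(f"disease {DD!r} not in DAG")
    closure = dag.ancestor_closure(DD)
    contrib: dict[str, float] = {}

    def d1(node: str) -> float:
        if node in contrib:
            return contrib[node]
        if node == DD:
            val = 1.0
        else:
            kids = [c for c in dag.children(node) if c in closure]
            val = delta * max(d1(c) for c in kids)
        contrib[node] = val
        return val

    # evaluate in closure order; recursion depth is bounded by DAG height
    for node in closure:
        d1(node)
    return contrib


def semantic_value(dag: DiseaseDAG, DD: str, delta: float = 0.5) -> float:
    """DV1: total semantic value of a disease, the sum of its D1 map."""
    return sum(semantic_contribution(dag, DD, delta).values())


def semantic_similarity(dag: DiseaseDAG, ids, delta: float = 0.5) -> KernelMatrix:
    """Pairwise disease semantic similarity over ``ids``.

    Sd(i, j) sums D1_i(t) + D1_j(t) over shared ancestors t and normalizes
    by DV1(i) + DV1(j); two diseases with disjoint hierarchies score 0, a
    disease with itself scores 1.
    """
    ids = [str(i) for i in ids]
    if not ids:
        raise ValueError("empty disease id list")
    contribs = [semantic_contribution(dag, d, delta) for d in ids]
    dv1 = [sum(c.values()) for c in contribs]
    m = len(ids)
    S = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            shared = contribs[i].keys() & contribs[j].keys()
            if shared:
                num = sum(contribs[i][t] + contribs[j][t] for t in shared)
                S[i, j] = S[j, i] = num / (dv1[i] + dv1[j])
    return KernelMatrix(S, side="disease", kind="semantic")


def _nearest_indices(K: np.ndarray) -> np.ndarray:
    """Row-wise argmax over off-diagonal entries, ties to smallest index."""
    n = K.shape[0]
    if n < 2:
        raise ValueError("nearest neighbour undefined for a single entity")
    masked = K.copy()
    np.fill_diagonal(masked, -np.inf)
    return masked.argmax(axis=1)


def nearest_profile_matrix(K: KernelMatrix, *, symmetrize: bool = False) -> NearestProfileMatrix:
    """Sparsify a kernel to its nearest-neighbour (NP) matrix.

    Self-similarity is removed, each row keeps only the kernel value at its
    most similar other entity (ties broken toward the smallest index), and
    everything else is zeroed.  The result is asymmetric by construction;
    ``symmetrize=True`` replaces it with ``(N + N.T) / 2``.
    """
    nearest = _nearest_indices(K.values)
    n = K.n
    N = np.zeros((n, n))
    rows = np.arange(n)
    N[rows, nearest] = K.values[rows, nearest]
    if symmetrize:
        N = (N + N.T) / 2.0
    return NearestProfileMatrix(N, side=K.side)


def np_profile(K: KernelMatrix, Y: AssociationMatrix, entity: int, side: str) -> np.ndarray:
    """Borrowed association profile for one entity via its nearest neighbour.

    Returns ``K(entity, nearest) * Y(nearest)`` where ``nearest`` maximizes
    similarity over the other entities on the same side — the profile used
    to score entities with no known associations of their own.
    """
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}")
    if side != K.side:
        raise ValueError(f"kernel side {K.side!r} does not match requested side {side!r}")
    nearest = int(_nearest_indices(K.values)[entity])
    sim = K.values[entity, nearest]
    profile = Y.values[nearest, :] if side == "mirna" else Y.values[:, nearest]
    return sim * profile
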