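"""Modularity matrix, partition quality, spin/binary forms, and thresholding.

The modularity matrix of a graph with adjacency ``A``, degree vector ``g``
and total weight ``2m`` is

    B = A - g g^T / 2m,

whose rows and columns sum to zero.  For a partition with community labels
``c_i`` the modularity is

    Q = (1/2m) * sum_ij B_ij * delta(c_i, c_j),

where the double sum runs over all pairs including ``i = j``.  Including
the diagonal matches the standard (Newman) values reported for the classic
benchmarks, e.g. 0.41979 for the karate club; dropping it would only shift
Q by a partition-independent constant.

For at most two communities the labels can be encoded as spins
``s_i in {-1, +1}`` and Q = s^T B s / 4m; because ``B 1 = 0`` this equals
the binary quadratic form ``x^T B x / m`` with ``x = (s + 1) / 2``, which
is the identity that lets the same matrix drive either an Ising- or a
QUBO-style solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import Graph

__all__ = [
    "ModularityMatrix",
    "Partition",
    "modularity_matrix",
    "modularity",
    "modularity_two_community",
    "ising_qubo_identity_check",
    "threshold_matrix",
]

#: absolute tolerance for the zero row/column sum invariant of B
ROW_SUM_ATOL = 1e-9


@dataclass(frozen=True)
class ModularityMatrix:
    """Dense symmetric modularity matrix ``B`` plus its ``2m`` normalizer."""

    B: np.ndarray = field(repr=False)
    two_m: float
    source: Graph | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.B.shape[0]

    def validate(self) -> None:
        """Check symmetry and the zero row-sum invariant (thresholded
        matrices intentionally violate the latter and skip this)."""
        if not np.allclose(self.B, self.B.T, atol=0.0):
            raise ValueError("B must be symmetric")
        rs = self.B.sum(axis=1)
        if np.abs(rs).max() > ROW_SUM_ATOL:
            raise ValueError(
                f"row sums of B must vanish; max |row sum| = {np.abs(rs).max():.3e}"
            )


@dataclass(frozen=True)
class Partition:
    """Community labels, one per node, with ``0 <= labels[i] < k``."""

    labels: tuple[int, ...]
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        lab = np.asarray(self.labels, dtype=int)
        if lab.size and (lab.min() < 0 or lab.max() >= self.k):
            raise ValueError(f"labels must lie in [0, {self.k})")
        object.__setattr__(self, "labels", tuple(int(c) for c in lab))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def num_communities(self) -> int:
        """Number of non-empty communities (empty label slots are legal)."""
        return len(set(self.labels))

    def one_hot(self) -> np.ndarray:
        """The ``n x k`` one-hot membership matrix X with X[i, c_i] = 1."""
        X = np.zeros((self.n, self.k), dtype=int)
        X[np.arange(self.n), np.asarray(self.labels)] = 1
        return X

    @classmethod
    def from_one_hot(cls, X: np.ndarray) -> "Partition":
        X = np.asarray(X)
        if not np.array_equal(X.sum(axis=1), np.ones(X.shape[0], dtype=X.dtype)):
            raise ValueError("each row of X must have exactly one set bit")
        return cls(tuple(int(c) for c in X.argmax(axis=1)), X.shape[1])


def _as_spins(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if not np.all(np.isin(s, (-1.0, 1.0))):
        raise ValueError("spin entries must be -1 or +1")
    return s


def modularity_matrix(graph: Graph) -> ModularityMatrix:
    """Construct ``B = A - g g^T / 2m`` for a graph with at least one edge."""
    two_m = graph.total_weight
    if two_m <= 0:
        raise ValueError("graph has no edges: 2m = 0, modularity undefined")
    g = graph.degrees
    B = graph.adjacency - np.outer(g, g) / two_m
    M = ModularityMatrix(B=B, two_m=two_m, source=graph)
    M.validate()
    return M


def modularity(M: ModularityMatrix, p: Partition) -> float:
    """Q = (1/2m) sum_ij B_ij delta(c_i, c_j), diagonal included."""
    if p.n != M.n:
        raise ValueError(f"partition has {p.n} labels for a {M.n}-node matrix")
    X = p.one_hot().astype(float)
    return float(np.einsum("ij,ic,jc->", M.B, X, X) / M.two_m)


def modularity_two_community(M: ModularityMatrix, s) -> float:
    """Two-community modularity from a spin vector:
    Q = (1/2m) sum_ij B_ij (s_i s_j + 1) / 2  ==  s^T B s / 4m."""
    s = _as_spins(s)
    if s.shape != (M.n,):
        raise ValueError(f"spin vector length {s.shape} != ({M.n},)")
    return float(np.sum(M.B * (np.outer(s, s) + 1.0) / 2.0) / M.two_m)


def ising_qubo_identity_check(M: ModularityMatrix, s) -> tuple[float, float]:
    """Return ``(s^T B s, 4 x^T B x)`` with ``x = (s + 1)/2``.

    The two agree exactly (up to roundoff) because ``B 1 = 0``, which is
    why the spin and binary forms of two-community modularity coincide.
    """
    s = _as_spins(s)
    x = (s + 1.0) / 2.0
    return float(s @ M.B @ s), float(4.0 * (x @ M.B @ x))


def threshold_matrix(M: ModularityMatrix, t: float) -> tuple[ModularityMatrix, int]:
    """Zero out off-diagonal entries with ``|B_ij| <= t``; keep the diagonal.

    Returns the sparsified matrix and the retained-pair count
    ``E' = #{(i, j) : i < j, |B_ij| > t}``.  The thresholded matrix is meant
    only for building a smaller optimization problem; partition quality is
    always evaluated against the original B.
    """
    if t < 0:
        raise ValueError(f"threshold must be non-negative, got {t}")
    keep = np.abs(M.B) > t
    np.fill_diagonal(keep, True)
    Bt = np.where(keep, M.B, 0.0)
    iu = np.triu_indices(M.n, k=1)
    retained = int(np.count_nonzero(keep[iu]))
    return ModularityMatrix(B=Bt, two_m=M.two_m, source=M.source), retained
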