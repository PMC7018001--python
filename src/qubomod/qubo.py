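"""Assembly of the k-concurrent one-hot QUBO for modularity maximization.

Each graph node ``i`` becomes a *logical super-node* of ``k`` binary
variables ``x_{i,j}`` (one per candidate community), with the one-hot
constraint ``sum_j x_{i,j} = 1`` enforced softly by a quadratic penalty.
Maximizing

    X^T (beta * blockdiag(B, ..., B) + B_Gamma) X - 2 Gamma^T X

over binary X is equivalent, after sign flip for a minimizing sampler and
absorbing ``x^2 = x``, to the QUBO built here:

* within community block ``j``: coupling ``-2 beta B_{i,i'}`` between
  ``x_{i,j}`` and ``x_{i',j}``, and linear term ``-beta B_{ii}``;
* within super-node ``i``: coupling ``+2 gamma_i`` between any two of its
  ``k`` variables and linear term ``-gamma_i``.

``gamma_i`` here is the positive penalty *magnitude*; it corresponds to a
negative relaxation coefficient in the maximization form.  Constant terms
are dropped exactly as the maximization form drops them (the ``offset``
field records any residual constant, zero for this construction), so for
any feasible one-hot assignment

    energy(X) = -beta * 2m * Q(X) - sum_i gamma_i

with Q the modularity of the decoded partition evaluated on the B used to
build the problem; infeasible assignments pay an additional positive
penalty.  Variables are column-stacked: ``x_{i,j}`` sits at index
``i + j*n``, making the block structure literal.  Coefficients are stored
sparsely, so a thresholded B directly shrinks the problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .modularity import ModularityMatrix

__all__ = ["QUBOProblem", "build_kconcurrent_qubo", "energy", "auto_penalty"]


@dataclass(frozen=True)
class QUBOProblem:
    """A minimization QUBO in upper-triangle convention.

    ``linear[u]`` holds the coefficient of ``b_u`` (the diagonal of the
    coefficient matrix); ``(rows[p], cols[p], vals[p])`` with
    ``rows[p] < cols[p]`` hold the pairwise couplings.  The energy of a
    bitstring ``b`` is ``linear . b + sum_p vals_p b_rows_p b_cols_p +
    offset``.
    """

    n: int
    k: int
    linear: np.ndarray = field(repr=False)
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)
    vals: np.ndarray = field(repr=False)
    offset: float
    beta: float
    gamma: np.ndarray = field(repr=False)  # per-node penalty magnitudes
    threshold: float | None = None  # provenance: B threshold used, if any
    metadata: dict[str, Any] = field(default_factory=dict, compare=False)

    @property
    def num_vars(self) -> int:
        return self.n * self.k

    def var_index(self, i: int, j: int) -> int:
        """Flat index of ``x_{i,j}`` (node i, community j), column-stacked."""
        if not (0 <= i < self.n and 0 <= j < self.k):
            raise IndexError(f"(i={i}, j={j}) out of range for n={self.n}, k={self.k}")
        return i + j * self.n

    def neighbor_lists(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetric CSR view (ptr, idx, val) of the couplings, for samplers."""
        N = self.num_vars
        deg = np.zeros(N, dtype=np.int64)
        np.add.at(deg, self.rows, 1)
        np.add.at(deg, self.cols, 1)
        ptr = np.zeros(N + 1, dtype=np.int64)
        np.cumsum(deg, out=ptr[1:])
        idx = np.empty(ptr[-1], dtype=np.int64)
        val = np.empty(ptr[-1], dtype=float)
        fill = ptr[:-1].copy()
        for u, v, w in zip(self.rows, self.cols, self.vals):
            idx[fill[u]] = v
            val[fill[u]] = w
            fill[u] += 1
            idx[fill[v]] = u
            val[fill[v]] = w
            fill[v] += 1
        return ptr, idx, val


def auto_penalty(M: ModularityMatrix, beta: float = 1.0) -> float:
    """Safe default penalty magnitude ``1 + beta * max_i sum_j |B_ij|``.

    Any constraint violation then costs more than the largest modularity
    gain a single variable can contribute, so the relaxed optimum is
    one-hot feasible.  Hand-tuned (smaller) values usually anneal better.
    """
    return 1.0 + float(beta * np.abs(M.B).sum(axis=1).max())


def build_kconcurrent_qubo(
    M: ModularityMatrix,
    k: int,
    gamma: float | np.ndarray | None = None,
    beta: float = 1.0,
    threshold: float | None = None,
) -> QUBOProblem:
    """Build the minimization QUBO for at-most-``k``-community detection.

    Parameters
    ----------
    M
        Modularity matrix (possibly thresholded) driving the objective.
    k
        Number of community slots; ``k = n`` imposes no prior on the count.
    gamma
        One-hot penalty magnitude(s), scalar or per-node, strictly positive.
        ``None`` selects :func:`auto_penalty`.
    beta
        Weight of the modularity term.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    n = M.n
    if gamma is None:
        gamma = auto_penalty(M, beta)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (n,)).copy()
    if np.any(gamma <= 0):
        raise ValueError("penalty magnitude gamma must be strictly positive "
                         "(zero would leave the one-hot constraint unenforced)")

    N = n * k
    linear = np.empty(N)
    for j in range(k):
        linear[j * n:(j + 1) * n] = -beta * np.diagonal(M.B) - gamma

    iu, ju = np.triu_indices(n, k=1)
    nz = M.B[iu, ju] != 0.0
    bi, bj, bv = iu[nz], ju[nz], M.B[iu, ju][nz]

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    # modularity couplings, replicated in each community block
    for j in range(k):
        rows.append(bi + j * n)
        cols.append(bj + j * n)
        vals.append(-2.0 * beta * bv)
    # one-hot penalty couplings inside each super-node
    node = np.arange(n)
    for j in range(k):
        for j2 in range(j + 1, k):
            rows.append(node + j * n)
            cols.append(node + j2 * n)
            vals.append(2.0 * gamma)

    return QUBOProblem(
        n=n,
        k=k,
        linear=linear,
        rows=np.concatenate(rows) if rows else np.empty(0, dtype=np.int64),
        cols=np.concatenate(cols) if cols else np.empty(0, dtype=np.int64),
        vals=np.concatenate(vals) if vals else np.empty(0),
        offset=0.0,
        beta=float(beta),
        gamma=gamma,
        threshold=threshold,
        metadata={"two_m": M.two_m},
    )


def energy(problem: QUBOProblem, assignment) -> float:
    """Energy of one bitstring: ``linear.b + sum couplings + offset``."""
    b = np.asarray(assignment, dtype=float).ravel()
    if b.shape != (problem.num_vars,):
        raise ValueError(
            f"assignment length {b.size} != num_vars {problem.num_vars}"
        )
    if not np.all(np.isin(b, (0.0, 1.0))):
        raise ValueError("assignment entries must be 0 or 1")
    quad = float(np.sum(problem.vals * b[problem.rows] * b[problem.cols]))
    return float(problem.linear @ b) + quad + problem.offset
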