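"""Decoding sampler bitstrings into partitions and running the full pipeline.

A sampler returns bitstrings over the ``N = k*n`` one-hot variables.  Each
logical super-node (the ``k`` bits of one graph node) must have exactly one
set bit; samples violating this are reported and, by default, discarded —
silent repair would mask an under-sized penalty.  Among feasible samples
the best partition is the one maximizing modularity *evaluated on the
original (unthresholded) modularity matrix*, which is what makes QUBO-side
thresholding a lossless-in-quality reduction up to surprisingly large
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .anneal import (
    AnnealSchedule,
    Sampler,
    SampleSet,
    check_sampler_output,
    simulated_anneal,
)
from .graph import Graph
from .modularity import ModularityMatrix, Partition, modularity, modularity_matrix, threshold_matrix
from .qubo import QUBOProblem, build_kconcurrent_qubo

__all__ = [
    "InfeasibilityReport",
    "PenaltyTooWeakError",
    "decode",
    "canonicalize",
    "repair_partition",
    "best_partition",
    "DetectionResult",
    "detect_communities",
    "sweep_k",
    "threshold_scan",
]

#: default cap on k when k is chosen automatically (k = n capped for large n)
DEFAULT_K_CAP = 16


@dataclass(frozen=True)
class InfeasibilityReport:
    """Which super-nodes violate the one-hot constraint, and how."""

    violations: dict[int, int]  # super-node index -> number of set bits (!= 1)

    @property
    def is_feasible(self) -> bool:
        return not self.violations


class PenaltyTooWeakError(RuntimeError):
    """Every sample violated the one-hot constraint."""


def _occupancy(assignment, n: int, k: int) -> np.ndarray:
    b = np.asarray(assignment).ravel()
    if b.size != n * k:
        raise ValueError(f"assignment length {b.size} != n*k = {n * k}")
    return b.reshape(k, n).T  # X[i, j] = bit of node i, community j


def decode(assignment, n: int, k: int) -> Partition | InfeasibilityReport:
    """Decode a column-stacked bitstring into a partition, or report why not."""
    X = _occupancy(assignment, n, k)
    occ = X.sum(axis=1)
    if np.all(occ == 1):
        return Partition(tuple(int(c) for c in X.argmax(axis=1)), k)
    return InfeasibilityReport(
        {int(i): int(occ[i]) for i in np.flatnonzero(occ != 1)}
    )


def canonicalize(p: Partition) -> Partition:
    """Relabel communities by first appearance in node order; drop empty slots.

    Idempotent; any two label-permuted partitions map to the same result.
    """
    mapping: dict[int, int] = {}
    labels = []
    for c in p.labels:
        if c not in mapping:
            mapping[c] = len(mapping)
        labels.append(mapping[c])
    return Partition(tuple(labels), max(len(mapping), 1))


def repair_partition(assignment, n: int, k: int, M: ModularityMatrix) -> Partition:
    """Greedy repair of an infeasible sample.

    Nodes with exactly one set bit keep their community; violating nodes
    (zero or multiple bits) are assigned in node order to the community
    with the largest modularity gain given the assignment so far.
    """
    X = _occupancy(assignment, n, k)
    occ = X.sum(axis=1)
    labels = X.argmax(axis=1)
    member = np.zeros((n, k), dtype=float)
    ok = occ == 1
    member[np.flatnonzero(ok), labels[ok]] = 1.0
    for i in np.flatnonzero(~ok):
        gains = M.B[i] @ member  # coupling of node i into each community
        j = int(gains.argmax())
        labels[i] = j
        member[i, j] = 1.0
    return Partition(tuple(int(c) for c in labels), k)


def best_partition(
    samples: SampleSet,
    M_original: ModularityMatrix,
    n: int,
    k: int,
    repair: bool = False,
) -> tuple[Partition, float, dict[str, Any]]:
    """Select the best feasible partition from a sample set.

    Quality is modularity on ``M_original``.  Ties are broken by fewest
    non-empty communities, then by lexicographically smallest canonical
    labeling.  With ``repair=True`` infeasible samples are greedily fixed
    instead of discarded.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    total = samples.num_reads
    infeasible_reads = 0
    best: tuple[float, int, tuple[int, ...]] | None = None
    best_p: Partition | None = None
    for bits, _e, count in samples:
        out = decode(bits, n, k)
        if isinstance(out, InfeasibilityReport):
            infeasible_reads += int(count)
            if not repair:
                continue
            p = repair_partition(bits, n, k, M_original)
        else:
            p = out
        q = modularity(M_original, p)
        canon = canonicalize(p)
        key = (-q, canon.num_communities, canon.labels)
        if best is None or key < best:
            best, best_p = key, canon
    if best_p is None:
        raise PenaltyTooWeakError(
            f"all {total} reads violate the one-hot constraint; "
            "increase the penalty magnitude gamma"
        )
    diagnostics = {
        "num_reads": total,
        "infeasible_fraction": infeasible_reads / total,
        "num_communities": best_p.num_communities,
        "repaired": repair and infeasible_reads > 0,
    }
    return best_p, -best[0], diagnostics


@dataclass(frozen=True)
class DetectionResult:
    """Everything the detection pipeline produced for one graph."""

    partition: Partition
    modularity: float
    num_communities: int
    graph: Graph = field(repr=False)
    problem: QUBOProblem = field(repr=False)
    samples: SampleSet = field(repr=False)
    retained_pairs: int
    diagnostics: dict[str, Any] = field(repr=False)

    def labels_by_node(self) -> dict[str, int]:
        return dict(zip(self.graph.nodes, self.partition.labels))


def detect_communities(
    graph: Graph,
    k: int | None = None,
    beta: float = 1.0,
    penalty: float | None = None,
    threshold: float = 0.0,
    num_reads: int = 1000,
    sweeps: int = 1000,
    beta_range: tuple[float, float] | None = None,
    seed: int | None = None,
    sampler: Sampler | None = None,
    repair_infeasible: bool = False,
    k_cap: int = DEFAULT_K_CAP,
) -> DetectionResult:
    """Full pipeline: B -> (optional threshold) -> QUBO -> sample -> decode.

    ``k=None`` uses ``min(n, k_cap)`` community slots — in principle
    ``k = n`` imposes no prior on the community count, and the cap only
    bounds problem size.  ``penalty=None`` selects the safe automatic
    magnitude.  The annealing runs on the thresholded matrix; the reported
    modularity is always evaluated on the original one.
    """
    M = modularity_matrix(graph)
    if k is None:
        k = min(graph.n, k_cap)
    M_solve, retained = threshold_matrix(M, threshold)
    problem = build_kconcurrent_qubo(
        M_solve, k, gamma=penalty, beta=beta, threshold=threshold
    )
    if sampler is None:
        samples = simulated_anneal(
            problem,
            num_reads=num_reads,
            schedule=AnnealSchedule(sweeps=sweeps, beta_range=beta_range),
            seed=seed,
        )
    else:
        samples = check_sampler_output(problem, sampler(problem))
    part, q, diag = best_partition(
        samples, M, graph.n, k, repair=repair_infeasible
    )
    return DetectionResult(
        partition=part,
        modularity=q,
        num_communities=part.num_communities,
        graph=graph,
        problem=problem,
        samples=samples,
        retained_pairs=retained,
        diagnostics=diag,
    )


def sweep_k(graph: Graph, k_values: Sequence[int], **config) -> pd.DataFrame:
    """Run the pipeline for each ``k``; tabulate communities found and Q.

    Returns a DataFrame with columns ``k``, ``num_communities``,
    ``modularity`` — the convergence-with-super-node-size experiment.
    """
    if len(k_values) == 0:
        raise ValueError("k_values must be nonempty")
    rows = []
    for k in k_values:
        res = detect_communities(graph, k=int(k), **config)
        rows.append(
            {"k": int(k), "num_communities": res.num_communities,
             "modularity": res.modularity}
        )
    return pd.DataFrame(rows)


def threshold_scan(graph: Graph, thresholds: Sequence[float], **config) -> pd.DataFrame:
    """Run the pipeline at each modularity-matrix threshold.

    Returns a DataFrame with columns ``threshold``, ``retained_pairs``,
    ``num_communities``, ``modularity`` (Q always on the original B).
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be nonempty")
    rows = []
    for t in thresholds:
        res = detect_communities(graph, threshold=float(t), **config)
        rows.append(
            {"threshold": float(t), "retained_pairs": res.retained_pairs,
             "num_communities": res.num_communities,
             "modularity": res.modularity}
        )
    return pd.DataFrame(rows)
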