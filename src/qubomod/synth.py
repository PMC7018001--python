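"""Synthetic graphs and exact oracles for testing the pipeline end to end.

Provides a planted-partition generator (known ground-truth communities),
a registry of tiny worked-example graphs, and an exact maximum-modularity
oracle that enumerates every set partition of up to 10 nodes via
restricted-growth strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph
from .modularity import Partition, modularity, modularity_matrix

__all__ = [
    "planted_partition",
    "toy_graphs",
    "ToyGraph",
    "brute_force_best_partition",
]

BRUTE_FORCE_CAP = 10  # Bell(10) = 115975 set partitions


def planted_partition(
    block_sizes,
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> tuple[Graph, np.ndarray]:
    """Random graph with planted community blocks.

    Each within-block node pair is an edge with probability ``p_in``,
    each cross-block pair with ``p_out`` (``0 <= p_out < p_in <= 1``).
    Returns the graph and the ground-truth block label per node.
    """
    sizes = [int(s) for s in block_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("block sizes must be positive")
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError(
            f"need 0 <= p_out < p_in <= 1 for planted structure, "
            f"got p_in={p_in}, p_out={p_out}"
        )
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = labels.size
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(labels[iu] == labels[ju], p_in, p_out)
    draw = rng.random(iu.size) < p
    A = np.zeros((n, n))
    A[iu[draw], ju[draw]] = 1.0
    A += A.T
    nodes = tuple(str(i) for i in range(n))
    return Graph(nodes, A), labels


def _restricted_growth_strings(n: int):
    """Yield every set partition of ``range(n)`` exactly once as a label
    array, via restricted-growth strings (labels[i] <= 1 + max(labels[:i]))."""
    labels = np.zeros(n, dtype=int)
    maxes = np.zeros(n, dtype=int)  # maxes[i] = max(labels[:i+1])
    while True:
        yield labels
        # find rightmost position (>=1) that can be incremented
        i = n - 1
        while i > 0 and labels[i] > maxes[i - 1]:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        labels[i + 1:] = 0
        maxes[i + 1:] = maxes[i]


def brute_force_best_partition(graph: Graph, max_n: int = BRUTE_FORCE_CAP) -> tuple[Partition, float]:
    """Exact maximum-modularity partition by exhaustive enumeration.

    Visits every set partition of the nodes once (restricted-growth
    strings) and returns the maximizer; the first-enumerated partition
    wins ties, which is also the one with fewest communities among the
    earliest in restricted-growth order.
    """
    n = graph.n
    if n > max_n:
        raise ValueError(
            f"brute force capped at {max_n} nodes (Bell numbers explode), got {n}"
        )
    M = modularity_matrix(graph)
    scale = M.B / M.two_m
    best_q = -np.inf
    best_labels: np.ndarray | None = None
    for labels in _restricted_growth_strings(n):
        q = float(scale[labels[:, None] == labels[None, :]].sum())
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels.copy()
    assert best_labels is not None
    k = int(best_labels.max()) + 1
    return Partition(tuple(int(c) for c in best_labels), k), best_q


@dataclass(frozen=True)
class ToyGraph:
    """A small named graph with its exact max-modularity oracle answer."""

    name: str
    graph: Graph
    best_partition: Partition
    best_modularity: float


def _toy_edges() -> dict[str, list[tuple[str, str]]]:
    tri = [("a", "b"), ("b", "c"), ("c", "a")]
    return {
        "triangle": tri,
        "path_4": [("a", "b"), ("b", "c"), ("c", "d")],
        "two_disjoint_triangles": tri + [("d", "e"), ("e", "f"), ("f", "d")],
        # two triangles joined by a single bridge edge
        "barbell": tri + [("d", "e"), ("e", "f"), ("f", "d"), ("c", "d")],
    }


def toy_graphs() -> dict[str, ToyGraph]:
    """Registry of worked-example graphs with brute-force oracle answers."""
    out = {}
    for name, edges in _toy_edges().items():
        g = Graph.from_edges(edges)
        p, q = brute_force_best_partition(g)
        out[name] = ToyGraph(name, g, p, q)
    return out
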