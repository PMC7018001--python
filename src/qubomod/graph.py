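"""Undirected weighted graphs with a fixed node order and dense adjacency.

The graph model is deliberately small: community detection by modularity
maximization only needs the adjacency matrix ``A`` (symmetric, zero
diagonal), the degree vector ``g_i = sum_j A_ij`` and the total edge weight
``2m = sum_i g_i``.  Node identifiers are arbitrary strings mapped to dense
0-based indices in first-appearance order; that order is fixed at load time
and preserved through every downstream matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "GraphParseError",
    "read_edge_list",
    "write_edge_list",
    "read_gml",
    "load_benchmark",
    "available_benchmarks",
]


class GraphParseError(ValueError):
    """Raised when an edge-list or GML file cannot be parsed."""


@dataclass(frozen=True)
class Graph:
    """An undirected, optionally weighted graph.

    Attributes
    ----------
    nodes
        Node identifiers in first-appearance order.  All matrices produced
        from this graph are indexed in this order.
    adjacency
        Dense symmetric ``n x n`` weight matrix with zero diagonal.
    """

    nodes: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        n = len(self.nodes)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} != ({n}, {n})")
        if not np.allclose(A, A.T, atol=0.0):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diagonal(A) != 0.0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if np.any(A < 0.0):
            raise ValueError("edge weights must be non-negative")
        object.__setattr__(self, "adjacency", A)

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.nodes)

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree vector ``g`` with ``g_i = sum_j A_ij``."""
        return self.adjacency.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """``2m = sum_i g_i``, twice the total edge weight."""
        return float(self.adjacency.sum())

    @property
    def num_edges(self) -> int:
        """Number of node pairs with nonzero weight."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.count_nonzero(self.adjacency[iu]))

    def edges(self) -> Iterable[tuple[str, str, float]]:
        """Yield ``(u, v, weight)`` for every edge, in index order."""
        A = self.adjacency
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if A[i, j] != 0.0:
                    yield self.nodes[i], self.nodes[j], float(A[i, j])

    def unweighted(self) -> "Graph":
        """Return a copy with every edge weight set to 1 (binarized)."""
        return Graph(self.nodes, (self.adjacency > 0).astype(float))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Sequence[str] | None = None,
    ) -> "Graph":
        """Build a graph from an iterable of ``(u, v[, w])`` tuples.

        Duplicate edges sum their weights; self-loops are dropped with a
        warning.  The node order is first-appearance order unless an
        explicit ``nodes`` sequence is given.
        """
        order: dict[str, int] = {}
        if nodes is not None:
            for name in nodes:
                order.setdefault(str(name), len(order))
        parsed: list[tuple[str, str, float]] = []
        for e in edges:
            u, v = str(e[0]), str(e[1])
            w = float(e[2]) if len(e) > 2 else 1.0
            if w < 0:
                raise ValueError(f"negative edge weight {w} on edge ({u}, {v})")
            if u == v:
                warnings.warn(
                    f"self-loop on node {u!r} dropped (adjacency diagonal is zero)",
                    stacklevel=2,
                )
                order.setdefault(u, len(order))
                continue
            order.setdefault(u, len(order))
            order.setdefault(v, len(order))
            parsed.append((u, v, w))
        n = len(order)
        A = np.zeros((n, n))
        for u, v, w in parsed:
            i, j = order[u], order[v]
            A[i, j] += w
            A[j, i] += w
        return cls(tuple(order), A)

    @classmethod
    def from_networkx(cls, G: nx.Graph, weighted: bool = True) -> "Graph":
        weight = "weight" if weighted else None
        nodes = tuple(str(v) for v in G.nodes())
        A = nx.to_numpy_array(G, weight=weight)
        np.fill_diagonal(A, 0.0)
        return cls(nodes, A)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        G.add_weighted_edges_from(self.edges())
        return G


# -- file I/O ----------------------------------------------------------------


def read_edge_list(path: str | Path, weighted: bool = True) -> Graph:
    """Read a whitespace-separated edge list.

    Each non-comment line is ``u v`` or ``u v w``.  Lines starting with
    ``#`` and blank lines are ignored.  With ``weighted=False`` the third
    column is ignored and every edge gets weight 1.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphParseError(
                    f"{path}: line {lineno}: expected 2 or 3 fields, got {len(parts)}"
                )
            w = 1.0
            if len(parts) == 3 and weighted:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise GraphParseError(
                        f"{path}: line {lineno}: bad weight {parts[2]!r}"
                    ) from exc
                if w < 0:
                    raise GraphParseError(
                        f"{path}: line {lineno}: negative weight {w}"
                    )
            edges.append((parts[0], parts[1], w))
    return Graph.from_edges(edges)


def write_edge_list(graph: Graph, path: str | Path) -> None:
    """Write ``u v w`` lines in node-index order."""
    with open(path, "w") as fh:
        for u, v, w in graph.edges():
            fh.write(f"{u} {v} {w:g}\n")


def read_gml(path: str | Path, weighted: bool = True) -> Graph:
    """Read a GML graph file (standard dialect), honoring edge weights."""
    try:
        G = nx.read_gml(path)
    except Exception as exc:  # networkx raises several parser error types
        raise GraphParseError(f"{path}: not a parsable GML file: {exc}") from exc
    if G.is_directed():
        G = G.to_undirected()
    return Graph.from_networkx(G, weighted=weighted)


# -- bundled benchmark fixtures ----------------------------------------------

#: name -> (data file, expected (n, |E|), has stored weights)
_BENCHMARKS: dict[str, tuple[str, tuple[int, int], bool]] = {
    "zachary": ("zachary.edgelist", (34, 78), False),
    "dolphins": ("dolphins.edgelist", (62, 159), False),
    "lesmiserables": ("lesmiserables.edgelist", (77, 254), True),
    "politicalbooks": ("politicalbooks.edgelist", (105, 441), False),
    "jazz": ("jazz.edgelist", (198, 2742), False),
    "elegans": ("elegans.edgelist", (453, 2040), False),
}


def available_benchmarks() -> list[str]:
    """Names of benchmark graphs whose fixture files are present."""
    out = []
    for name, (fname, _, _) in _BENCHMARKS.items():
        if resources.files("qubomod.data").joinpath(fname).is_file():
            out.append(name)
    return out


def load_benchmark(name: str, weighted: bool = True) -> Graph:
    """Load a bundled benchmark graph by name.

    ``weighted=False`` binarizes the adjacency for benchmarks that store
    weights (e.g. the Les Miserables coappearance counts).
    """
    key = name.lower()
    if key not in _BENCHMARKS:
        raise KeyError(
            f"unknown benchmark {name!r}; known names: {sorted(_BENCHMARKS)}"
        )
    fname, (n_exp, e_exp), _ = _BENCHMARKS[key]
    ref = resources.files("qubomod.data").joinpath(fname)
    if not ref.is_file():
        raise KeyError(
            f"benchmark {name!r} has no bundled fixture file; available: "
            f"{available_benchmarks()}"
        )
    with resources.as_file(ref) as p:
        g = read_edge_list(p, weighted=weighted)
    if (g.n, g.num_edges) != (n_exp, e_exp):
        raise RuntimeError(
            f"benchmark {name!r} fixture corrupt: got (n={g.n}, E={g.num_edges}), "
            f"expected {(n_exp, e_exp)}"
        )
    return g
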