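"""Interaction-network substrate for the opinion model.

The simulator runs on a simple undirected graph whose structure supplies
three quantities to the dynamics: node degree ``k_i`` (drives individual
conservatism), the common-neighbour count ``n_ij`` of an adjacent pair
(drives embeddedness, the tie-strength proxy), and the neighbour lists
used for per-step partner selection.  Three standard random-graph families
are supported: Barabasi-Albert scale-free, Watts-Strogatz small-world and
Erdos-Renyi random graphs.

Everything is a thin, validated wrapper over :mod:`networkx`; the only
model-specific quantity computed here is :func:`embeddedness`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "OpinionNetwork",
    "generate_ba",
    "generate_ws",
    "generate_er",
    "embeddedness",
    "clustering_coefficient",
    "average_degree",
    "read_edge_list",
    "write_edge_list",
]


class OpinionNetwork:
    """A simple undirected graph with the queries the opinion model needs.

    Nodes are the integers ``0..n-1``.  Wraps an :class:`networkx.Graph`
    and pre-builds neighbour arrays so the hot simulation loop never touches
    networkx adjacency views.
    """

    def __init__(self, graph: nx.Graph):
        n = graph.number_of_nodes()
        if set(graph.nodes) != set(range(n)):
            graph = nx.convert_node_labels_to_integers(graph, ordering="sorted")
        if any(u == v for u, v in graph.edges):
            raise ValueError("self-loops are not allowed")
        self.graph = graph
        self.n = n
        self.neighbors: list[np.ndarray] = [
            np.fromiter(graph.neighbors(i), dtype=np.int64, count=graph.degree(i))
            for i in range(n)
        ]
        self.degrees = np.array([graph.degree(i) for i in range(n)], dtype=np.int64)

    def __len__(self) -> int:
        return self.n

    def degree(self, i: int) -> int:
        return int(self.degrees[i])

    def common_neighbors(self, i: int, j: int) -> int:
        """Number of neighbours shared by ``i`` and ``j`` (symmetric)."""
        return len(list(nx.common_neighbors(self.graph, i, j)))

    def edges(self) -> Iterable[tuple[int, int]]:
        return self.graph.edges()

    def embeddedness_map(self) -> dict[tuple[int, int], float]:
        """Precompute embeddedness for every edge, keyed both ways."""
        out: dict[tuple[int, int], float] = {}
        for u, v in self.graph.edges():
            e = embeddedness(self, u, v)
            out[(u, v)] = e
            out[(v, u)] = e
        return out


def generate_ba(n: int, m_attach: int, seed: int | None = None) -> OpinionNetwork:
    """Barabasi-Albert preferential-attachment graph.

    Parameters
    ----------
    n : total node count (must exceed ``m_attach``)
    m_attach : edges attached from each new node; mean degree is about
        ``2 * m_attach``
    seed : RNG seed; a fixed seed reproduces the edge set exactly
    """
    if m_attach < 1 or n <= m_attach:
        raise ValueError(f"require n > m_attach >= 1, got n={n}, m_attach={m_attach}")
    return OpinionNetwork(nx.barabasi_albert_graph(n, m_attach, seed=seed))


def generate_ws(n: int, k_ring: int, p_rewire: float, seed: int | None = None) -> OpinionNetwork:
    """Watts-Strogatz ring lattice with random rewiring.

    The edge count ``n * k_ring / 2`` — and hence the average degree,
    exactly ``k_ring`` — is preserved by rewiring.
    """
    if k_ring % 2 != 0:
        raise ValueError(f"k_ring must be even, got {k_ring}")
    if not 0 <= p_rewire <= 1:
        raise ValueError(f"p_rewire must be in [0, 1], got {p_rewire}")
    if k_ring >= n:
        raise ValueError(f"require k_ring < n, got k_ring={k_ring}, n={n}")
    return OpinionNetwork(nx.watts_strogatz_graph(n, k_ring, p_rewire, seed=seed))


def generate_er(n: int, p_edge: float, seed: int | None = None) -> OpinionNetwork:
    """Erdos-Renyi G(n, p): each unordered pair is an edge with ``p_edge``."""
    if not 0 <= p_edge <= 1:
        raise ValueError(f"p_edge must be in [0, 1], got {p_edge}")
    return OpinionNetwork(nx.gnp_random_graph(n, p_edge, seed=seed))


def embeddedness(net: OpinionNetwork, i: int, j: int) -> float:
    """Tie strength of the adjacent pair ``(i, j)``: E_ij in [0, 1].

    Defined as the common-neighbour count normalised by the maximum number
    of common neighbours the pair could have, ``(k_i - 1) + (k_j - 1)``.
    Mutual sole neighbours (``k_i = k_j = 1``) are the strongest possible
    tie and get 1.  Interaction is restricted to directly connected pairs,
    so a non-adjacent pair is a usage error.
    """
    if not net.graph.has_edge(i, j):
        raise ValueError(f"nodes {i} and {j} are not adjacent")
    ki, kj = net.degree(i), net.degree(j)
    if ki == 1 and kj == 1:
        return 1.0
    return net.common_neighbors(i, j) / ((ki - 1) + (kj - 1))


def clustering_coefficient(net: OpinionNetwork) -> float:
    """Average local clustering coefficient."""
    if net.n == 0:
        raise ValueError("empty graph")
    return nx.average_clustering(net.graph)


def average_degree(net: OpinionNetwork) -> float:
    """Mean node degree, ``2E / N``."""
    if net.n == 0:
        raise ValueError("empty graph")
    return float(net.degrees.mean())


def write_edge_list(net: OpinionNetwork, path: str | Path) -> None:
    """One edge per line, two whitespace-separated 0-based node ids."""
    with open(path, "w") as fh:
        fh.write(f"# nodes: {net.n}\n")
        for u, v in sorted(net.graph.edges()):
            fh.write(f"{u} {v}\n")


def read_edge_list(path: str | Path, n: int | None = None) -> OpinionNetwork:
    """Read an edge list written by :func:`write_edge_list`.

    ``#`` comments are ignored.  If ``n`` is omitted, a ``# nodes:`` header
    or the maximum node id fixes the node count (isolated trailing nodes
    need an explicit ``n``).
    """
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if n is None and line.startswith("# nodes:"):
                    n = int(line.split(":", 1)[1])
                continue
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {line!r}")
            g.add_edge(int(parts[0]), int(parts[1]))
    if n is None:
        n = (max(g.nodes) + 1) if g.number_of_nodes() else 0
    g.add_nodes_from(range(n))
    return OpinionNetwork(g)
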