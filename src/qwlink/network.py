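"""Undirected simple-graph data model, edge-list I/O and summary statistics.

A :class:`Network` stores an undirected simple graph with contiguous
0-based integer node indices; original node labels from the input file
are preserved for output.  The adjacency matrix is dense — the walk
model operates on matrices of dimension ``2N`` and the intended problem
sizes (up to a few thousand nodes) stay comfortably in memory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkStats",
    "load_edge_list",
    "write_edge_list",
    "common_neighbors",
    "network_stats",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


@dataclass
class Network:
    """Undirected simple graph with contiguous integer node indices.

    Parameters
    ----------
    node_labels : list
        Original labels, position ``i`` is the label of node index ``i``.
    edges : set of tuple
        Unordered edges stored as ``(min, max)`` index pairs.
    """

    node_labels: list
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.node_labels)
        for j, k in self.edges:
            if j == k:
                raise ValueError(f"self-loop on node {j} not allowed")
            if not (0 <= j < n and 0 <= k < n):
                raise IndexError(f"edge ({j}, {k}) out of range for N={n}")
        self.edges = {(min(j, k), max(j, k)) for j, k in self.edges}
        self._adjacency: np.ndarray | None = None
        self._neighbor_sets: list[set[int]] | None = None

    # -- basic structure ------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    @property
    def adjacency(self) -> np.ndarray:
        """Symmetric N x N 0/1 matrix with zero diagonal."""
        if self._adjacency is None:
            a = np.zeros((self.num_nodes, self.num_nodes))
            for j, k in self.edges:
                a[j, k] = a[k, j] = 1.0
            self._adjacency = a
        return self._adjacency

    @property
    def neighbor_sets(self) -> list[set[int]]:
        if self._neighbor_sets is None:
            sets: list[set[int]] = [set() for _ in range(self.num_nodes)]
            for j, k in self.edges:
                sets[j].add(k)
                sets[k].add(j)
            self._neighbor_sets = sets
        return self._neighbor_sets

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_edge_pairs(cls, pairs: Iterable[tuple], labels: Sequence | None = None) -> "Network":
        """Build a network from an iterable of label pairs.

        Labels are mapped to indices in first-appearance order; duplicate
        edges collapse, self-loops are dropped with a warning.
        """
        label_to_idx: dict = {}
        node_labels: list = []
        edges: set[tuple[int, int]] = set()
        if labels is not None:
            for lab in labels:
                if lab not in label_to_idx:
                    label_to_idx[lab] = len(node_labels)
                    node_labels.append(lab)
        for a, b in pairs:
            for lab in (a, b):
                if lab not in label_to_idx:
                    label_to_idx[lab] = len(node_labels)
                    node_labels.append(lab)
            j, k = label_to_idx[a], label_to_idx[b]
            if j == k:
                logger.warning("dropping self-loop on node %r", a)
                continue
            edges.add((min(j, k), max(j, k)))
        return cls(node_labels=node_labels, edges=edges)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        return cls.from_edge_pairs(g.edges(), labels=list(g.nodes()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.num_nodes))
        g.add_edges_from(self.edges)
        return g

    def subgraph_with_edges(self, edges: Iterable[tuple[int, int]]) -> "Network":
        """Same node set, restricted edge set (used for the training graph)."""
        return Network(node_labels=list(self.node_labels), edges=set(edges))

    # -- queries ----------------------------------------------------------

    def has_edge(self, j: int, k: int) -> bool:
        return (min(j, k), max(j, k)) in self.edges

    def non_edges(self) -> list[tuple[int, int]]:
        """All unordered node pairs not present as edges (candidate links)."""
        n = self.num_nodes
        return [
            (j, k)
            for j in range(n)
            for k in range(j + 1, n)
            if (j, k) not in self.edges
        ]


@dataclass(frozen=True)
class NetworkStats:
    """Summary statistics of a network.

    ``clustering`` is the global transitivity (3 x triangles / connected
    triples); ``diameter`` is taken over the largest connected component.
    """

    num_nodes: int
    num_edges: int
    mean_degree: float
    max_degree: int
    diameter: int
    clustering: float
    assortativity: float


def load_edge_list(path: str | Path, delimiter: str | None = None) -> Network:
    """Read an edge list: two labels per line, ``#`` comments ignored.

    Tokens are split on `delimiter` if given, else on commas or any
    whitespace.  Duplicate edges collapse; self-loop lines are dropped
    with a logged warning.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if delimiter is not None:
                tokens = [t for t in line.split(delimiter) if t.strip()]
            else:
                tokens = line.replace(",", " ").split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            pairs.append((tokens[0], tokens[1]))
    return Network.from_edge_pairs(pairs)


def write_edge_list(net: Network, path: str | Path, delimiter: str = " ") -> None:
    """Write one edge per line using the original node labels."""
    with open(path, "w") as fh:
        for j, k in sorted(net.edges):
            fh.write(f"{net.node_labels[j]}{delimiter}{net.node_labels[k]}\n")


def common_neighbors(net: Network, j: int, k: int) -> int:
    """|N(j) ∩ N(k)|; symmetric, and equals the degree of j when j == k."""
    n = net.num_nodes
    if not (0 <= j < n and 0 <= k < n):
        raise IndexError(f"node index out of range for N={n}")
    return len(net.neighbor_sets[j] & net.neighbor_sets[k])


def common_neighbor_matrix(net: Network) -> np.ndarray:
    """Matrix of |Γ(j,k)| for all pairs; the diagonal holds the degrees."""
    a = net.adjacency
    return a @ a


def network_stats(net: Network) -> NetworkStats:
    """Compute summary statistics (diameter over the largest component)."""
    if net.num_nodes < 2:
        raise ValueError("need at least 2 nodes for network statistics")
    g = net.to_networkx()
    n, m = net.num_nodes, net.num_edges
    degrees = net.degrees
    if nx.is_connected(g):
        diam = nx.diameter(g)
    else:
        comp = max(nx.connected_components(g), key=len)
        diam = nx.diameter(g.subgraph(comp))
    if m == 0 or np.allclose(degrees, degrees[0]):
        # Pearson degree correlation is 0/0 on regular graphs
        warnings.warn("degenerate assortativity (regular graph); returning 0")
        rho = 0.0
    else:
        rho = float(nx.degree_assortativity_coefficient(g))
    return NetworkStats(
        num_nodes=n,
        num_edges=m,
        mean_degree=2.0 * m / n,
        max_degree=int(degrees.max()) if n else 0,
        diameter=int(diam),
        clustering=float(nx.transitivity(g)),
        assortativity=rho,
    )
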