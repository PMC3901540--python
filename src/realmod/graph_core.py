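"""Network and partition data model, edge-list I/O, and degree profiles.

Networks are immutable sets of nodes and edges. Edges are ordered
``(source, target)`` pairs; in an undirected network the pair is stored in
canonical (lexicographically sorted) order so that ``(a, b)`` and ``(b, a)``
denote the same edge. Self-loops (e.g. cannibalism in food webs) are legal
and retained.

Degree conventions
------------------
For a directed network, a node's *generality* ``g`` is its number of
successors (out-neighbours; prey, in food-web terms), its *vulnerability*
``v`` its number of predecessors (in-neighbours), and its degree
``d = g + v``. A self-loop contributes 1 to both ``g`` and ``v`` (hence 2 to
``d``), and reciprocal links ``i->j`` and ``j->i`` count as two distinct
edges. For an undirected network the convention ``g = v = d`` is used, with
``d`` counting a self-loop twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GraphError",
    "ParseError",
    "Network",
    "Partition",
    "DegreeProfile",
    "read_edgelist",
    "write_edgelist",
    "read_partition",
    "read_partition_raw",
    "write_partition",
    "read_incidence",
    "bipartite_to_unipartite",
    "degree_profile",
    "symmetrize",
]


class GraphError(ValueError):
    """A contract violation on network or partition data."""


class ParseError(GraphError):
    """An input file could not be parsed."""


def _canonical_edge(u: str, v: str, directed: bool) -> tuple[str, str]:
    if directed or u <= v:
        return (u, v)
    return (v, u)


@dataclass(frozen=True)
class Network:
    """An immutable unipartite network.

    Attributes
    ----------
    nodes : frozenset of str
        Node identifiers (opaque strings).
    edges : frozenset of (str, str)
        Ordered (source, target) pairs; canonically sorted when undirected.
    directed : bool
        Whether edge direction is meaningful.
    bipartite_origin : bool
        True when the network was produced from a bipartite incidence matrix
        (all edges then run from row-nodes to column-nodes).
    """

    nodes: frozenset = field(default_factory=frozenset)
    edges: frozenset = field(default_factory=frozenset)
    directed: bool = True
    bipartite_origin: bool = False

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise GraphError(f"edge endpoint {u!r} or {v!r} missing from node set")
            if not self.directed and u > v:
                raise GraphError(f"undirected edge ({u!r}, {v!r}) not in canonical order")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        directed: bool = True,
        bipartite_origin: bool = False,
    ) -> "Network":
        """Build a network from an edge iterable, deduplicating edges.

        ``nodes`` may list additional (possibly isolated) nodes; edge
        endpoints are always included.
        """
        node_set = {str(x) for x in nodes}
        edge_set = set()
        for u, v in edges:
            u, v = str(u), str(v)
            node_set.add(u)
            node_set.add(v)
            edge_set.add(_canonical_edge(u, v, directed))
        return cls(frozenset(node_set), frozenset(edge_set), directed, bipartite_origin)

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.nodes)

    @property
    def size(self) -> int:
        """Number of edges, E."""
        return len(self.edges)

    @property
    def has_self_loops(self) -> bool:
        return any(u == v for u, v in self.edges)

    @property
    def connectance(self) -> float:
        """Realized fraction of possible (loop-free) links.

        ``E / (n(n-1))`` for directed, ``E / (n(n-1)/2)`` for undirected
        networks, counting non-loop edges only.
        """
        if self.n < 2:
            return 0.0
        possible = self.n * (self.n - 1)
        if not self.directed:
            possible //= 2
        realized = sum(1 for u, v in self.edges if u != v)
        return realized / possible

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def to_networkx(self):
        """Export to a :class:`networkx.DiGraph` or :class:`networkx.Graph`."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.sorted_nodes())
        g.add_edges_from(self.sorted_edges())
        return g

    @classmethod
    def from_networkx(cls, graph, bipartite_origin: bool = False) -> "Network":
        directed = graph.is_directed()
        return cls.from_edges(
            graph.edges(), nodes=graph.nodes(), directed=directed,
            bipartite_origin=bipartite_origin,
        )


@dataclass(frozen=True)
class Partition:
    """A total node -> module assignment with canonical integer labels.

    Labels are contiguous integers ``0..k-1``, assigned by first appearance
    when nodes are visited in lexicographic order, so two partitions that
    group nodes identically compare equal whatever labels they started from.
    """

    assignment: Mapping

    @classmethod
    def from_assignment(cls, mapping: Mapping) -> "Partition":
        relabel: dict = {}
        canonical: dict = {}
        for node in sorted(mapping, key=str):
            label = mapping[node]
            if label not in relabel:
                relabel[label] = len(relabel)
            canonical[str(node)] = relabel[label]
        return cls(canonical)

    def __getitem__(self, node: str) -> int:
        return self.assignment[node]

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and dict(self.assignment) == dict(other.assignment)

    @property
    def n_modules(self) -> int:
        return 1 + max(self.assignment.values()) if self.assignment else 0

    def modules(self) -> dict:
        """Module label -> set of member nodes."""
        out: dict = {}
        for node, label in self.assignment.items():
            out.setdefault(label, set()).add(node)
        return out

    def require_total(self, network: Network) -> None:
        """Raise unless the assignment covers every node of ``network``."""
        missing = sorted(network.nodes - set(self.assignment))
        if missing:
            raise GraphError(f"partition missing nodes: {', '.join(missing)}")


@dataclass(frozen=True)
class DegreeProfile:
    """Per-node degree ``d``, generality ``g`` and vulnerability ``v``."""

    degree: Mapping
    generality: Mapping
    vulnerability: Mapping

    def as_dataframe(self) -> pd.DataFrame:
        nodes = sorted(self.degree)
        return pd.DataFrame(
            {
                "d": [self.degree[n] for n in nodes],
                "g": [self.generality[n] for n in nodes],
                "v": [self.vulnerability[n] for n in nodes],
            },
            index=nodes,
        )


# ---------------------------------------------------------------------------
# I/O


def read_edgelist(path, directed: bool = True) -> Network:
    """Read a whitespace-separated edge list.

    One interaction per line, ``source target``; blank lines and lines
    starting with ``#`` are skipped; a third (e.g. weight) column is ignored
    with a logged warning; duplicate edges collapse.
    """
    path = Path(path)
    edges = []
    warned = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'source target', got {line!r}")
        if len(tokens) > 2 and not warned:
            logger.warning("%s:%d: extra columns ignored (unweighted edges assumed)", path, lineno)
            warned = True
        edges.append((tokens[0], tokens[1]))
    if not edges:
        raise ParseError(f"{path}: no edges")
    return Network.from_edges(edges, directed=directed)


def write_edgelist(network: Network, path) -> None:
    """Write the edge list in the dialect :func:`read_edgelist` reads."""
    lines = [f"{u}\t{v}" for u, v in network.sorted_edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_partition_raw(path) -> dict:
    """Read a ``node<whitespace>module_label`` file into a plain mapping."""
    path = Path(path)
    raw: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'node module', got {line!r}")
        raw[tokens[0]] = tokens[1]
    return raw


def read_partition(path, network: Network) -> Partition:
    """Read a ``node<whitespace>module_label`` file covering the network."""
    raw = read_partition_raw(path)
    unknown = sorted(set(raw) - network.nodes)
    if unknown:
        raise GraphError(f"{path}: nodes not in the network: {', '.join(unknown)}")
    missing = sorted(network.nodes - set(raw))
    if missing:
        raise GraphError(f"{path}: partition missing nodes: {', '.join(missing)}")
    return Partition.from_assignment(raw)


def write_partition(partition: Partition, path) -> None:
    lines = [f"{node}\t{partition[node]}" for node in sorted(partition.assignment)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_incidence(path) -> pd.DataFrame:
    """Read a dense text incidence matrix.

    First row holds column names, first column holds row names, cells are
    whitespace-separated.
    """
    return pd.read_csv(path, sep=r"\s+", index_col=0)


def bipartite_to_unipartite(incidence: pd.DataFrame) -> Network:
    """Turn a 0/1 incidence matrix into a directed row -> column network.

    Every nonzero cell becomes exactly one directed edge, preserving each
    interaction. Row and column names are prefixed ``R:`` / ``C:`` if they
    collide. Quantitative (non-0/1) matrices are refused.
    """
    values = incidence.to_numpy()
    bad = (values != 0) & (values != 1)
    if bad.any():
        raise GraphError("incidence matrix must be 0/1 (quantitative matrices unsupported)")
    rows = [str(r) for r in incidence.index]
    cols = [str(c) for c in incidence.columns]
    if set(rows) & set(cols):
        rows = [f"R:{r}" for r in rows]
        cols = [f"C:{c}" for c in cols]
    edges = [
        (rows[i], cols[j])
        for i in range(len(rows))
        for j in range(len(cols))
        if values[i, j] == 1
    ]
    return Network.from_edges(edges, nodes=rows + cols, directed=True, bipartite_origin=True)


# ---------------------------------------------------------------------------
# Derived quantities


def degree_profile(network: Network) -> DegreeProfile:
    """Compute per-node degree, generality and vulnerability.

    Directed networks: ``g`` = out-degree, ``v`` = in-degree, ``d = g + v``;
    a self-loop adds 1 to each of ``g`` and ``v``. Undirected networks use
    the convention ``g = v = d`` with loops counted twice in ``d``.
    """
    g = {node: 0 for node in network.nodes}
    v = {node: 0 for node in network.nodes}
    if network.directed:
        for u, w in network.edges:
            g[u] += 1
            v[w] += 1
        d = {node: g[node] + v[node] for node in network.nodes}
    else:
        d = {node: 0 for node in network.nodes}
        for u, w in network.edges:
            d[u] += 1
            d[w] += 1  # a loop (u == w) thus counts twice
        g = dict(d)
        v = dict(d)
    return DegreeProfile(d, g, v)


def symmetrize(network: Network) -> Network:
    """Undirected projection: each directed edge becomes an unordered edge.

    Reciprocal pairs collapse to a single edge; self-loops are preserved.
    """
    return Network.from_edges(
        network.edges,
        nodes=network.nodes,
        directed=False,
        bipartite_origin=network.bipartite_origin,
    )
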