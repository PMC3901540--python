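"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: Q is evaluated
straight from its definition on raw edge lists, and the optimal partition is
found by exhaustive enumeration of all set partitions (feasible for n <= 8).
"""

from __future__ import annotations

from typing import Iterable


def set_partitions(items: Iterable) -> Iterable[dict]:
    """Enumerate every partition of ``items`` via restricted growth strings."""
    items = list(items)
    n = len(items)

    def rec(i: int, labels: list, bound: int):
        if i == n:
            yield dict(zip(items, labels))
            return
        for lab in range(bound + 1):
            yield from rec(i + 1, labels + [lab], max(bound, lab + 1))

    if n:
        yield from rec(0, [], 0)


def q_direct(edges: list, labels: dict) -> float:
    """Newman–Girvan Q evaluated directly from its definition.

    ``edges`` are undirected (u, v) pairs (a loop is (u, u)); ``labels``
    maps every node to a module. e_mm is the fraction of edges inside
    module m; a_m the fraction of edge endpoints in m.
    """
    n_edges = len(edges)
    within: dict = {}
    endpoints: dict = {}
    for u, v in edges:
        if labels[u] == labels[v]:
            within[labels[u]] = within.get(labels[u], 0) + 1
        endpoints[labels[u]] = endpoints.get(labels[u], 0) + 1
        endpoints[labels[v]] = endpoints.get(labels[v], 0) + 1
    modules = set(labels.values())
    return sum(
        within.get(m, 0) / n_edges - (endpoints.get(m, 0) / (2 * n_edges)) ** 2
        for m in modules
    )


def max_q_exhaustive(edges: list, nodes: Iterable) -> float:
    """Maximum Q over all set partitions of ``nodes`` (brute force)."""
    best = float("-inf")
    for labels in set_partitions(nodes):
        best = max(best, q_direct(edges, labels))
    return best


def random_loopless_graph(rng, n: int, p: float) -> list:
    """Edge list of a G(n, p) graph on integer-string nodes, >= 1 edge."""
    while True:
        edges = [
            (str(i), str(j))
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        if edges:
            return edges
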