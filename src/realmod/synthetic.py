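"""Synthetic network generators for benchmarking the measures.

Three generators cover the test surface: planted-partition graphs (known
ground-truth modules, edges denser within than between), Erdős–Rényi
baselines, and an exact-count fixture that realizes a requested (E, W)
within/between edge split — the worked-example shape of a cartoon modular
network with 36 interactions of which 31 are within modules.
"""

from __future__ import annotations

import numpy as np

from .graph_core import GraphError, Network, Partition

__all__ = [
    "planted_partition",
    "erdos_renyi",
    "fixture_network",
    "balanced_bisection",
]


def _node_names(n: int) -> list[str]:
    width = max(1, len(str(n - 1)))
    return [f"v{i:0{width}d}" for i in range(n)]


def planted_partition(
    sizes: tuple[int, ...],
    p_in: float,
    p_out: float,
    directed: bool = False,
    seed: int = 0,
) -> tuple[Network, Partition]:
    """Generate a planted-partition graph and its ground-truth partition.

    Each within-module (ordered, if directed) node pair receives an edge
    with probability ``p_in``, each between-module pair with ``p_out``;
    self-loops are never drawn. Requires ``0 <= p_out <= p_in <= 1``
    (anti-modular specs refused). Bit-reproducible under a fixed seed.
    """
    if not sizes or any(s < 1 for s in sizes):
        raise GraphError("module sizes must be positive integers")
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise GraphError(f"need 0 <= p_out <= p_in <= 1, got p_in={p_in}, p_out={p_out}")
    n = int(sum(sizes))
    labels = np.repeat(np.arange(len(sizes)), sizes)
    names = _node_names(n)
    rng = np.random.default_rng(seed)
    same = labels[:, None] == labels[None, :]
    prob = np.where(same, p_in, p_out)
    draws = rng.random((n, n)) < prob
    if directed:
        np.fill_diagonal(draws, False)
    else:
        draws &= np.triu(np.ones((n, n), dtype=bool), k=1)
    sources, targets = np.nonzero(draws)
    edges = [(names[i], names[j]) for i, j in zip(sources, targets)]
    network = Network.from_edges(edges, nodes=names, directed=directed)
    partition = Partition.from_assignment({names[i]: int(labels[i]) for i in range(n)})
    return network, partition


def erdos_renyi(n: int, p: float, seed: int = 0, directed: bool = False) -> Network:
    """Erdős–Rényi G(n, p) baseline (no self-loops)."""
    network, _ = planted_partition((n,), p_in=p, p_out=p, directed=directed, seed=seed)
    return network


def fixture_network(
    n_edges: int = 36,
    n_within: int = 31,
    sizes: tuple[int, ...] = (9, 9, 9, 9),
    seed: int = 0,
) -> tuple[Network, Partition]:
    """Undirected network with exactly ``n_edges`` edges, ``n_within`` within-module.

    Edges are sampled uniformly without replacement from the within- and
    between-module pair pools, so realized_modularity on the output returns
    (W, E) = (n_within, n_edges) exactly on every seed. The defaults give
    the worked example Q_R = 31/36 ≈ 0.86, Q'_R ≈ 0.72.
    """
    if n_edges < 1:
        raise GraphError("need at least 1 edge")
    if n_within > n_edges:
        raise GraphError(f"W = {n_within} cannot exceed E = {n_edges}")
    if n_within < 0:
        raise GraphError("W must be non-negative")
    n = int(sum(sizes))
    labels = np.repeat(np.arange(len(sizes)), sizes)
    names = _node_names(n)
    within = [(i, j) for i in range(n) for j in range(i + 1, n) if labels[i] == labels[j]]
    between = [(i, j) for i in range(n) for j in range(i + 1, n) if labels[i] != labels[j]]
    n_between = n_edges - n_within
    if n_within > len(within) or n_between > len(between):
        raise GraphError(
            f"infeasible edge counts for module sizes {tuple(sizes)}: "
            f"within capacity {len(within)} (requested {n_within}), "
            f"between capacity {len(between)} (requested {n_between})"
        )
    rng = np.random.default_rng(seed)
    picks = []
    if n_within:
        picks.extend(within[k] for k in rng.choice(len(within), n_within, replace=False))
    if n_between:
        picks.extend(between[k] for k in rng.choice(len(between), n_between, replace=False))
    edges = [(names[i], names[j]) for i, j in picks]
    network = Network.from_edges(edges, nodes=names, directed=False)
    partition = Partition.from_assignment({names[i]: int(labels[i]) for i in range(n)})
    return network, partition


def balanced_bisection(network: Network, seed: int | np.random.Generator = 0) -> Partition:
    """Random balanced two-module partition of a network's nodes.

    Useful as the randomization under which Q'_R is expected to centre on
    0: a uniformly random equal split puts just under half of all node
    pairs within modules.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = network.sorted_nodes()
    order = rng.permutation(len(nodes))
    half = len(nodes) // 2
    assignment = {nodes[int(i)]: (0 if rank < half else 1) for rank, i in enumerate(order)}
    return Partition.from_assignment(assignment)
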