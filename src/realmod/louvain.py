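"""Louvain community detection (two-phase greedy modularity maximization).

Phase 1 sweeps the nodes in a seeded-random order, greedily moving each node
to the neighbouring community giving the largest strictly positive
modularity gain (ties broken toward the lowest community label, for
determinism). Phase 2 aggregates each community into a super-node whose
self-loop carries the within-community weight, and the two phases repeat
until a full pass improves Q by less than 1e-8.

The implementation is unweighted at the interface; aggregation uses integer
edge multiplicities internally. Directed input is symmetrized first, since
modularity optimization here operates on the undirected projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import GraphError, Network, Partition, symmetrize
from .measures import PartitionScore, RealizedModularityResult, newman_girvan_q, realized_modularity

__all__ = ["DetectionResult", "louvain", "best_louvain", "score_partition"]

#: a pass must improve Q by at least this much to continue
_Q_TOLERANCE = 1e-8
#: float guard when comparing move gains
_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class DetectionResult:
    """A detected partition with its per-pass modularity trace."""

    partition: Partition
    q_trace: tuple
    passes: int
    seed: int

    @property
    def q(self) -> float:
        """Newman–Girvan Q of the final partition."""
        return self.q_trace[-1]


def _local_move(adj: list, rng: np.random.Generator) -> tuple[list, bool]:
    """Phase 1: greedy node moves until no move improves Q.

    ``adj`` is a symmetric adjacency list of dicts with self-loops stored at
    twice their weight (matrix convention A_ii = 2w). Returns the community
    labels renumbered 0..c-1 and whether any node moved.
    """
    n = len(adj)
    k = [sum(nb.values()) for nb in adj]
    two_m = sum(k)
    comm = list(range(n))
    sigma_tot = list(k)
    order = [int(i) for i in rng.permutation(n)]
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in order:
            c0 = comm[i]
            ki = k[i]
            links: dict = {}
            for j, w in adj[i].items():
                if j != i:
                    cj = comm[j]
                    links[cj] = links.get(cj, 0.0) + w
            sigma_tot[c0] -= ki
            # gain of membership in c, up to constants: k_{i,in}(c) - sigma_tot(c)*k_i/(2m)
            best_c = c0
            best_gain = links.get(c0, 0.0) - sigma_tot[c0] * ki / two_m
            for c in sorted(links):
                if c == c0:
                    continue
                gain = links[c] - sigma_tot[c] * ki / two_m
                if gain > best_gain + _GAIN_EPS:
                    best_gain = gain
                    best_c = c
            comm[i] = best_c
            sigma_tot[best_c] += ki
            if best_c != c0:
                improved = True
                moved_any = True
    relabel: dict = {}
    out = []
    for c in comm:
        if c not in relabel:
            relabel[c] = len(relabel)
        out.append(relabel[c])
    return out, moved_any


def _aggregate(adj: list, comm: list) -> list:
    """Phase 2: collapse communities into super-nodes.

    Within-community weight accumulates on the diagonal; because the
    symmetric adjacency stores every non-loop edge twice, the diagonal
    automatically carries the A_cc = 2w convention.
    """
    n_comms = max(comm) + 1
    new: list = [dict() for _ in range(n_comms)]
    for i, neighbours in enumerate(adj):
        ci = comm[i]
        for j, w in neighbours.items():
            cj = comm[j]
            new[ci][cj] = new[ci].get(cj, 0.0) + w
    return new


def louvain(network: Network, seed: int = 0) -> DetectionResult:
    """Detect communities by two-phase modularity optimization.

    Parameters
    ----------
    network : Network
        Any network with at least one edge; directed networks are
        symmetrized before detection.
    seed : int
        Seeds the node sweep order, making runs reproducible.
    """
    und = symmetrize(network) if network.directed else network
    if und.size == 0:
        raise GraphError("community detection undefined for edgeless network")
    nodes = und.sorted_nodes()
    index = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    adj: list = [dict() for _ in range(n)]
    for u, v in und.edges:
        iu, iv = index[u], index[v]
        if iu == iv:
            adj[iu][iu] = adj[iu].get(iu, 0.0) + 2.0
        else:
            adj[iu][iv] = adj[iu].get(iv, 0.0) + 1.0
            adj[iv][iu] = adj[iv].get(iu, 0.0) + 1.0

    rng = np.random.default_rng(seed)
    membership = list(range(n))
    q_trace: list = []
    prev_q = None
    while True:
        comm, moved = _local_move(adj, rng)
        membership = [comm[c] for c in membership]
        partition = Partition.from_assignment({nodes[i]: membership[i] for i in range(n)})
        q = newman_girvan_q(und, partition).q
        q_trace.append(q)
        if not moved:
            break
        if prev_q is not None and q - prev_q < _Q_TOLERANCE:
            break
        if max(comm) == 0:
            break
        prev_q = q
        adj = _aggregate(adj, comm)
    return DetectionResult(partition, tuple(q_trace), len(q_trace), seed)


def best_louvain(network: Network, seed: int = 0, restarts: int = 1) -> DetectionResult:
    """Best-of-k restarts: run Louvain with k derived seeds, keep max Q."""
    if restarts < 1:
        raise GraphError("at least 1 restart required")
    child_seeds = np.random.SeedSequence(seed).generate_state(restarts)
    best = None
    for child in child_seeds:
        result = louvain(network, seed=int(child) & 0x7FFFFFFF)
        if best is None or result.q > best.q:
            best = result
    return best


def score_partition(
    network: Network, partition: Partition
) -> tuple[PartitionScore, RealizedModularityResult]:
    """Score any externally produced partition by both Q and Q_R.

    Q is evaluated on the undirected projection; Q_R on the native edge
    set. Returning both lets competing partitions — from walktrap,
    spinglass, edge betweenness or any other method — be ranked a
    posteriori on a common scale.
    """
    und = symmetrize(network) if network.directed else network
    score = newman_girvan_q(und, partition)
    realized = realized_modularity(network, partition)
    return score, realized
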