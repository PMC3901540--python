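"""Partition quality measures: realized modularity and Newman–Girvan Q.

Realized modularity is an a-posteriori goodness-of-fit for a community
partition: of the E interactions in the network, if W run between members of
the same module then

    Q_R  = W / E,
    Q'_R = 2 Q_R - 1.

Q_R is 1 when no edge crosses modules and 1/2 when within- and
between-module edges are equally numerous; Q'_R rescales this so that random
balanced bisections centre on 0 and negative values flag partitions with
more between- than within-module interactions. Both are agnostic to how the
partition was obtained, so they can rank partitions from any detection
method on a common scale.

Newman–Girvan modularity Q = sum_m (e_mm - a_m^2) — with e_mm the fraction
of edges inside module m and a_m the fraction of edge endpoints in m — is
provided for scoring partitions on the undirected projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .graph_core import GraphError, Network, Partition

__all__ = [
    "RealizedModularityResult",
    "PartitionScore",
    "realized_modularity",
    "q_prime",
    "newman_girvan_q",
]


@dataclass(frozen=True)
class RealizedModularityResult:
    """W, E and the derived Q_R, Q'_R for one (network, partition) pair."""

    n_edges: int
    n_within: int
    q_r: float
    q_prime: float

    def to_record(self) -> dict:
        return {
            "e": self.n_edges,
            "w": self.n_within,
            "qr": self.q_r,
            "qprime": self.q_prime,
        }


@dataclass(frozen=True)
class PartitionScore:
    """Newman–Girvan Q with its per-module components."""

    q: float
    n_modules: int
    within_fraction: Mapping  # e_mm per module
    degree_fraction: Mapping  # a_m per module


def q_prime(qr: float) -> float:
    """Rescale Q_R from [0, 1] to Q'_R = 2*Q_R - 1 in [-1, 1]."""
    if not 0.0 <= qr <= 1.0:
        raise GraphError(f"Q_R must lie in [0, 1], got {qr!r}")
    return 2.0 * qr - 1.0


def realized_modularity(network: Network, partition: Partition) -> RealizedModularityResult:
    """Count within-module edges and return Q_R = W/E and Q'_R.

    Computed on the network's native edge set (directed if so stored);
    self-loops are within-module by construction. Undefined on edgeless
    networks.
    """
    if network.size == 0:
        raise GraphError("realized modularity undefined for edgeless network")
    partition.require_total(network)
    w = sum(1 for u, v in network.edges if partition[u] == partition[v])
    qr = w / network.size
    return RealizedModularityResult(network.size, w, qr, q_prime(qr))


def newman_girvan_q(network: Network, partition: Partition) -> PartitionScore:
    """Newman–Girvan modularity of a partition on an undirected network.

    ``Q = sum_m (e_mm - a_m^2)`` with ``e_mm`` the fraction of edges whose
    two endpoints are in module m and ``a_m`` the fraction of edge endpoints
    in m. A self-loop contributes one within-module edge and both its
    endpoints to the node's module.
    """
    if network.directed:
        raise GraphError("Newman–Girvan Q requires an undirected network; symmetrize() first")
    if network.size == 0:
        raise GraphError("modularity undefined for edgeless network")
    partition.require_total(network)
    e_count: dict = {}
    endpoint_count: dict = {}
    for u, v in network.edges:
        mu, mv = partition[u], partition[v]
        if mu == mv:
            e_count[mu] = e_count.get(mu, 0) + 1
        endpoint_count[mu] = endpoint_count.get(mu, 0) + 1
        endpoint_count[mv] = endpoint_count.get(mv, 0) + 1
    e_total = network.size
    labels = range(partition.n_modules)
    e_mm = {m: e_count.get(m, 0) / e_total for m in labels}
    a_m = {m: endpoint_count.get(m, 0) / (2 * e_total) for m in labels}
    q = sum(e_mm[m] - a_m[m] ** 2 for m in labels)
    return PartitionScore(q, partition.n_modules, e_mm, a_m)
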