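"""Degree-profile-preserving Bernoulli null model.

For each ordered pair of nodes (i, j) of a directed network, the probability
that i links to j in a random replicate is

    P(i -> j) = 1/2 (g_i / d_i + v_j / d_j),

with g the node's generality (successor count), v its vulnerability
(predecessor count) and d = g + v its degree. Replicates are drawn by an
independent Bernoulli trial per ordered pair, so each replicate conserves
the expected generality/vulnerability structure of the empirical network
while the realized edges vary.

Caveat: as defined, the pair probability need not conserve expected
connectance exactly — e.g. a pure-source node i (g_i = d_i) paired with a
pure-sink node j (v_j = d_j) forces P(i -> j) = 1 whatever the network's
density. The formula is implemented verbatim as the default; an alternative
"size" normalization P = 1/2 (g_i/n + v_j/n) is available via
``normalization="size"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .graph_core import GraphError, Network, Partition, degree_profile, symmetrize
from .louvain import louvain
from .measures import newman_girvan_q, realized_modularity

__all__ = [
    "LinkProbabilityMatrix",
    "NullEnsemble",
    "link_probabilities",
    "sample_null",
    "null_ensemble",
]

#: replicates with fewer edges than this are discarded (edgeless or
#: single-edge draws carry no community structure to detect)
_MIN_REPLICATE_EDGES = 2


@dataclass(frozen=True)
class LinkProbabilityMatrix:
    """Dense P(i -> j) over the ordered node pairs of a network.

    ``nodes`` fixes the row/column order; rows are sources. Diagonal
    entries are zero unless the empirical network contains self-loops, in
    which case self-pairs are sampled like any other pair.
    """

    nodes: tuple
    probabilities: np.ndarray
    allow_self: bool

    @property
    def expected_edges(self) -> float:
        """Expected edge count of a replicate, sum of all pair probabilities."""
        return float(self.probabilities.sum())

    @property
    def edge_count_stderr(self) -> float:
        """Standard deviation of a replicate's edge count (sum of Bernoullis)."""
        p = self.probabilities
        return float(np.sqrt((p * (1.0 - p)).sum()))


@dataclass(frozen=True)
class NullEnsemble:
    """Per-replicate Q and Q'_R statistics from a null-model run."""

    q_values: tuple
    q_prime_values: tuple
    requested: int
    retained: int
    discarded: int
    seed: int


def link_probabilities(network: Network, normalization: str = "degree") -> LinkProbabilityMatrix:
    """Build the pair-probability matrix for a directed network.

    ``normalization="degree"`` is the verbatim formula above;
    ``"size"`` divides by the node count n instead of d. Nodes with d = 0
    get zero probability on all their pairs (they stay isolated in every
    replicate). Probabilities are clipped to [0, 1].
    """
    if not network.directed:
        raise GraphError(
            "the null model needs a directed network: under the undirected "
            "g = v = d convention every connected pair would get P = 1"
        )
    if normalization not in ("degree", "size"):
        raise GraphError(f"unknown normalization {normalization!r}")
    nodes = tuple(network.sorted_nodes())
    profile = degree_profile(network)
    g = np.array([profile.generality[x] for x in nodes], dtype=float)
    v = np.array([profile.vulnerability[x] for x in nodes], dtype=float)
    d = np.array([profile.degree[x] for x in nodes], dtype=float)
    if normalization == "degree":
        denom = d
    else:
        denom = np.full_like(d, float(len(nodes)))
    with np.errstate(divide="ignore", invalid="ignore"):
        out_ratio = np.where(denom > 0, g / denom, 0.0)
        in_ratio = np.where(denom > 0, v / denom, 0.0)
    p = 0.5 * (out_ratio[:, None] + in_ratio[None, :])
    zero = d == 0
    p[zero, :] = 0.0
    p[:, zero] = 0.0
    allow_self = network.has_self_loops
    if not allow_self:
        np.fill_diagonal(p, 0.0)
    return LinkProbabilityMatrix(nodes, np.clip(p, 0.0, 1.0), allow_self)


def sample_null(
    network: Network,
    seed: int,
    probabilities: LinkProbabilityMatrix | None = None,
    normalization: str = "degree",
) -> Network:
    """Draw one Bernoulli replicate of a directed network.

    The node set is preserved (isolated nodes are legal, and an edgeless
    draw is legal — the ensemble caller discards it).
    """
    lpm = probabilities if probabilities is not None else link_probabilities(network, normalization)
    rng = np.random.default_rng(seed)
    draws = rng.random(lpm.probabilities.shape) < lpm.probabilities
    sources, targets = np.nonzero(draws)
    edges = [(lpm.nodes[i], lpm.nodes[j]) for i, j in zip(sources, targets)]
    return Network.from_edges(edges, nodes=lpm.nodes, directed=True)


def _default_detector(replicate: Network, seed: int) -> Partition:
    return louvain(replicate, seed=seed).partition


def null_ensemble(
    network: Network,
    replicates: int = 1000,
    seed: int = 0,
    detector: Callable[[Network, int], Union[Partition, "object"]] | None = None,
    normalization: str = "degree",
) -> NullEnsemble:
    """Generate pseudo-random replicates and score each detected partition.

    For each retained replicate a partition is detected (Louvain by
    default, or any ``detector(network, seed)`` returning a Partition or an
    object with a ``.partition``), and its Newman–Girvan Q and realized
    Q'_R are recorded. Replicate seeds derive deterministically from the
    master seed. Replicates with fewer than 2 edges are discarded and
    counted, not resampled.
    """
    if replicates < 1:
        raise GraphError("at least 1 replicate required")
    detect = detector if detector is not None else _default_detector
    lpm = link_probabilities(network, normalization)
    states = np.random.SeedSequence(seed).generate_state(2 * replicates)
    q_values: list = []
    q_prime_values: list = []
    discarded = 0
    for r in range(replicates):
        sample_seed = int(states[2 * r]) & 0x7FFFFFFF
        detect_seed = int(states[2 * r + 1]) & 0x7FFFFFFF
        replicate = sample_null(network, sample_seed, probabilities=lpm)
        if replicate.size < _MIN_REPLICATE_EDGES:
            discarded += 1
            continue
        detected = detect(replicate, detect_seed)
        partition = getattr(detected, "partition", detected)
        q = newman_girvan_q(symmetrize(replicate), partition).q
        q_prime = realized_modularity(replicate, partition).q_prime
        q_values.append(q)
        q_prime_values.append(q_prime)
    if not q_values:
        raise GraphError(
            f"all {replicates} replicates were degenerate (< {_MIN_REPLICATE_EDGES} edges); "
            "the network is too sparse for this null model"
        )
    return NullEnsemble(
        tuple(q_values), tuple(q_prime_values), replicates, len(q_values), discarded, seed
    )
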