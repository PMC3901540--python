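import pytest

from realmod import Network, Partition, fixture_network


@pytest.fixture
def two_triangles() -> Network:
    """Two disjoint triangles: the textbook Q = 0.5 graph."""
    return Network.from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
        directed=False,
    )


@pytest.fixture
def triangle_partition() -> Partition:
    return Partition.from_assignment(
        {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
    )


@pytest.fixture
def four_cycle() -> Network:
    return Network.from_edges(
        [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")], directed=False
    )


@pytest.fixture
def worked_example():
    """36-edge, 31-within fixture mirroring the cartoon modular network."""
    return fixture_network(n_edges=36, n_within=31, sizes=(9, 9, 9, 9), seed=0)
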