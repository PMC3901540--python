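import logging

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from realmod import (
    GraphError,
    Network,
    ParseError,
    Partition,
    bipartite_to_unipartite,
    degree_profile,
    read_edgelist,
    read_incidence,
    read_partition,
    symmetrize,
    write_edgelist,
    write_partition,
)

node_ids = st.text(alphabet="abcdef", min_size=1, max_size=2)
edge_lists = st.lists(st.tuples(node_ids, node_ids), min_size=1, max_size=30)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadEdgelist:
    def test_parses_directed_triangle(self, tmp_path):
        net = read_edgelist(_write(tmp_path, "x.edges", "a b\nb c\nc a\n"), directed=True)
        assert net.n == 3 and net.size == 3 and net.directed

    def test_duplicates_collapse(self, tmp_path):
        net = read_edgelist(_write(tmp_path, "x.edges", "a b\na b\n"))
        assert net.size == 1

    def test_undirected_reverse_duplicates_collapse(self, tmp_path):
        net = read_edgelist(_write(tmp_path, "x.edges", "a b\nb a\n"), directed=False)
        assert net.size == 1

    def test_comments_skipped_and_extra_columns_warn(self, tmp_path, caplog):
        path = _write(tmp_path, "x.edges", "# comment\na b x 1.0\n")
        with caplog.at_level(logging.WARNING):
            net = read_edgelist(path)
        assert net.size == 1
        assert any("extra columns" in rec.message for rec in caplog.records)

    def test_single_token_line_names_line_number(self, tmp_path):
        path = _write(tmp_path, "x.edges", "a b\nlonely\n")
        with pytest.raises(ParseError, match=":2"):
            read_edgelist(path)

    def test_empty_file_is_an_error(self, tmp_path):
        with pytest.raises(ParseError, match="no edges"):
            read_edgelist(_write(tmp_path, "x.edges", "# nothing\n"))


class TestReadPartition:
    @pytest.fixture
    def net(self, tmp_path):
        return read_edgelist(_write(tmp_path, "n.edges", "a b\nb c\n"))

    def test_basic(self, net, tmp_path):
        part = read_partition(_write(tmp_path, "p.txt", "a 0\nb 0\nc 1\n"), net)
        assert part.n_modules == 2

    def test_missing_node_named(self, net, tmp_path):
        with pytest.raises(GraphError, match="c"):
            read_partition(_write(tmp_path, "p.txt", "a 0\nb 0\n"), net)

    def test_unknown_node_rejected(self, net, tmp_path):
        with pytest.raises(GraphError, match="zz"):
            read_partition(_write(tmp_path, "p.txt", "a 0\nb 0\nc 1\nzz 1\n"), net)

    def test_labels_canonicalized_by_first_appearance(self, net, tmp_path):
        part = read_partition(_write(tmp_path, "p.txt", "a x\nb x\nc y\n"), net)
        assert [part[n] for n in "abc"] == [0, 0, 1]


class TestBipartite:
    def test_identity_incidence(self):
        inc = pd.DataFrame([[1, 0], [0, 1]], index=["r1", "r2"], columns=["c1", "c2"])
        net = bipartite_to_unipartite(inc)
        assert net.n == 4 and net.size == 2
        assert net.directed and net.bipartite_origin

    def test_all_ones_degree_profile(self):
        inc = pd.DataFrame([[1, 1, 1], [1, 1, 1]], index=["r1", "r2"], columns=["c1", "c2", "c3"])
        net = bipartite_to_unipartite(inc)
        prof = degree_profile(net)
        assert net.size == 6
        assert all(prof.generality[r] == 3 and prof.vulnerability[r] == 0 for r in ("r1", "r2"))
        assert all(prof.generality[c] == 0 for c in ("c1", "c2", "c3"))

    def test_quantitative_cells_rejected(self):
        inc = pd.DataFrame([[0.5]], index=["r"], columns=["c"])
        with pytest.raises(GraphError, match="0/1"):
            bipartite_to_unipartite(inc)

    def test_name_collision_namespaced(self):
        inc = pd.DataFrame([[1]], index=["x"], columns=["x"])
        net = bipartite_to_unipartite(inc)
        assert net.nodes == {"R:x", "C:x"}

    def test_incidence_roundtrip_via_text(self, tmp_path):
        path = _write(tmp_path, "inc.txt", "name c1 c2\nr1 1 0\nr2 1 1\n")
        net = bipartite_to_unipartite(read_incidence(path))
        assert net.size == 3 and ("r2", "c2") in net.edges


class TestDegreeProfile:
    def test_chain(self):
        net = Network.from_edges([("a", "b"), ("b", "c")])
        prof = degree_profile(net)
        assert [prof.generality[x] for x in "abc"] == [1, 1, 0]
        assert [prof.vulnerability[x] for x in "abc"] == [0, 1, 1]
        assert [prof.degree[x] for x in "abc"] == [1, 2, 1]

    def test_self_loop_counts_in_both_directions(self):
        prof = degree_profile(Network.from_edges([("a", "a")]))
        assert prof.generality["a"] == 1 and prof.vulnerability["a"] == 1
        assert prof.degree["a"] == 2

    def test_reciprocal_edges_are_two_edges(self):
        net = Network.from_edges([("a", "b"), ("b", "a")])
        prof = degree_profile(net)
        assert net.size == 2
        assert prof.degree["a"] == 2 and prof.degree["b"] == 2

    def test_undirected_convention(self, four_cycle):
        prof = degree_profile(four_cycle)
        assert all(prof.degree[n] == prof.generality[n] == prof.vulnerability[n] == 2
                   for n in four_cycle.nodes)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(edge_lists)
    def test_degree_sums_match_edge_count(self, raw_edges):
        net = Network.from_edges(raw_edges, directed=True)
        prof = degree_profile(net)
        assert sum(prof.generality.values()) == net.size
        assert sum(prof.vulnerability.values()) == net.size
        assert sum(prof.degree.values()) == 2 * net.size


class TestSymmetrizeAndRoundtrip:
    def test_reciprocal_collapses(self):
        und = symmetrize(Network.from_edges([("a", "b"), ("b", "a")]))
        assert und.size == 1 and not und.directed

    def test_single_edge_and_loops_preserved(self):
        und = symmetrize(Network.from_edges([("b", "a"), ("c", "c")]))
        assert und.edges == frozenset({("a", "b"), ("c", "c")})

    def test_empty_edge_set_identity(self):
        und = symmetrize(Network(frozenset({"a"}), frozenset(), directed=True))
        assert und.size == 0 and und.nodes == {"a"}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(raw_edges=edge_lists, directed=st.booleans())
    def test_write_read_roundtrip(self, tmp_path_factory, raw_edges, directed):
        net = Network.from_edges(raw_edges, directed=directed)
        path = tmp_path_factory.mktemp("rt") / "net.edges"
        write_edgelist(net, path)
        back = read_edgelist(path, directed=directed)
        assert back.edges == net.edges and back.nodes == net.nodes

    def test_partition_roundtrip(self, tmp_path, two_triangles, triangle_partition):
        path = tmp_path / "p.txt"
        write_partition(triangle_partition, path)
        assert read_partition(path, two_triangles) == triangle_partition


class TestNetworkInvariants:
    def test_edge_endpoint_must_be_a_node(self):
        with pytest.raises(GraphError):
            Network(frozenset({"a"}), frozenset({("a", "b")}))

    def test_connectance(self, four_cycle):
        assert four_cycle.connectance == pytest.approx(4 / 6)

    def test_networkx_roundtrip(self, two_triangles):
        assert Network.from_networkx(two_triangles.to_networkx()) == two_triangles
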