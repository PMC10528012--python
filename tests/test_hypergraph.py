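import io

import numpy as np
import pytest

from hypervn import (
    Hypergraph,
    HypergraphError,
    read_bipartite_tsv,
    read_hyperedge_list,
    write_bipartite_tsv,
    write_hyperedge_list,
)

from _oracles import bfs_components, line_graph_adjacency, two_section_edges
from conftest import random_hypergraphs


class TestReadHyperedgeList:
    def test_fig1_file(self, fig1_text):
        h = read_hyperedge_list(fig1_text)
        assert h.num_nodes == 11
        assert h.num_edges == 4
        assert h.cardinalities == (3, 6, 4, 4)

    def test_singleton(self):
        h = read_hyperedge_list("a\n")
        assert h.num_nodes == 1 and h.num_edges == 1 and h.cardinality(0) == 1

    def test_duplicate_hyperedges_kept(self):
        h = read_hyperedge_list("1,2\n1,2")
        assert h.num_edges == 2
        assert h.members(0) == h.members(1)

    def test_comments_whitespace_and_within_line_duplicates(self):
        h = read_hyperedge_list("# header\n a , b , a \n\nb,c  # trailing\n")
        assert h.num_edges == 2
        assert h.members(0) == frozenset({"a", "b"})
        assert h.members(1) == frozenset({"b", "c"})

    @pytest.mark.parametrize("text", ["", "# only comments\n", "a\n,,\n"])
    def test_rejects_empty_input_and_empty_lines(self, text):
        with pytest.raises(HypergraphError):
            read_hyperedge_list(text)

    def test_node_order_is_first_appearance(self, fig1_text):
        h = read_hyperedge_list(fig1_text)
        assert h.nodes[:4] == ("1", "2", "3", "4")


class TestRoundTrip:
    @pytest.mark.parametrize("writer,reader", [
        (write_hyperedge_list, read_hyperedge_list),
        (write_bipartite_tsv, read_bipartite_tsv),
    ])
    def test_lossless_up_to_set_order(self, writer, reader):
        for h in random_hypergraphs(5, seed=11):
            buf = io.StringIO()
            writer(h, buf)
            h2 = reader(buf.getvalue())
            assert h2.num_edges == h.num_edges
            assert [h2.members(j) for j in range(h2.num_edges)] == \
                   [h.members(j) for j in range(h.num_edges)]

    def test_tsv_rejects_malformed_rows(self):
        with pytest.raises(HypergraphError):
            read_bipartite_tsv("a\tb\tc\n")


class TestMatrices:
    def test_incidence_fig1(self, fig1):
        B = fig1.incidence_matrix()
        assert B.shape == (4, 11)
        assert B.sum(axis=1).tolist() == [3, 6, 4, 4]
        assert B[:, fig1.node_index("v4")].sum() == 2  # v4 in e2 and e4

    def test_incidence_single_hyperedge(self):
        assert Hypergraph([["1", "2"]]).incidence_matrix().tolist() == [[1, 1]]

    def test_adjacency_fig1(self, fig1):
        A = fig1.adjacency_matrix()
        i = {v: fig1.node_index(v) for v in fig1.nodes}
        assert A[i["v1"], i["v4"]] == 0  # no shared hyperedge
        assert A[i["v2"], i["v4"]] == 1  # share e2

    def test_adjacency_is_sign_of_gram_matrix(self):
        for h in random_hypergraphs(5, seed=3):
            B = h.incidence_matrix().astype(int)
            G = B.T @ B
            np.fill_diagonal(G, 0)
            assert np.array_equal(h.adjacency_matrix(), np.sign(G))

    def test_single_hyperedge_adjacency_is_clique(self):
        A = Hypergraph([["1", "2", "3"]]).adjacency_matrix()
        assert np.array_equal(A, np.ones((3, 3)) - np.eye(3))

    def test_degree_conservation(self):
        for h in random_hypergraphs(8, seed=5):
            total_hyperdegree = sum(h.hyperdegree(v) for v in h.nodes)
            assert total_hyperdegree == sum(h.cardinalities)


class TestTwoSection:
    def test_fig1_edge_count_matches_enumeration_oracle(self, fig1):
        sets = [fig1.members(j) for j in range(4)]
        expected = two_section_edges(sets)
        assert len(expected) == 26
        g = fig1.two_section_graph()
        assert {tuple(sorted(e)) for e in g.edges()} == expected

    def test_single_hyperedge_is_complete_graph(self):
        g = Hypergraph([[str(i) for i in range(6)]]).two_section_graph()
        assert g.number_of_edges() == 15

    def test_disjoint_hyperedges_give_disjoint_cliques(self):
        h = Hypergraph([["a", "b", "c"], ["d", "e"]])
        g = h.two_section_graph()
        assert g.number_of_edges() == 4
        comps = bfs_components(list(g.nodes()), set(g.edges()))
        assert sorted(len(c) for c in comps) == [2, 3]


class TestOverlapsAndLineGraphs:
    def test_fig1_overlaps(self, fig1):
        assert fig1.overlap_size(1, 2) == 3
        assert fig1.overlap_size(0, 3) == 0
        with pytest.raises(ValueError):
            fig1.overlap_size(2, 2)

    def test_duplicate_hyperedges_overlap_fully(self):
        h = Hypergraph([["1", "2", "3"], ["1", "2", "3"]])
        assert h.overlap_size(0, 1) == 3
        assert h.max_overlap() == 3

    def test_max_overlap_degenerate_cases(self, fig1):
        assert fig1.max_overlap() == 3
        assert Hypergraph([["a", "b"], ["c", "d"]]).max_overlap() == 0
        assert Hypergraph([["a", "b"]]).max_overlap() == 0

    @pytest.mark.parametrize("s,expected", [
        (1, {(0, 1), (1, 2), (1, 3)}),
        (2, {(0, 1), (1, 2)}),
        (3, {(1, 2)}),
        (4, set()),
    ])
    def test_fig1_line_graphs(self, fig1, s, expected):
        lg = fig1.s_line_graph(s)
        assert set(lg.edges) == expected
        assert lg.num_vertices == 4  # isolates included

    def test_rejects_order_below_one(self, fig1):
        with pytest.raises(ValueError):
            fig1.s_line_graph(0)

    def test_line_graph_matches_pair_enumeration_oracle(self):
        for h in random_hypergraphs(10, max_m=12, seed=17):
            sets = [h.member_indices(j) for j in range(h.num_edges)]
            for s in range(1, max(1, h.max_overlap()) + 1):
                A = line_graph_adjacency([set(e) for e in sets], s)
                got = h.s_line_graph(s)
                expected = {(j, k) for j in range(len(sets))
                            for k in range(j + 1, len(sets)) if A[j, k]}
                assert set(got.edges) == expected

    def test_nested_projection(self):
        for h in random_hypergraphs(10, seed=23):
            smax = h.max_overlap()
            for s in range(1, smax + 1):
                assert set(h.s_line_graph(s + 1).edges) <= set(h.s_line_graph(s).edges)

    def test_two_section_connected_iff_l1_connected(self):
        # coverage holds by construction, so the equivalence is two-sided
        for h in random_hypergraphs(12, seed=29):
            g = h.two_section_graph()
            ts_connected = len(bfs_components(list(g.nodes()), set(g.edges()))) == 1
            lg = h.s_line_graph(1)
            l1_connected = len(bfs_components(list(range(lg.num_vertices)),
                                              set(lg.edges))) == 1
            assert ts_connected == l1_connected


# -- randomised structural properties ---------------------------------------

from hypothesis import given, settings, strategies as st

labels = st.text(alphabet="abcdefgh", min_size=1, max_size=2)
hyperedge_lists = st.lists(st.lists(labels, min_size=1, max_size=6),
                           min_size=1, max_size=8)


@settings(max_examples=60, derandomize=True)
@given(hyperedge_lists)
def test_property_io_round_trip(edges):
    h = Hypergraph(edges)
    buf = io.StringIO()
    write_hyperedge_list(h, buf)
    h2 = read_hyperedge_list(buf.getvalue())
    assert [h2.members(j) for j in range(h2.num_edges)] == \
           [h.members(j) for j in range(h.num_edges)]


@settings(max_examples=60, derandomize=True)
@given(hyperedge_lists)
def test_property_nesting_and_degree_conservation(edges):
    h = Hypergraph(edges)
    assert sum(h.hyperdegree(v) for v in h.nodes) == sum(h.cardinalities)
    smax = h.max_overlap()
    previous = None
    for s in range(1, smax + 2):
        current = set(h.s_line_graph(s).edges)
        if previous is not None:
            assert current <= previous
        previous = current
    if smax:
        assert h.s_line_graph(smax).num_edges >= 1
        assert h.s_line_graph(smax + 1).num_edges == 0
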