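"""Graph container, family constructors, predicates, and edge-list I/O."""

import pytest

from morancol.graph_core import (
    DirectedGraph,
    GraphFamilySpec,
    GraphError,
    backward_graph,
    build_family,
    complete_graph,
    cycle_graph,
    default_start,
    double_star_graph,
    is_regular,
    is_undirected,
    lollipop_graph,
    random_reachable_digraph,
    reachable_from,
    read_edge_list,
    star_graph,
    total_order_graph,
    write_edge_list,
)


class TestContainer:
    def test_rejects_self_loop(self):
        with pytest.raises(GraphError, match="self-loop"):
            DirectedGraph(2, ((0,), (0,)))

    def test_rejects_duplicate_edge(self):
        with pytest.raises(GraphError, match="duplicate"):
            DirectedGraph(2, ((1, 1), ()))

    def test_rejects_out_of_range_target(self):
        with pytest.raises(GraphError, match="range"):
            DirectedGraph(2, ((5,), ()))

    def test_sink_nodes_are_legal(self):
        g = total_order_graph(4)
        assert g.degree(3) == 0


class TestFamilies:
    def test_backward_3_explicit_edges(self):
        g = backward_graph(3)
        assert g.edge_set() == {(0, 1), (1, 2), (1, 0), (2, 0), (2, 1)}
        assert g.degrees == (1, 2, 2)

    def test_complete_3_equals_cycle_3(self):
        assert complete_graph(3).edge_set() == cycle_graph(3).edge_set()

    def test_total_order_4_degrees_and_sink(self):
        g = total_order_graph(4)
        assert g.degrees == (3, 2, 1, 0)

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_edge_counts(self, n):
        assert complete_graph(n).num_edges == n * (n - 1)
        assert backward_graph(n).num_edges == (n - 1) + n * (n - 1) // 2
        assert star_graph(n).num_edges == 2 * (n - 1)
        assert total_order_graph(n).num_edges == n * (n - 1) // 2

    def test_double_star_structure(self):
        g = double_star_graph(3)
        assert g.n == 6
        assert is_undirected(g)
        assert sorted(g.degrees, reverse=True) == [3, 3, 1, 1, 1, 1]

    def test_lollipop_structure(self):
        g = lollipop_graph(16)  # path of 4, cluster of 12
        assert g.degrees[0] == 1 and g.degrees[3] == 12
        assert all(d == 11 for d in g.degrees[4:])
        # no edges from the cluster back to the path
        assert all(v >= 4 for u in range(4, 16) for v in g.out_neighbors[u])

    def test_lollipop_attach_one(self):
        g = lollipop_graph(16, attach="one")
        assert g.out_neighbors[3] == (4,)

    @pytest.mark.parametrize(
        "family,kwargs",
        [("complete", {"n": 1}), ("cycle", {"n": 2}), ("star", {"n": 1}),
         ("double_star", {"k": 1}), ("lollipop", {"n": 3}),
         ("nonsense", {"n": 5})],
    )
    def test_invalid_specs_rejected(self, family, kwargs):
        with pytest.raises(GraphError):
            if family == "nonsense":
                build_family(GraphFamilySpec(family="nonsense", n=5))
            elif family == "double_star":
                double_star_graph(kwargs["k"])
            else:
                build_family(GraphFamilySpec(family=family, **kwargs))

    @pytest.mark.parametrize(
        "family,n", [("complete", 8), ("cycle", 8), ("star", 8),
                     ("double_star", 8), ("total_order", 8), ("backward", 8),
                     ("lollipop", 8)],
    )
    def test_default_start_reaches_all_nodes(self, family, n):
        g = build_family(GraphFamilySpec(family=family, n=n))
        assert reachable_from(g, {default_start(family)}) == frozenset(range(n))


class TestReachability:
    def test_total_order_from_source_and_sink(self):
        g = total_order_graph(5)
        assert reachable_from(g, {0}) == frozenset(range(5))
        assert reachable_from(g, {4}) == frozenset({4})

    def test_backward_is_strongly_connected(self):
        g = backward_graph(6)
        for v in range(6):
            assert reachable_from(g, {v}) == frozenset(range(6))

    def test_empty_sources_rejected(self):
        with pytest.raises(GraphError):
            reachable_from(complete_graph(3), set())


class TestPredicates:
    def test_cycle_is_regular_undirected(self):
        g = cycle_graph(8)
        assert is_undirected(g) and is_regular(g)
        assert set(g.degrees) == {2}

    def test_star_is_undirected_not_regular(self):
        g = star_graph(5)
        assert is_undirected(g) and not is_regular(g)

    def test_backward_is_directed(self):
        assert not is_undirected(backward_graph(5))


class TestRandomDigraph:
    def test_forced_complete_at_prob_one(self):
        g = random_reachable_digraph(2, 1.0, seed=0)
        assert g.edge_set() == {(0, 1), (1, 0)}

    def test_deterministic_given_seed(self):
        a = random_reachable_digraph(8, 0.3, seed=42)
        b = random_reachable_digraph(8, 0.3, seed=42)
        assert a.out_neighbors == b.out_neighbors

    @pytest.mark.parametrize("seed", range(10))
    def test_postcondition_reachable(self, seed):
        g = random_reachable_digraph(8, 0.25, seed=seed)
        assert reachable_from(g, {0}) == frozenset(range(8))

    def test_undirected_flag(self):
        g = random_reachable_digraph(8, 0.5, seed=3, undirected=True)
        assert is_undirected(g)

    def test_hopeless_edge_prob_fails_loudly(self):
        with pytest.raises(GraphError, match="edge_prob"):
            random_reachable_digraph(10, 1e-6, seed=0, max_rejections=5)


class TestEdgeListIO:
    def test_two_node_file(self, tmp_path):
        path = tmp_path / "k2.tsv"
        path.write_text("0\t1\n1\t0\n")
        g = read_edge_list(path)
        assert g.edge_set() == {(0, 1), (1, 0)}

    @pytest.mark.parametrize("maker", [backward_graph, total_order_graph,
                                       star_graph])
    def test_round_trip(self, tmp_path, maker):
        g = maker(5)
        path = tmp_path / "g.tsv"
        write_edge_list(g, path)
        assert read_edge_list(path).out_neighbors == g.out_neighbors

    def test_undirected_dialect(self, tmp_path):
        path = tmp_path / "u.tsv"
        path.write_text("# undirected\n0\t1\n")
        assert read_edge_list(path).edge_set() == {(0, 1), (1, 0)}

    @pytest.mark.parametrize("content,msg", [
        ("0\t0\n", "self-loop"),
        ("0\t1\n0\t1\n", "duplicate"),
        ("0 1\n", "expected"),
        ("a\tb\n", "non-integer"),
    ])
    def test_malformed_lines_name_the_line(self, tmp_path, content, msg):
        path = tmp_path / "bad.tsv"
        path.write_text(content)
        with pytest.raises(GraphError, match=msg):
            read_edge_list(path)
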