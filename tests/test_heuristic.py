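"""The shortest-hyperpath heuristic, its recovery subroutine, and the heap."""

import networkx as nx
import pytest

from hyperpaths import (
    EdgeHeap,
    Hyperedge,
    Hypergraph,
    brute_force_hyperpaths,
    check_witness,
    doubly_reachable_subgraph,
    is_hyperpath,
    shortest_by_enumeration,
    shortest_hyperpath_heuristic,
    singleton_tail_matrix,
)


class TestEdgeHeap:
    def test_extracts_minimum(self):
        h = EdgeHeap()
        h.insert("a", 3)
        h.insert("b", 1)
        assert h.extract_min() == "b"
        assert h.extract_min() == "a"

    def test_decrease_key_reorders(self):
        h = EdgeHeap()
        h.insert("a", 3)
        h.decrease("a", 1)
        h.insert("b", 2)
        assert h.extract_min() == "a"

    def test_increase_is_noop_and_ties_fifo(self):
        h = EdgeHeap()
        h.insert("a", 1)
        h.insert("b", 1)
        h.decrease("a", 5)  # no-op by contract
        assert h.extract_min() == "a"  # earliest insertion wins the tie
        assert h.extract_min() == "b"
        with pytest.raises(IndexError):
            h.extract_min()

    def test_tie_break_survives_decrease(self):
        h = EdgeHeap()
        h.insert("a", 5)
        h.insert("b", 5)
        h.decrease("b", 5)
        h.decrease("a", 5)
        assert h.extract_min() == "a"


@pytest.mark.parametrize(
    "name, expected_edges, expected_weight, expected_cyclic",
    [
        ("chain", {"e1", "e2"}, 2.0, False),
        ("and_gadget", {"e1", "e2", "e3"}, 3.0, False),
        ("cyclic_gadget", {"e1", "e2", "e3"}, 3.0, True),
        ("two_route", {"e1", "e3"}, 2.0, False),
        ("trim_test", {"e1", "e2"}, 2.0, False),
    ],
)
def test_worked_examples(examples, name, expected_edges, expected_weight, expected_cyclic):
    g, s, t = examples[name]
    p = shortest_hyperpath_heuristic(g, s, t)
    assert p.edge_set == expected_edges
    assert p.weight == pytest.approx(expected_weight)
    assert p.cyclic is expected_cyclic
    assert check_witness(g, p.edges, s, t)


def test_unreachable_sink_returns_none(examples):
    g, s, t = examples["chain"]
    assert shortest_hyperpath_heuristic(g, t, s) is None
    g2 = g.copy()
    g2.add_vertex("island")
    assert shortest_hyperpath_heuristic(g2, s, "island") is None


def test_unknown_vertices_raise(examples):
    g, s, t = examples["chain"]
    with pytest.raises(ValueError):
        shortest_hyperpath_heuristic(g, "nope", t)
    with pytest.raises(ValueError):
        shortest_hyperpath_heuristic(g, s, "nope")


def test_trim_discards_heaviest_redundant_branch(examples):
    """With a branching head covering both routes, the greedy trim must
    drop the weight-10 branch and keep the weight-1 branch."""
    g, s, t = examples["trim_test"]
    p = shortest_hyperpath_heuristic(g, s, t)
    assert p.edge_set == {"e1", "e2"} and p.weight == pytest.approx(2.0)


def test_search_state_diagnostics(examples):
    g, s, t = examples["and_gadget"]
    p, state = shortest_hyperpath_heuristic(g, s, t, return_search_state=True)
    assert p.weight == pytest.approx(3.0)
    assert set(state["e3"].inedges) == {"e1", "e2"}  # both branches recorded
    assert state["e3"].length == pytest.approx(3.0)
    assert state["e1"].length == pytest.approx(1.0)


def test_restriction_safety(make_random):
    """Running on the doubly-reachable subgraph yields the same weight as
    running on the full graph."""
    for seed in range(30):
        g, s, t, reach = make_random(seed)
        if not reach:
            continue
        full = shortest_hyperpath_heuristic(g, s, t)
        sub = shortest_hyperpath_heuristic(doubly_reachable_subgraph(g, s, t), s, t)
        assert full is not None and sub is not None
        assert full.weight == pytest.approx(sub.weight)


def test_determinism(make_random):
    for seed in range(15):
        g, s, t, _ = make_random(seed)
        p1 = shortest_hyperpath_heuristic(g, s, t)
        p2 = shortest_hyperpath_heuristic(g, s, t)
        assert (p1 is None) == (p2 is None)
        if p1 is not None:
            assert p1.edges == p2.edges and p1.weight == p2.weight


def test_weight_scaling(make_random):
    """Scaling all weights by c > 0 scales the result by c and keeps the
    same edge set."""
    for seed in range(10):
        g, s, t, reach = make_random(seed, weight_range=(0.5, 4.0))
        if not reach:
            continue
        scaled = Hypergraph(
            Hyperedge(id=e.id, tail=e.tail, head=e.head, weight=3.0 * e.weight)
            for e in g.edges()
        )
        p = shortest_hyperpath_heuristic(g, s, t)
        ps = shortest_hyperpath_heuristic(scaled, s, t)
        assert ps.edge_set == p.edge_set
        assert ps.weight == pytest.approx(3.0 * p.weight)


def test_upper_bound_against_enumeration(make_random):
    """The heuristic never beats the enumerated optimum; it usually ties."""
    ties = co_run = 0
    for seed in range(40):
        g, s, t, reach = make_random(seed, n_max=10, m_max=9, weight_range=(0.5, 5.0))
        if not reach:
            continue
        p = shortest_hyperpath_heuristic(g, s, t)
        opt = shortest_by_enumeration(g, s, t)
        co_run += 1
        assert p.weight >= opt.weight - 1e-9
        ties += abs(p.weight - opt.weight) < 1e-9
    assert co_run > 5
    assert ties > 0


def test_output_is_always_a_hyperpath(make_random):
    for seed in range(60):
        g, s, t, reach = make_random(seed, n_max=10, m_max=10)
        p = shortest_hyperpath_heuristic(g, s, t)
        assert (p is not None) == reach
        if p is not None:
            assert is_hyperpath(g, p.edge_set, s, t)


def _singleton_tail_dijkstra(g, s, t):
    """Independent oracle valid only for singleton-tail hypergraphs, where
    every hyperpath is a simple chain of hyperedges (each head covering the
    next singleton tail): shortest s,t-hyperpath weight equals the shortest
    path in the edge-adjacency digraph with arc cost = target edge weight."""
    D = nx.DiGraph()
    ids = list(g.edge_ids)
    D.add_nodes_from(["SRC", "SNK"] + ids)
    for e in ids:
        he = g.edge(e)
        if he.tail == frozenset({s}):
            D.add_edge("SRC", e, w=he.weight)
        if t in he.head:
            D.add_edge(e, "SNK", w=0.0)
        for f in ids:
            if he.head & g.edge(f).tail:
                D.add_edge(e, f, w=g.edge(f).weight)
    try:
        return nx.dijkstra_path_length(D, "SRC", "SNK", weight="w")
    except nx.NetworkXNoPath:
        return None


def test_singleton_tail_matches_independent_dijkstra_oracle():
    """Exactness on the singleton-tail class, cross-checked against an
    ordinary-graph shortest path rather than hyperpath enumeration."""
    reachable = 0
    for g, s, t, _ in singleton_tail_matrix(count=100, seed=3):
        heur = shortest_hyperpath_heuristic(g, s, t)
        opt = _singleton_tail_dijkstra(g, s, t)
        assert (heur is None) == (opt is None)
        if heur is not None:
            reachable += 1
            assert heur.weight == pytest.approx(opt, abs=1e-9)
    assert reachable >= 15


def test_sink_inedge_overlap_stays_minimal():
    """When one sink in-edge lies inside the superpath recovered for
    another, the final trim must still return a minimal s,t-superpath."""
    g = Hypergraph(
        [
            Hyperedge(id="e1", tail={"s"}, head={"a", "t"}, weight=1.0),
            Hyperedge(id="e2", tail={"a"}, head={"t"}, weight=0.0),
        ]
    )
    p = shortest_hyperpath_heuristic(g, "s", "t")
    assert is_hyperpath(g, p.edge_set, "s", "t")
    assert p.edge_set == {"e1"}
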