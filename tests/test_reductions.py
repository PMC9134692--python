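"""Supersource/sink reductions and instance preparation."""

import pytest

from hyperpaths import (
    SUPERSINK,
    SUPERSOURCE,
    Hyperedge,
    Hypergraph,
    brute_force_hyperpaths,
    prepare_instance,
    reduce_sources_sinks,
    source_vertices,
)


def _graph(*edges):
    return Hypergraph(
        Hyperedge(id=i, tail=frozenset(tl), head=frozenset(hd), weight=w)
        for i, tl, hd, w in edges
    )


def test_reduce_all_mode_adds_two_zero_weight_edges():
    g = _graph(("e1", {"a"}, {"t"}, 1.0), ("e2", {"b"}, {"t"}, 1.0))
    out, s, t = reduce_sources_sinks(g, sources={"a", "b"}, sinks={"t"}, sink_mode="all")
    assert (s, t) == (SUPERSOURCE, SUPERSINK)
    assert len(out) == len(g) + 2
    src_edge = out.edge("__SRC_EDGE__")
    assert src_edge.tail == frozenset({s}) and src_edge.head == frozenset({"a", "b"})
    snk_edge = out.edge("__SNK_EDGE__")
    assert snk_edge.tail == frozenset({"t"}) and snk_edge.head == frozenset({t})
    assert src_edge.weight == 0.0 and snk_edge.weight == 0.0
    assert len(list(g.edges())) == 2  # input untouched


def test_reduce_any_mode_adds_one_edge_per_sink():
    g = _graph(("e1", {"s"}, {"x", "y"}, 1.0))
    out, _, t = reduce_sources_sinks(g, sources={"s"}, sinks={"x", "y"}, sink_mode="any")
    sink_edges = [e for e in out.edges() if t in e.head]
    assert sorted(tuple(e.tail) for e in sink_edges) == [("x",), ("y",)]
    assert all(e.weight == 0.0 for e in sink_edges)


def test_reduce_same_vertex_as_source_and_sink():
    """Wiring a vertex as both source and sink yields the 2-edge zero-weight
    hyperpath through it, confirmed by exhaustive subset scan."""
    g = _graph(("e1", {"a"}, {"b"}, 1.0))
    out, s, t = reduce_sources_sinks(g, sources={"a"}, sinks={"a"}, sink_mode="all")
    paths = brute_force_hyperpaths(out, s, t)
    assert len(paths) == 1
    (p,) = paths
    assert len(p) == 2 and out.weight(p) == 0.0


def test_reduce_rejects_empty_sets_and_collisions():
    g = _graph(("e1", {"a"}, {"b"}, 1.0))
    with pytest.raises(ValueError):
        reduce_sources_sinks(g, sources=set(), sinks={"b"})
    with pytest.raises(ValueError):
        reduce_sources_sinks(g, sources={"a"}, sinks=set())
    clash = _graph(("e1", {SUPERSOURCE}, {"b"}, 1.0))
    with pytest.raises(ValueError, match="collides"):
        reduce_sources_sinks(clash, sources={"b"}, sinks={"b"})


def test_prepare_instance_chain():
    g = _graph(("e1", {"s"}, {"a"}, 1.0), ("e2", {"a"}, {"t"}, 1.0))
    out, ss, tt = prepare_instance(g, target="t")
    assert len(out) == len(g) + 2
    assert out.edge("__SRC_EDGE__").head == frozenset({"s"})
    assert out.edge("__SNK_EDGE__").tail == frozenset({"t"})


def test_prepare_instance_includes_self_loop_only_vertices():
    """A vertex whose only in-edge is a self-loop counts as a source, since
    the loop is otherwise never traversable."""
    g = _graph(
        ("loop", {"b", "c"}, {"b", "d"}, 1.0),
        ("mid", {"b"}, {"c"}, 1.0),
        ("last", {"d"}, {"z"}, 1.0),
    )
    assert "b" in source_vertices(g)
    out, ss, _ = prepare_instance(g, target="z")
    assert "b" in out.edge("__SRC_EDGE__").head


def test_prepare_instance_errors():
    cyclic = _graph(("e1", {"a"}, {"b"}, 1.0), ("e2", {"b"}, {"a"}, 1.0))
    with pytest.raises(ValueError, match="no source vertices"):
        prepare_instance(cyclic, target="a", allow_target_out_edges=True)
    g = _graph(("e1", {"s"}, {"a"}, 1.0), ("e2", {"a"}, {"t"}, 1.0))
    with pytest.raises(ValueError, match="out-edges"):
        prepare_instance(g, target="a")
    with pytest.warns(UserWarning):
        prepare_instance(g, target="a", allow_target_out_edges=True)


def _multi_source_optimum(g, sources, sink):
    """Brute-force oracle for the multi-source problem on the raw graph:
    minimum weight over edge subsets from which the sink is reachable when
    every source starts covered (with nonnegative weights this equals the
    minimum over minimal such subsets, i.e. over hyperpaths)."""
    ids = sorted(g.edge_ids)
    best = None
    for mask in range(1 << len(ids)):
        F = [ids[i] for i in range(len(ids)) if mask >> i & 1]
        covered = set(sources)
        changed = True
        used = set()
        while changed:
            changed = False
            for eid in F:
                e = g.edge(eid)
                if eid not in used and e.tail <= covered:
                    used.add(eid)
                    if not e.head <= covered:
                        covered |= e.head
                    changed = True
        if sink in covered:
            w = g.weight(F)
            if best is None or w < best:
                best = w
    return best


def test_reduction_soundness_multi_source(make_random):
    """Minimum s*,t*-hyperpath weight after the reduction equals the
    brute-force multi-source optimum on the raw graph (wiring edges are
    zero-weight, so totals agree exactly)."""
    checked_reachable = 0
    for seed in range(10):
        g, s, t, _ = make_random(seed, n_max=6, m_max=6)
        sources = {s} | set(sorted(g.vertices)[:2])
        reduced, ss, tt = reduce_sources_sinks(g, sources=sources, sinks={t}, sink_mode="all")
        reduced_best = min(
            (reduced.weight(p) for p in brute_force_hyperpaths(reduced, ss, tt)),
            default=None,
        )
        direct_best = _multi_source_optimum(g, sources, t)
        assert (reduced_best is None) == (direct_best is None)
        if reduced_best is not None:
            checked_reachable += 1
            assert reduced_best == pytest.approx(direct_best)
    assert checked_reachable > 0  # the matrix must exercise the reachable case
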