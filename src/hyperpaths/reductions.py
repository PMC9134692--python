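"""Multi-source / multi-sink reductions and instance preparation.

Shortest hyperpaths with a single source and sink captures the multi-source
and multi-sink variants: add a fresh supersource s* with one zero-weight
hyperedge ({s*}, S) to the source set, and either a single zero-weight edge
(T, {t*}) to reach *all* sinks, or one zero-weight edge ({v}, {t*}) per sink
v to reach *any* sink.

``prepare_instance`` mirrors the standard experimental convention for
pathway hypergraphs: the sources are the vertices with no in-edges (plus
vertices whose only in-edges are self-loops, which would otherwise never be
traversable), all wired at once to a supersource, and the chosen target is
wired to a fresh sink.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Set, Tuple

from .model import Hyperedge, Hypergraph

__all__ = [
    "SUPERSOURCE",
    "SUPERSINK",
    "reduce_sources_sinks",
    "prepare_instance",
]

SUPERSOURCE = "__SRC__"
SUPERSINK = "__SNK__"
_SRC_EDGE = "__SRC_EDGE__"
_SNK_EDGE = "__SNK_EDGE__"


def _check_fresh(g: Hypergraph, vertex_ids: Iterable[str], edge_ids: Iterable[str]) -> None:
    for v in vertex_ids:
        if g.has_vertex(v):
            raise ValueError(f"reserved vertex id {v!r} collides with an existing vertex")
    for e in edge_ids:
        if g.has_edge(e):
            raise ValueError(f"reserved edge id {e!r} collides with an existing edge")


def reduce_sources_sinks(
    g: Hypergraph,
    sources: Set[str],
    sinks: Set[str],
    sink_mode: str = "all",
) -> Tuple[Hypergraph, str, str]:
    """Reduce a multi-source / multi-sink problem to single source and sink.

    Returns a copy of ``g`` augmented with a supersource edge
    ({__SRC__}, sources) of weight 0 and, depending on ``sink_mode``:

    - ``"all"``: one edge (sinks, {__SNK__}) of weight 0, so a hyperpath
      must reach every sink;
    - ``"any"``: one edge ({v}, {__SNK__}) of weight 0 per sink v, so a
      hyperpath must reach at least one sink.

    Any s*,t*-hyperpath in the result corresponds to a solution of the
    multi-source/sink problem on ``g``.
    """
    if not sources:
        raise ValueError("sources must be nonempty")
    if not sinks:
        raise ValueError("sinks must be nonempty")
    if sink_mode not in ("all", "any"):
        raise ValueError(f"sink_mode must be 'all' or 'any', got {sink_mode!r}")
    unknown = (set(sources) | set(sinks)) - set(g.vertices)
    if unknown:
        raise ValueError(f"unknown vertices: {sorted(unknown)}")

    sink_edge_ids = (
        [_SNK_EDGE] if sink_mode == "all" else [f"{_SNK_EDGE}{v}" for v in sorted(sinks)]
    )
    _check_fresh(g, [SUPERSOURCE, SUPERSINK], [_SRC_EDGE] + sink_edge_ids)

    out = g.copy()
    out.add_edge(
        Hyperedge(id=_SRC_EDGE, tail=frozenset({SUPERSOURCE}), head=frozenset(sources), weight=0.0)
    )
    if sink_mode == "all":
        out.add_edge(
            Hyperedge(id=_SNK_EDGE, tail=frozenset(sinks), head=frozenset({SUPERSINK}), weight=0.0)
        )
    else:
        for v in sorted(sinks):
            out.add_edge(
                Hyperedge(
                    id=f"{_SNK_EDGE}{v}",
                    tail=frozenset({v}),
                    head=frozenset({SUPERSINK}),
                    weight=0.0,
                )
            )
    return out, SUPERSOURCE, SUPERSINK


def source_vertices(g: Hypergraph) -> Set[str]:
    """Vertices with no in-edges, plus vertices all of whose in-edges are
    self-loops (which can never be traversed without outside help)."""
    out = set()
    for v in g.vertices:
        ins = g.in_edges(v)
        if not ins or all(g.edge(e).is_self_loop_at(v) for e in ins):
            out.add(v)
    return out


def prepare_instance(
    g: Hypergraph,
    target: str,
    allow_target_out_edges: bool = False,
) -> Tuple[Hypergraph, str, str]:
    """Build a single source-sink instance for ``target``.

    Wires a fresh supersource to every source vertex (no in-edges, or only
    self-loop in-edges) with one zero-weight hyperedge, and the target to a
    fresh sink with a zero-weight edge ({target}, {__SNK__}).

    Targets conventionally have no out-edges; a target that does is
    permitted with a warning when ``allow_target_out_edges`` is set, since
    biologically interesting source-target pairs outside the convention
    exist.
    """
    if not g.has_vertex(target):
        raise ValueError(f"unknown target vertex {target!r}")
    if g.out_edges(target):
        if not allow_target_out_edges:
            raise ValueError(
                f"target {target!r} has out-edges; pass allow_target_out_edges=True to override"
            )
        warnings.warn(f"target {target!r} has out-edges", stacklevel=2)
    srcs = source_vertices(g) - {target}
    if not srcs:
        raise ValueError("no source vertices exist (every vertex has a non-self-loop in-edge)")
    _check_fresh(g, [SUPERSOURCE, SUPERSINK], [_SRC_EDGE, _SNK_EDGE])
    out = g.copy()
    out.add_edge(
        Hyperedge(id=_SRC_EDGE, tail=frozenset({SUPERSOURCE}), head=frozenset(srcs), weight=0.0)
    )
    out.add_edge(
        Hyperedge(id=_SNK_EDGE, tail=frozenset({target}), head=frozenset({SUPERSINK}), weight=0.0)
    )
    return out, SUPERSOURCE, SUPERSINK
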