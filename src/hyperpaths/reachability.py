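"""Reachability primitives for directed hypergraphs (B-connectivity).

A vertex is *forward reachable* from source s if an s,v-superpath exists;
a hyperedge is forward reachable when its whole tail is.  A vertex v is
*backward traceable* from sink t if v = t, or v lies in the tail of an edge
some of whose head vertices are backward traceable; an edge is backward
traceable when some head vertex is.  An edge that is both is *doubly
reachable* — every edge of every s,t-hyperpath is doubly reachable, so
restricting to the doubly-reachable subgraph is safe.

The forward sweep keeps, per edge, a countdown of uncovered tail vertices
and explores vertices breadth-first (FIFO, insertion order), so results and
discovery orders are deterministic.  All functions take per-call state;
repeated calls need no global reset.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Set, Tuple

from .model import Hypergraph

__all__ = [
    "ReachResult",
    "forward_reachable",
    "backward_traceable",
    "is_reachable",
    "is_vertex_reachable",
    "doubly_reachable_subgraph",
]


@dataclass(frozen=True)
class ReachResult:
    """Outcome of a forward sweep: the reached vertices and edges, plus the
    order in which edges were discovered (a valid traversal order: each
    edge's tail is covered by the source and heads of earlier edges)."""

    reached_vertices: FrozenSet[str]
    reached_edges: FrozenSet[str]
    edge_order: Tuple[str, ...]


def _forward_sweep(
    g: Hypergraph,
    s: str,
    excluded: FrozenSet[str],
    active: Optional[FrozenSet[str]],
    stop_edge: Optional[str] = None,
    stop_vertex: Optional[str] = None,
) -> Tuple[Set[str], List[str], bool]:
    """Shared forward-reachability worker.

    Edges outside ``active`` (when given) or inside ``excluded`` are
    ignored.  If ``stop_edge``/``stop_vertex`` is given, the sweep halts as
    soon as it is reached, returning (partial) results plus a hit flag.
    """
    count = {}
    reached_v: Set[str] = {s}
    order: List[str] = []
    queue = deque([s])
    if stop_vertex == s:
        return reached_v, order, True
    while queue:
        v = queue.popleft()
        for eid in g.out_edges_sorted(v):
            if eid in excluded or (active is not None and eid not in active):
                continue
            e = g.edge(eid)
            if eid not in count:
                count[eid] = len(e.tail)
            count[eid] -= 1
            if count[eid] == 0:
                order.append(eid)
                if eid == stop_edge:
                    return reached_v, order, True
                for w in e.head_sorted:
                    if w not in reached_v:
                        reached_v.add(w)
                        if w == stop_vertex:
                            return reached_v, order, True
                        queue.append(w)
    return reached_v, order, False


def forward_reachable(
    g: Hypergraph, s: str, excluded: FrozenSet[str] = frozenset()
) -> ReachResult:
    """All edges forward reachable from ``s`` using non-excluded edges.

    Reached vertices are {s} plus the heads of reached edges.  Work is
    proportional to the incidence size of the explored subgraph.
    """
    if not g.has_vertex(s):
        raise ValueError(f"unknown source vertex {s!r}")
    reached_v, order, _ = _forward_sweep(g, s, frozenset(excluded), active=None)
    return ReachResult(
        reached_vertices=frozenset(reached_v),
        reached_edges=frozenset(order),
        edge_order=tuple(order),
    )


def backward_traceable(g: Hypergraph, t: str) -> FrozenSet[str]:
    """All edges with some head vertex backward traceable from ``t``."""
    if not g.has_vertex(t):
        raise ValueError(f"unknown sink vertex {t!r}")
    traceable_v: Set[str] = {t}
    marked: Set[str] = set()
    queue = deque([t])
    while queue:
        w = queue.popleft()
        for eid in sorted(g.in_edges(w)):
            if eid in marked:
                continue
            marked.add(eid)
            for v in sorted(g.edge(eid).tail):
                if v not in traceable_v:
                    traceable_v.add(v)
                    queue.append(v)
    return frozenset(marked)


def is_reachable(g: Hypergraph, s: str, edge_id: str, active: FrozenSet[str]) -> bool:
    """True iff ``edge_id`` becomes forward reachable from ``s`` using only
    edges in ``active``; halts as soon as the edge is reached."""
    _, _, hit = _forward_sweep(g, s, frozenset(), frozenset(active), stop_edge=edge_id)
    return hit


def is_vertex_reachable(g: Hypergraph, s: str, v: str, active: FrozenSet[str]) -> bool:
    """True iff vertex ``v`` is forward reachable from ``s`` using only
    edges in ``active``; halts as soon as ``v`` is reached."""
    _, _, hit = _forward_sweep(g, s, frozenset(), frozenset(active), stop_vertex=v)
    return hit


def doubly_reachable_subgraph(g: Hypergraph, s: str, t: str) -> Hypergraph:
    """Subgraph induced by edges both forward reachable from ``s`` and
    backward traceable from ``t``; may be empty.  Contains every edge of
    every s,t-hyperpath of ``g``."""
    fwd = forward_reachable(g, s).reached_edges
    bwd = backward_traceable(g, t)
    return g.subgraph(fwd & bwd, extra_vertices=(s, t))
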