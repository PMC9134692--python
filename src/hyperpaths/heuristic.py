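"""Dijkstra-like heuristic for shortest source-sink hyperpaths.

The search maintains a min-heap of *hyperedges* (not vertices) keyed by the
weight of the best hyperpath recovered so far from the source to that edge.
Restricting to the doubly-reachable subgraph first, it seeds the heap with
the edges whose tail is exactly {s}, then repeatedly extracts the
minimum-key edge e, finalizes its path-length estimate e.length by
recovering an s,e-hyperpath, and relaxes the out-edges f of e's head
vertices: e is appended to f.inedges, f's uncovered-tail countdown is
decremented, and once f's tail is fully covered an s,f-hyperpath is
recovered to insert f or decrease its key.  Finally the best hyperpath over
the sink's reached in-edges is recovered and returned.

Path recovery is itself greedy: phase I traces backward through recorded
inedges lists to collect an s,e-superpath, and phase II trims it to a
minimal superpath by attempting to discard edges in decreasing order of
their finalized length estimates, re-testing reachability after each
removal.  Since recovery only consults inedges of edges extracted earlier,
the result is an upper bound on the true distance; it is exact on
singleton-tail hypergraphs, and the heuristic always returns a hyperpath
when one exists.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .model import Hypergraph, Hyperpath
from .reachability import (
    doubly_reachable_subgraph,
    is_reachable,
    is_vertex_reachable,
)
from .validation import ordered_hyperpath

__all__ = [
    "EdgeSearchState",
    "EdgeHeap",
    "recover_short_hyperpath",
    "shortest_hyperpath_heuristic",
]


class EdgeHeap:
    """Binary min-heap of edges with decrease-key via lazy deletion.

    Ties on equal keys break by earliest first insertion.  ``decrease`` with
    a key not smaller than the current one is a no-op by contract.
    """

    def __init__(self) -> None:
        self._heap: List[Tuple[float, int, str]] = []
        self._key: Dict[str, float] = {}
        self._seq: Dict[str, int] = {}
        self._next_seq = 0

    def __len__(self) -> int:
        return len(self._key)

    def __contains__(self, item: str) -> bool:
        return item in self._key

    def insert(self, item: str, key: float) -> None:
        if item in self._key:
            raise ValueError(f"{item!r} already on heap")
        self._seq.setdefault(item, self._next_seq)
        self._next_seq += 1
        self._key[item] = key
        heapq.heappush(self._heap, (key, self._seq[item], item))

    def decrease(self, item: str, key: float) -> None:
        if item not in self._key or key >= self._key[item]:
            return
        self._key[item] = key
        heapq.heappush(self._heap, (key, self._seq[item], item))

    def extract_min(self) -> str:
        while self._heap:
            key, _, item = heapq.heappop(self._heap)
            if self._key.get(item) == key:
                del self._key[item]
                return item
        raise IndexError("extract from empty heap")


@dataclass
class EdgeSearchState:
    """Per-edge mutable search fields.

    count: tail vertices not yet covered; inedges: extracted edges whose
    head meets this edge's tail, in extraction order; key: weight of the
    best recovered hyperpath while on the heap; length: finalized estimate
    set exactly once at extraction (an upper bound on the true distance);
    on_heap: whether the edge was ever inserted.
    """

    count: int
    inedges: List[str] = field(default_factory=list)
    inedge_set: Set[str] = field(default_factory=set)
    key: float = math.inf
    length: Optional[float] = None
    on_heap: bool = False


def _trace_superpath(
    h: Hypergraph, s: str, target: str, state: Dict[str, EdgeSearchState]
) -> Set[str]:
    """Phase I: collect an s,target-superpath by tracing inedges backward."""
    superpath = {target}
    queue = [target]
    while queue:
        f = queue.pop()
        st = state[f]
        for v in h.edge(f).tail:
            if v == s:
                continue
            covered = False
            for gid in st.inedges:
                if v in h.edge(gid).head:
                    covered = True
                    if gid not in superpath:
                        superpath.add(gid)
                        queue.append(gid)
            if not covered:
                raise RuntimeError(
                    f"recovery precondition violated: tail vertex {v!r} of edge "
                    f"{f!r} not covered by any recorded in-edge"
                )
    return superpath


def _trim(
    h: Hypergraph,
    s: str,
    superpath: Set[str],
    candidates: List[str],
    keep_reachable,
) -> Set[str]:
    """Phase II: greedily discard candidate edges (in the given order) while
    ``keep_reachable(remaining)`` holds."""
    remaining = set(superpath)
    for f in candidates:
        trial = frozenset(remaining - {f})
        if keep_reachable(trial):
            remaining.discard(f)
    return remaining


def _candidate_order(state: Dict[str, EdgeSearchState], edges: Set[str]) -> List[str]:
    # decreasing finalized length; ties by descending edge id
    return sorted(sorted(edges, reverse=True), key=lambda f: -state[f].length)


def recover_short_hyperpath(
    h: Hypergraph, s: str, edge_id: str, state: Dict[str, EdgeSearchState]
) -> Hyperpath:
    """Recover a short s,e-hyperpath for ``edge_id`` from recorded inedges.

    Phase I traces backward through ``state[...].inedges`` to collect an
    s,e-superpath; phase II trims it to a minimal s,e-superpath, trying
    candidates (never the target edge itself) in decreasing order of their
    finalized length estimates.  Raises if some tail vertex of a traced
    edge is covered by no recorded in-edge (an internal invariant breach).
    """
    superpath = _trace_superpath(h, s, edge_id, state)
    candidates = _candidate_order(state, superpath - {edge_id})
    final = _trim(
        h,
        s,
        superpath,
        candidates,
        lambda active: is_reachable(h, s, edge_id, active),
    )
    return ordered_hyperpath(h, s, frozenset(final))


def _recover_to_sink(
    h: Hypergraph, s: str, t: str, edge_id: str, state: Dict[str, EdgeSearchState]
) -> Hyperpath:
    """Final recovery for a sink in-edge: trace back from the in-edge, then
    trim to a *minimal s,t-superpath* (every edge, the in-edge included, is
    a trim candidate; the predicate is reachability of the sink vertex)."""
    superpath = _trace_superpath(h, s, edge_id, state)
    candidates = _candidate_order(state, superpath)
    final = _trim(
        h,
        s,
        superpath,
        candidates,
        lambda active: is_vertex_reachable(h, s, t, active),
    )
    return ordered_hyperpath(h, s, frozenset(final))


def shortest_hyperpath_heuristic(
    g: Hypergraph,
    s: str,
    t: str,
    return_search_state: bool = False,
):
    """Find a short s,t-hyperpath, or None when the sink is unreachable.

    Always returns a valid s,t-hyperpath whenever one exists; the returned
    weight is an upper bound on the optimum, attained exactly on
    singleton-tail hypergraphs with nonnegative weights.  Deterministic:
    heap ties break by earliest insertion, trim ties by descending edge id.

    With ``return_search_state`` the per-edge search state of the
    doubly-reachable subgraph (notably the recorded inedges lists) is
    returned alongside the path, for diagnostics.
    """
    if not g.has_vertex(s):
        raise ValueError(f"unknown source vertex {s!r}")
    if not g.has_vertex(t):
        raise ValueError(f"unknown sink vertex {t!r}")

    h = doubly_reachable_subgraph(g, s, t)
    state: Dict[str, EdgeSearchState] = {
        eid: EdgeSearchState(count=len(h.edge(eid).tail)) for eid in h.edge_ids
    }
    heap = EdgeHeap()
    covered: Set[str] = {s}
    finalized: Set[str] = set()

    def relax(f: str) -> None:
        st = state[f]
        if st.count != 0 or f in finalized:
            return
        path = recover_short_hyperpath(h, s, f, state)
        if not st.on_heap:
            st.on_heap = True
            st.key = path.weight
            heap.insert(f, path.weight)
        elif path.weight < st.key:
            st.key = path.weight
            heap.decrease(f, path.weight)

    # seed: edges whose tail is exactly {s}
    for eid in sorted(h.out_edges(s)):
        state[eid].count -= 1
        relax(eid)

    while len(heap):
        eid = heap.extract_min()
        finalized.add(eid)
        st = state[eid]
        st.length = recover_short_hyperpath(h, s, eid, state).weight
        e = h.edge(eid)
        touched: Set[str] = set()
        for v in sorted(e.head):
            newly = v not in covered
            if newly:
                covered.add(v)
            for fid in h.out_edges(v):
                touched.add(fid)
                if newly:
                    state[fid].count -= 1
        for fid in sorted(touched):
            fst = state[fid]
            if eid not in fst.inedge_set:
                fst.inedge_set.add(eid)
                fst.inedges.append(eid)
            relax(fid)

    best: Optional[Hyperpath] = None
    for eid in sorted(h.in_edges(t)):
        if not state[eid].on_heap:
            continue
        path = _recover_to_sink(h, s, t, eid, state)
        if best is None or (path.weight, tuple(sorted(path.edges))) < (
            best.weight,
            tuple(sorted(best.edges)),
        ):
            best = path
    if return_search_state:
        return best, state
    return best
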