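"""Certification of superpath / hyperpath properties, cycle detection, and
the brute-force enumeration oracle used by property tests.

An s,t-superpath is an edge subset F orderable as e_1..e_k with
(i) tail(e_1) = {s}, (ii) each tail(e_i) covered by {s} and earlier heads,
and (iii) t in head(e_k).  A hyperpath is a minimal superpath.  A hyperpath
is *cyclic* when every valid ordering contains a back-pair: a later edge
whose head intersects the tail of an earlier edge.

Cyclicity is decided here on the hyperpath's edge-adjacency digraph (arc
e -> f whenever head(e) intersects tail(f), including self-arcs): a
back-pair in a linear order is exactly a backward arc, a topological order
of an acyclic digraph is a back-pair-free witness ordering, and a digraph
cycle forces a backward arc in every linear order.  The equivalence with
the order-quantified definition is additionally enforced by the
``cyclic_by_ordering_scan`` oracle in tests rather than trusted.
"""

from __future__ import annotations

from itertools import permutations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .model import Hypergraph, Hyperpath
from .reachability import _forward_sweep

__all__ = [
    "edge_adjacency_arcs",
    "is_superpath",
    "is_hyperpath",
    "is_cyclic",
    "check_witness",
    "ordered_hyperpath",
    "cyclic_by_ordering_scan",
    "brute_force_hyperpaths",
]


def edge_adjacency_arcs(g: Hypergraph, edge_ids: Iterable[str]) -> Dict[str, Set[str]]:
    """Arcs e -> f (over the given edges) whenever head(e) meets tail(f);
    a self-arc at e marks head(e) meeting tail(e)."""
    ids = list(edge_ids)
    arcs: Dict[str, Set[str]] = {e: set() for e in ids}
    for e in ids:
        he = g.edge(e).head
        for f in ids:
            if he & g.edge(f).tail:
                arcs[e].add(f)
    return arcs


def _digraph_has_cycle(arcs: Dict[str, Set[str]]) -> bool:
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {v: WHITE for v in arcs}
    for root in arcs:
        if color[root] != WHITE:
            continue
        stack: List[Tuple[str, Iterable[str]]] = [(root, iter(sorted(arcs[root])))]
        color[root] = GRAY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GRAY:
                    return True
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter(sorted(arcs[nxt]))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return False


def is_cyclic(g: Hypergraph, p: Union[Hyperpath, Iterable[str]]) -> bool:
    """True iff the hyperpath contains a cycle (every valid ordering has a
    back-pair), decided via its edge-adjacency digraph."""
    edge_ids = p.edges if isinstance(p, Hyperpath) else tuple(p)
    return _digraph_has_cycle(edge_adjacency_arcs(g, edge_ids))


def check_witness(g: Hypergraph, order: Sequence[str], s: str, t: str) -> bool:
    """Re-check a witness ordering position by position against conditions
    (i)-(iii) of the superpath definition."""
    if not order:
        return False
    if g.edge(order[0]).tail != frozenset({s}):
        return False
    covered = {s} | set(g.edge(order[0]).head)
    for eid in order[1:]:
        e = g.edge(eid)
        if not e.tail <= covered:
            return False
        covered |= e.head
    return t in g.edge(order[-1]).head


def is_superpath(
    g: Hypergraph, edge_ids: Iterable[str], s: str, t: str
) -> Tuple[bool, Optional[Tuple[str, ...]]]:
    """Decide whether an edge subset is an s,t-superpath.

    Constructive: returns ``(True, witness_ordering)`` or ``(False, None)``.
    The witness is built by covered-tail peeling — every edge must be
    forward reachable within the subset, and some edge with t in its head
    must be placeable last (all other edges orderable without it, and its
    tail covered by them).  Candidate last edges are tried in ascending id
    order for determinism.
    """
    F = frozenset(edge_ids)
    if not F or not g.has_vertex(s):
        return False, None
    reached_v, order, _ = _forward_sweep(g, s, frozenset(), F)
    if set(order) != F:
        return False, None
    for last in sorted(e for e in F if t in g.edge(e).head):
        rest = F - {last}
        if not rest:
            if g.edge(last).tail == frozenset({s}):
                return True, (last,)
            continue
        rv, ro, _ = _forward_sweep(g, s, frozenset(), rest)
        if set(ro) == rest and g.edge(last).tail <= rv:
            return True, tuple(ro) + (last,)
    return False, None


def _contains_superpath(g: Hypergraph, edge_ids: FrozenSet[str], s: str, t: str) -> bool:
    """True iff some subset of ``edge_ids`` is an s,t-superpath, i.e. the
    forward sweep restricted to them reaches an edge with t in its head."""
    _, order, _ = _forward_sweep(g, s, frozenset(), edge_ids)
    return any(t in g.edge(e).head for e in order)


def is_hyperpath(g: Hypergraph, edge_ids: Iterable[str], s: str, t: str) -> bool:
    """True iff the subset is a minimal s,t-superpath.

    Minimality means no *proper subset* is a superpath — strictly stronger
    than surviving single-edge removals, since removing one edge can strand
    others that a smaller superpath never needed.  Equivalent formulation
    used here: F contains a superpath, but F minus any single edge does
    not (then F itself must be that superpath, and it is minimal).
    """
    F = frozenset(edge_ids)
    if not F or not g.has_vertex(s):
        return False
    if not _contains_superpath(g, F, s, t):
        return False
    return all(not _contains_superpath(g, F - {e}, s, t) for e in F)


def ordered_hyperpath(g: Hypergraph, s: str, edge_ids: Iterable[str]) -> Hyperpath:
    """Package an edge set as a Hyperpath with a breadth-first witness
    ordering, total weight, and cyclic flag.  The set must be fully
    orderable from the source (every edge forward reachable within it)."""
    F = frozenset(edge_ids)
    _, order, _ = _forward_sweep(g, s, frozenset(), F)
    if set(order) != F:
        raise RuntimeError("edge set is not orderable from the source")
    return Hyperpath(edges=tuple(order), weight=g.weight(F), cyclic=is_cyclic(g, order))


def cyclic_by_ordering_scan(g: Hypergraph, edge_ids: Iterable[str], s: str, t: str) -> bool:
    """Brute-force cyclicity oracle: scan all orderings of the edge set and
    report True iff no valid (i)-(iii) ordering is free of back-pairs.
    Exponential; intended for hyperpaths with few edges in tests."""
    F = tuple(sorted(edge_ids))
    saw_valid = False
    for perm in permutations(F):
        if not check_witness(g, perm, s, t):
            continue
        saw_valid = True
        back_pair = False
        for i, earlier in enumerate(perm):
            tail_i = g.edge(earlier).tail
            for later in perm[i:]:
                if g.edge(later).head & tail_i:
                    back_pair = True
                    break
            if back_pair:
                break
        if not back_pair:
            return False
    if not saw_valid:
        raise ValueError("edge set admits no valid ordering (not a superpath)")
    return True


def brute_force_hyperpaths(
    g: Hypergraph, s: str, t: str, cap: int = 14
) -> List[FrozenSet[str]]:
    """All s,t-hyperpaths by exhaustive subset scan (test oracle).

    Raises if the graph has more than ``cap`` edges, since the scan is
    exponential in the edge count.
    """
    ids = sorted(g.edge_ids)
    if len(ids) > cap:
        raise ValueError(f"{len(ids)} edges exceeds brute-force cap {cap}")
    found: List[FrozenSet[str]] = []
    for mask in range(1, 1 << len(ids)):
        F = frozenset(ids[i] for i in range(len(ids)) if mask >> i & 1)
        if is_hyperpath(g, F, s, t):
            found.append(F)
    return found
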