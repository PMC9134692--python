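"""Core data model for directed hypergraphs.

A directed hypergraph is a pair (V, E) where each hyperedge e is directed
from a nonempty *tail* vertex set to a nonempty *head* vertex set, with a
nonnegative weight.  In cell-signaling networks a hyperedge models a
reaction: reactants and positive regulators form the tail, products form
the head.

Vertex and edge identifiers are opaque, case-sensitive strings with no
biological semantics attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Iterator, List, Set, Tuple

__all__ = [
    "Hyperedge",
    "Hypergraph",
    "Hyperpath",
    "SizeParams",
    "size_params",
]


@dataclass(frozen=True)
class Hyperedge:
    """A weighted directed hyperedge tail -> head.

    Invariants: tail and head are nonempty; weight >= 0.  Zero weights are
    accepted because the multi-source/multi-sink reductions introduce
    zero-weight wiring edges; negative weights are always rejected.
    """

    id: str
    tail: FrozenSet[str]
    head: FrozenSet[str]
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tail", frozenset(self.tail))
        object.__setattr__(self, "head", frozenset(self.head))
        # cached sorted views; traversals use these for determinism
        object.__setattr__(self, "tail_sorted", tuple(sorted(self.tail)))
        object.__setattr__(self, "head_sorted", tuple(sorted(self.head)))
        if not self.tail:
            raise ValueError(f"edge {self.id!r}: tail must be nonempty")
        if not self.head:
            raise ValueError(f"edge {self.id!r}: head must be nonempty")
        if not (self.weight >= 0):
            raise ValueError(f"edge {self.id!r}: weight must be >= 0, got {self.weight}")

    def is_self_loop_at(self, v: str) -> bool:
        """True iff this edge is a self-loop at v (v in both tail and head)."""
        return v in self.tail and v in self.head

    @property
    def has_self_loop(self) -> bool:
        return bool(self.tail & self.head)


class Hypergraph:
    """A directed hypergraph with incidence indices.

    Maintains ``in_index[v]`` (edges with v in their head) and
    ``out_index[v]`` (edges with v in their tail), kept exactly consistent
    with the edge set after every mutation.  Vertices may exist in
    isolation (touched by no edge).
    """

    def __init__(
        self,
        edges: Iterable[Hyperedge] = (),
        vertices: Iterable[str] = (),
    ) -> None:
        self._edges: Dict[str, Hyperedge] = {}
        self._vertices: Set[str] = set(vertices)
        self._in: Dict[str, Set[str]] = {}
        self._out: Dict[str, Set[str]] = {}
        self._out_sorted: Dict[str, Tuple[str, ...]] = {}
        for e in edges:
            self.add_edge(e)

    # -- construction -----------------------------------------------------

    def add_vertex(self, v: str) -> None:
        self._vertices.add(v)

    def add_edge(self, e: Hyperedge) -> None:
        if e.id in self._edges:
            raise ValueError(f"duplicate edge id {e.id!r}")
        self._out_sorted.clear()
        self._edges[e.id] = e
        for v in e.tail:
            self._vertices.add(v)
            self._out.setdefault(v, set()).add(e.id)
        for v in e.head:
            self._vertices.add(v)
            self._in.setdefault(v, set()).add(e.id)

    def remove_edge(self, edge_id: str) -> None:
        self._out_sorted.clear()
        e = self._edges.pop(edge_id)
        for v in e.tail:
            self._out[v].discard(e.id)
        for v in e.head:
            self._in[v].discard(e.id)

    # -- queries ----------------------------------------------------------

    @property
    def vertices(self) -> FrozenSet[str]:
        return frozenset(self._vertices)

    @property
    def edge_ids(self) -> List[str]:
        """Edge ids in insertion order."""
        return list(self._edges)

    def edges(self) -> Iterator[Hyperedge]:
        return iter(self._edges.values())

    def edge(self, edge_id: str) -> Hyperedge:
        return self._edges[edge_id]

    def has_edge(self, edge_id: str) -> bool:
        return edge_id in self._edges

    def has_vertex(self, v: str) -> bool:
        return v in self._vertices

    def __len__(self) -> int:
        return len(self._edges)

    def in_edges(self, v: str) -> Set[str]:
        """Edge ids e with v in head(e)."""
        return set(self._in.get(v, ()))

    def out_edges(self, v: str) -> Set[str]:
        """Edge ids e with v in tail(e)."""
        return set(self._out.get(v, ()))

    def out_edges_sorted(self, v: str) -> Tuple[str, ...]:
        """Sorted out-edge ids of v, cached between mutations (hot path of
        the reachability sweeps)."""
        cached = self._out_sorted.get(v)
        if cached is None:
            cached = tuple(sorted(self._out.get(v, ())))
            self._out_sorted[v] = cached
        return cached

    def weight(self, edge_ids: Iterable[str]) -> float:
        # summed in sorted id order so identical edge sets always produce
        # bit-identical totals regardless of container iteration order
        return sum(self._edges[i].weight for i in sorted(edge_ids))

    def subgraph(self, edge_ids: Iterable[str], extra_vertices: Iterable[str] = ()) -> "Hypergraph":
        """Subgraph induced by an edge subset.

        Vertices are those touched by the kept edges, plus any explicitly
        requested extras (e.g. the source and sink, which must survive even
        if no kept edge touches them).
        """
        keep = set(edge_ids)
        sub = Hypergraph(vertices=extra_vertices)
        for eid in self._edges:
            if eid in keep:
                sub.add_edge(self._edges[eid])
        return sub

    def copy(self) -> "Hypergraph":
        return Hypergraph(edges=self.edges(), vertices=self._vertices)

    def check_indices(self) -> None:
        """Assert incidence indices are exactly consistent with the edges."""
        in_idx: Dict[str, Set[str]] = {}
        out_idx: Dict[str, Set[str]] = {}
        for e in self._edges.values():
            for v in e.tail:
                out_idx.setdefault(v, set()).add(e.id)
            for v in e.head:
                in_idx.setdefault(v, set()).add(e.id)
        if {v: s for v, s in self._in.items() if s} != in_idx:
            raise AssertionError("in_index inconsistent with edge heads")
        if {v: s for v, s in self._out.items() if s} != out_idx:
            raise AssertionError("out_index inconsistent with edge tails")
        named = set().union(*(e.tail | e.head for e in self._edges.values())) if self._edges else set()
        if not named <= self._vertices:
            raise AssertionError("vertex named by an edge missing from vertex set")

    # -- statistics -------------------------------------------------------

    def self_loops(self) -> List[str]:
        """Edge ids with intersecting tail and head."""
        return [e.id for e in self._edges.values() if e.has_self_loop]

    def unreachable_self_loops(self) -> List[str]:
        """Self-loops at a vertex whose only in-edge is the loop itself.

        Such a loop can never be traversed: the looping vertex has no other
        way of being produced, so the loop's tail can never be covered.
        Exposed as a statistic only; no algorithm depends on it.
        """
        out = []
        for e in self._edges.values():
            for v in e.tail & e.head:
                if self.in_edges(v) == {e.id}:
                    out.append(e.id)
                    break
        return out


@dataclass(frozen=True)
class SizeParams:
    """Hypergraph size measures: n vertices, m edges, total incidence
    ell = sum over edges of |tail|+|head|, and degree d = max over vertices
    of max(in-degree, out-degree)."""

    n: int
    m: int
    ell: int
    d: int


def size_params(g: Hypergraph) -> SizeParams:
    n = len(g.vertices)
    m = len(g)
    ell = sum(len(e.tail) + len(e.head) for e in g.edges())
    d = 0
    for v in g.vertices:
        d = max(d, len(g.in_edges(v)), len(g.out_edges(v)))
    return SizeParams(n=n, m=m, ell=ell, d=d)


@dataclass(frozen=True)
class Hyperpath:
    """A source-sink hyperpath: a minimal superpath with a witness ordering.

    ``edges`` lists edge ids in an ordering satisfying tail coverage: the
    first edge's tail is exactly {source}, and each edge's tail is covered
    by the source plus the heads of earlier edges.  ``weight`` is the sum
    of edge weights; ``cyclic`` records whether every valid ordering must
    place some head vertex in an earlier edge's tail.
    """

    edges: Tuple[str, ...]
    weight: float
    cyclic: bool

    @property
    def edge_set(self) -> FrozenSet[str]:
        return frozenset(self.edges)

    def __len__(self) -> int:
        return len(self.edges)
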