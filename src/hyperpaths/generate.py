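"""Seeded synthetic hypergraph generators.

``random_hypergraph`` draws sparse random instances whose default size
distribution mimics curated pathway hypergraphs: small tail sets (mean
around 2, reactants plus regulators), smaller head sets (mean around 1.5,
products), and fewer hyperedges than vertices.  The instances are
structural stand-ins only — no biological meaning is claimed.

``worked_examples`` returns the fixed micro-instances used across the test
suite (a two-edge chain, an AND gadget whose only hyperpath needs both
branches, a gadget whose unique hyperpath is cyclic, a two-route graph, and
a trim-test graph), each small enough for exhaustive oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, NamedTuple, Tuple

import numpy as np

from .model import Hyperedge, Hypergraph
from .reachability import forward_reachable

__all__ = [
    "GenSpec",
    "GeneratedInstance",
    "random_hypergraph",
    "cyclic_only_gadget",
    "worked_examples",
    "small_mixed_matrix",
    "singleton_tail_matrix",
    "feasibility_matrix",
]


@dataclass(frozen=True)
class GenSpec:
    """Parameters of one random instance.

    Sizes of tail and head sets are drawn uniformly from the inclusive
    ranges; weights uniformly from ``weight_range`` (a degenerate range
    such as (1, 1) gives unit weights).  ``singleton_tail`` forces all tail
    sets to one vertex.  ``self_loop_rate`` is the probability that an edge
    is forced to share a vertex between tail and head.  Identical specs
    produce identical hypergraphs.
    """

    n: int
    m: int
    tail_size_range: Tuple[int, int] = (1, 3)
    head_size_range: Tuple[int, int] = (1, 2)
    weight_range: Tuple[float, float] = (1.0, 1.0)
    singleton_tail: bool = False
    self_loop_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 vertices (source and sink)")
        for lo, hi in (self.tail_size_range, self.head_size_range):
            if not (1 <= lo <= hi):
                raise ValueError("size ranges must be nonempty with minimum >= 1")
        if self.tail_size_range[1] > self.n or self.head_size_range[1] > self.n:
            raise ValueError("set sizes cannot exceed the vertex count")
        lo, hi = self.weight_range
        if not (0 <= lo <= hi):
            raise ValueError("weight range must be nonnegative and nonempty")
        if not (0 <= self.self_loop_rate <= 1):
            raise ValueError("self_loop_rate must be in [0, 1]")


class GeneratedInstance(NamedTuple):
    graph: Hypergraph
    source: str
    sink: str
    sink_reachable: bool


def random_hypergraph(spec: GenSpec) -> GeneratedInstance:
    """Draw a random hypergraph with designated source and sink.

    The source is the first vertex and the sink the last; whether the sink
    is actually forward reachable is reported so callers can stratify."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n - 1))
    vertices = [f"v{i:0{width}d}" for i in range(spec.n)]
    ewidth = len(str(max(spec.m - 1, 0)))
    g = Hypergraph(vertices=vertices)
    for j in range(spec.m):
        if spec.singleton_tail:
            tail_size = 1
        else:
            tail_size = int(rng.integers(spec.tail_size_range[0], spec.tail_size_range[1] + 1))
        head_size = int(rng.integers(spec.head_size_range[0], spec.head_size_range[1] + 1))
        tail = frozenset(
            vertices[i] for i in rng.choice(spec.n, size=tail_size, replace=False)
        )
        head = frozenset(
            vertices[i] for i in rng.choice(spec.n, size=head_size, replace=False)
        )
        if spec.self_loop_rate and rng.random() < spec.self_loop_rate and not (tail & head):
            head = (head - {sorted(head)[0]}) | {sorted(tail)[0]}
        lo, hi = spec.weight_range
        weight = lo if lo == hi else float(rng.uniform(lo, hi))
        g.add_edge(Hyperedge(id=f"e{j:0{ewidth}d}", tail=tail, head=head, weight=weight))
    s, t = vertices[0], vertices[-1]
    reachable = t in forward_reachable(g, s).reached_vertices
    return GeneratedInstance(graph=g, source=s, sink=t, sink_reachable=reachable)


def _matrix(count, seed, draw):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        spec = draw(rng, int(rng.integers(0, 2**31 - 1)))
        out.append(random_hypergraph(spec))
    return out


def small_mixed_matrix(count: int = 100, seed: int = 0):
    """Small mixed-size instances (n <= 12, m <= 10, tail/head sizes 1-3,
    unit weights): the regime where the 2^m subset brute force is exact and
    fast, used to certify enumeration and reachability against it."""
    return _matrix(
        count,
        seed,
        lambda rng, s: GenSpec(
            n=int(rng.integers(4, 13)),
            m=int(rng.integers(2, 11)),
            tail_size_range=(1, 3),
            head_size_range=(1, 3),
            seed=s,
        ),
    )


def singleton_tail_matrix(count: int = 200, seed: int = 0):
    """Sparse singleton-tail instances (n <= 30, m <= n, head sizes 1-3,
    weights uniform on [0, 10]): the class where the heuristic is provably
    optimal.  Density stays below one edge per vertex, the sparse regime of
    curated pathway hypergraphs."""

    def draw(rng, s):
        n = int(rng.integers(10, 31))
        return GenSpec(
            n=n,
            m=int(rng.integers(max(2, n // 2), n + 1)),
            head_size_range=(1, 3),
            weight_range=(0.0, 10.0),
            singleton_tail=True,
            seed=s,
        )

    return _matrix(count, seed, draw)


def feasibility_matrix(count: int = 500, seed: int = 0):
    """Mixed instances (n <= 15, m <= 14) spanning reachable and
    unreachable source-sink pairs, for the guarantee that the heuristic
    returns a hyperpath exactly when one exists."""
    return _matrix(
        count,
        seed,
        lambda rng, s: GenSpec(
            n=int(rng.integers(4, 16)),
            m=int(rng.integers(2, 15)),
            tail_size_range=(1, 3),
            head_size_range=(1, 3),
            seed=s,
        ),
    )


def _build(edges) -> Hypergraph:
    return Hypergraph(
        Hyperedge(id=i, tail=frozenset(tl), head=frozenset(hd), weight=w)
        for i, tl, hd, w in edges
    )


def cyclic_only_gadget() -> Tuple[Hypergraph, str, str]:
    """Unit-weight gadget whose unique s,t-hyperpath is cyclic.

    e3 regenerates b, which e2 consumed earlier — the hypergraph analogue
    of a reaction releasing an upstream species — so no ordering of the
    unique hyperpath {e1, e2, e3} avoids a back-pair, and any method
    restricted to acyclic orderings finds nothing.
    """
    g = _build(
        [
            ("e1", {"s"}, {"a", "b"}, 1.0),
            ("e2", {"a", "b"}, {"c"}, 1.0),
            ("e3", {"c"}, {"b", "t"}, 1.0),
        ]
    )
    return g, "s", "t"


def worked_examples() -> Dict[str, Tuple[Hypergraph, str, str]]:
    """Fixed micro-instances with fully known behavior.

    - ``chain``: s -> a -> t; unique hyperpath of weight 2.
    - ``and_gadget``: both branches required to cover the tail {a, b};
      unique hyperpath {e1, e2, e3} of weight 3.
    - ``cyclic_gadget``: see :func:`cyclic_only_gadget`.
    - ``two_route``: two vertex-disjoint routes of weights 2 and 6.
    - ``trim_test``: a branching head makes both e2 (weight 1) and e3
      (weight 10) reach t; greedy trimming must discard e3.
    """
    chain = _build([("e1", {"s"}, {"a"}, 1.0), ("e2", {"a"}, {"t"}, 1.0)])
    and_gadget = _build(
        [
            ("e1", {"s"}, {"a"}, 1.0),
            ("e2", {"s"}, {"b"}, 1.0),
            ("e3", {"a", "b"}, {"t"}, 1.0),
        ]
    )
    two_route = _build(
        [
            ("e1", {"s"}, {"a"}, 1.0),
            ("e2", {"s"}, {"b"}, 5.0),
            ("e3", {"a"}, {"t"}, 1.0),
            ("e4", {"b"}, {"t"}, 1.0),
        ]
    )
    trim_test = _build(
        [
            ("e1", {"s"}, {"a", "b"}, 1.0),
            ("e2", {"a"}, {"t"}, 1.0),
            ("e3", {"b"}, {"t"}, 10.0),
        ]
    )
    cyclic = cyclic_only_gadget()
    return {
        "chain": (chain, "s", "t"),
        "and_gadget": (and_gadget, "s", "t"),
        "cyclic_gadget": cyclic,
        "two_route": (two_route, "s", "t"),
        "trim_test": (trim_test, "s", "t"),
    }
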