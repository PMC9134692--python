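"""Exhaustive generation of all source-sink hyperpaths.

Subproblems are (Out, Keep) pairs of edge-id sets: find an s,t-hyperpath
disjoint from Out, where descendants may not add edges of Keep to their own
out-sets.  The keep-sets guarantee every queued subproblem has a distinct
out-set, so no subproblem is ever solved twice; at most 2^m subproblems
exist.  Solving a subproblem is easy because only out-sets (never in-sets)
constrain it: drop the out-edges, restrict to the forward-reachable edge
set, and greedily remove edges while the sink stays reachable, which yields
a minimal s,t-superpath.

The same hyperpath can still arise from different subproblems, so results
are deduplicated by their (sorted) edge set.  ``shortest_by_enumeration``
doubles as the optimality oracle for the shortest-hyperpath heuristic on
instances small enough to enumerate.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Set

from .model import Hypergraph, Hyperpath
from .reachability import forward_reachable, is_vertex_reachable
from .validation import ordered_hyperpath

__all__ = [
    "Subproblem",
    "EnumerationBudgetExceeded",
    "EnumerationStats",
    "one_hyperpath",
    "all_hyperpaths",
    "shortest_by_enumeration",
]

DEFAULT_BUDGET = 10**6


class EnumerationBudgetExceeded(RuntimeError):
    """The subproblem budget was exhausted before enumeration finished."""


@dataclass(frozen=True)
class Subproblem:
    """(Out, Keep) pair: Out edges are forbidden in the solution; Keep
    edges may not be added to descendants' out-sets.  Out and Keep are
    disjoint, and out-sets are pairwise distinct across all subproblems."""

    out: FrozenSet[str]
    keep: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.out & self.keep:
            raise ValueError("Out and Keep sets must be disjoint")


@dataclass
class EnumerationStats:
    """Instrumentation: subproblems processed and their out-sets (for the
    pairwise-distinctness guarantee)."""

    subproblems: int = 0
    out_sets: List[FrozenSet[str]] = field(default_factory=list)


def _one_hyperpath_edges(
    g: Hypergraph, s: str, t: str, out: FrozenSet[str]
) -> Optional[FrozenSet[str]]:
    """Edge set of one s,t-hyperpath disjoint from ``out`` (or None):
    restrict to the forward-reachable edges minus ``out``, then greedily
    remove edges — in reverse discovery order of the forward sweep — while
    the sink stays reachable, leaving a minimal s,t-superpath."""
    if not g.has_vertex(s) or not g.has_vertex(t):
        return None
    res = forward_reachable(g, s, excluded=frozenset(out))
    if t not in res.reached_vertices:
        return None
    remaining: Set[str] = set(res.reached_edges)
    for eid in reversed(res.edge_order):
        trial = frozenset(remaining - {eid})
        if is_vertex_reachable(g, s, t, trial):
            remaining.discard(eid)
    return frozenset(remaining)


def one_hyperpath(
    g: Hypergraph, s: str, t: str, out: FrozenSet[str] = frozenset()
) -> Optional[Hyperpath]:
    """One s,t-hyperpath disjoint from ``out``, or None if there is none."""
    edges = _one_hyperpath_edges(g, s, t, frozenset(out))
    if edges is None:
        return None
    return ordered_hyperpath(g, s, edges)


def all_hyperpaths(
    g: Hypergraph,
    s: str,
    t: str,
    max_subproblems: int = DEFAULT_BUDGET,
    stats: Optional[EnumerationStats] = None,
) -> List[Hyperpath]:
    """All distinct s,t-hyperpaths, each generated exactly once.

    A FIFO queue starts from the unconstrained subproblem (Out, Keep) =
    (empty, empty).  A solved subproblem with hyperpath P spawns one child
    per edge e of P outside its keep-set, forbidding e and keeping the
    edges handed to earlier siblings; children inherit Out and Keep.
    Raises EnumerationBudgetExceeded rather than returning a partial list.
    """
    queue = deque([Subproblem(out=frozenset(), keep=frozenset())])
    found: List[Hyperpath] = []
    seen: dict = {}  # edge set -> witness ordering
    processed = 0
    while queue:
        sub = queue.popleft()
        processed += 1
        if processed > max_subproblems:
            raise EnumerationBudgetExceeded(
                f"exceeded budget of {max_subproblems} subproblems"
            )
        if stats is not None:
            stats.subproblems = processed
            stats.out_sets.append(sub.out)
        edges = _one_hyperpath_edges(g, s, t, sub.out)
        if edges is None:
            continue
        if edges not in seen:
            path = ordered_hyperpath(g, s, edges)
            seen[edges] = path.edges
            found.append(path)
        handed: Set[str] = set()
        for eid in seen[edges]:  # witness order fixes which sibling keeps what
            if eid in sub.keep:
                continue
            queue.append(
                Subproblem(
                    out=sub.out | {eid},
                    keep=frozenset(sub.keep | handed),
                )
            )
            handed.add(eid)
    return found


def shortest_by_enumeration(
    g: Hypergraph, s: str, t: str, max_subproblems: int = DEFAULT_BUDGET
) -> Optional[Hyperpath]:
    """Minimum-weight s,t-hyperpath by exhaustive enumeration; ties break
    by lexicographically smallest sorted edge-id list.  None when no
    hyperpath exists; raises EnumerationBudgetExceeded on overflow."""
    paths = all_hyperpaths(g, s, t, max_subproblems=max_subproblems)
    if not paths:
        return None
    return min(paths, key=lambda p: (p.weight, tuple(sorted(p.edges))))
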