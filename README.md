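# hyperpaths

Shortest source–sink hyperpaths in general directed hypergraphs, with
reachability primitives, exhaustive hyperpath enumeration, validation
oracles, synthetic instance generators, and a CLI.

## Why directed hypergraphs

Cell-signaling databases describe reactions that consume *sets* of
molecules and produce *sets* of molecules: reactants and positive
regulators on one side, products on the other.  An ordinary graph edge
cannot express "this reaction fires only when **all** of its inputs are
present"; a directed hyperedge e = (tail(e), head(e)) can.  The natural
analogue of a path is then an **s,t-superpath**: an edge subset orderable
as e₁…e_k with tail(e₁) = {s}, every tail(e_i) ⊆ {s} ∪ ⋃_{j<i} head(e_j),
and t ∈ head(e_k).  An **s,t-hyperpath** is a minimal superpath (no proper
subset is one), and the *shortest hyperpath* problem asks for a hyperpath
minimizing ω(P) = Σ_{e∈P} ω(e).  Unlike minimal paths in ordinary graphs,
hyperpaths can be inherently **cyclic** — a downstream reaction may
regenerate an upstream species — and real pathway databases contain
source–target pairs whose *only* hyperpaths are cyclic, which purely
acyclic formulations cannot recover at all.

Shortest hyperpaths is NP-complete, so the core algorithm is a
Dijkstra-like **heuristic over hyperedges**: a min-heap of edges keyed by
the weight of the best hyperpath recovered so far from the source, run on
the *doubly-reachable* subgraph (edges both forward reachable from s and
backward traceable from t).  Recovery of a concrete hyperpath traces
recorded in-edge lists backward to a superpath, then greedily trims it —
attempting removals in decreasing order of finalized length estimates —
until it is minimal.  The heuristic

- always returns a valid hyperpath when one exists (including cyclic ones),
- never beats the true optimum (it is an upper bound), and
- is *provably optimal* on singleton-tail hypergraphs (|tail(e)| = 1
  everywhere).

A companion algorithm enumerates **all** s,t-hyperpaths through
out-set-constrained subproblems with keep-set bookkeeping (every
subproblem has a distinct out-set; at most 2^m subproblems), providing the
exact optimum on instances small enough to enumerate.

## Worked example

The bundled gadget whose unique hyperpath is cyclic (e3 regenerates `b`,
which e2 already consumed):

```sh
$ python -c "from hyperpaths import cyclic_only_gadget, write_hypergraph as w; \
             g, s, t = cyclic_only_gadget(); w(g, 'cyclic.hgr')"
$ cat cyclic.hgr
# hgr v1
e1	s	a,b	1
e2	a,b	c	1
e3	c	b,t	1

$ hyperpaths shortest --graph cyclic.hgr --source s --sink t
{"cyclic": true, "edges": ["e1", "e2", "e3"], "weight": 3.0}

$ hyperpaths enumerate --graph cyclic.hgr --source s --sink t
{"cyclic": true, "edges": ["e1", "e2", "e3"], "weight": 3.0}
{"hyperpaths": 1, "max_weight": 3.0, "min_weight": 3.0, "subproblems": 4}

$ hyperpaths stats --graph cyclic.hgr --source s --sink t
{"backward_traceable": 3, "d": 2, "doubly_reachable": 3, "ell": 9, "forward_reachable": 3, "m": 3, "n": 5, "self_loops": 0, "unreachable_self_loops": 0}
```

The heuristic returns the unique hyperpath {e1, e2, e3} of weight 3 in
witness order (each edge's tail is covered by the source plus earlier
heads); `"cyclic": true` records that every valid ordering has a later
edge whose head re-enters an earlier tail.  Enumeration confirms it is the
only hyperpath, after 4 subproblems.  `stats` mirrors the usual dataset
summary measures: n/m/ℓ/d size parameters plus the forward-, backward-,
and doubly-reachable edge counts for the given source and sink.

Other subcommands: `reach` (reachable edge sets), `validate` (certify a
hyperpath JSON), `simulate` (seeded random instances in HGR-TSV).  Exit
codes: 0 success, 1 no hyperpath, 2 usage/parse error, 3 enumeration
budget exceeded.

### Library use

```python
from hyperpaths import (GenSpec, random_hypergraph,
                        shortest_hyperpath_heuristic, shortest_by_enumeration)

g, s, t, reachable = random_hypergraph(GenSpec(n=20, m=18, seed=7))
path = shortest_hyperpath_heuristic(g, s, t)      # None iff t unreachable
exact = shortest_by_enumeration(g, s, t)          # small instances only
```

Multi-source/multi-sink problems reduce to the single-pair case with
`reduce_sources_sinks` (zero-weight supersource/sink wiring edges), and
`prepare_instance` applies the standard pathway convention: supersource
wired to every vertex with no in-edges (or only self-loop in-edges), sink
wired to the chosen target.

## File format

HGR-TSV: UTF-8 text, `#` comments, one edge per line as
`edge_id<TAB>tail_csv<TAB>head_csv<TAB>weight` with comma-separated vertex
ids and nonnegative decimal weights.  Writing is deterministic (edges
sorted by id, members sorted), so write→read→write is byte-identical.

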