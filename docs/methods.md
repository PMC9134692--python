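# Methods

## Model

A directed hypergraph (V, E) has hyperedges e = (tail(e), head(e)) with
nonempty vertex sets on both sides and a nonnegative weight ω(e).  In
cell-signaling use, a hyperedge is a reaction: reactants and positive
regulators form the tail, products the head.  An *s,t-superpath* is an edge
subset orderable as e₁…e_k with tail(e₁) = {s}, each tail(e_i) ⊆ {s} ∪
⋃_{j<i} head(e_j), and t ∈ head(e_k); an *s,t-hyperpath* is a minimal
superpath (no proper subset is a superpath).  The shortest-hyperpath
problem — minimize ω(P) = Σ_{e∈P} ω(e) — is NP-complete in general, which
is why the central algorithm here is a heuristic.

A hyperpath is *cyclic* when every valid ordering contains a back-pair: a
later edge whose head intersects an earlier edge's tail.  Biologically this
happens when a reaction regenerates an upstream species (a complex breaking
apart and releasing a component).  Cyclicity is decided on the hyperpath's
edge-adjacency digraph (arc e→f iff head(e) ∩ tail(f) ≠ ∅, self-arcs
included): a topological order of an acyclic digraph is a back-pair-free
witness, and a digraph cycle forces a backward arc in every linear order.
A single edge whose head meets its own tail (a self-loop) therefore counts
as cyclic, matching how self-loop instances are conventionally tallied.
The digraph criterion is not merely trusted: a brute-force scan over all
valid orderings is kept as an oracle and the two are asserted equal on
every small hyperpath arising in tests.

### Minimality is subset-minimality, not single-removal stability

Checking that no *single* edge can be removed is strictly weaker than
Definition-level minimality: removing one edge can strand other edges that
a smaller superpath never needed, so a set can survive all single-removal
checks while a proper subset is a superpath (e.g. {({s},{t}), ({s},{a}),
({a},{t})}).  `is_hyperpath` therefore uses the equivalent reachability
form: F contains a superpath (the restricted forward sweep reaches an edge
with t in its head), and F−{e} contains none, for every e ∈ F.  Greedy
trimming that repeatedly deletes edges while the sink stays reachable
produces exactly such sets, so all trimmed outputs are genuine hyperpaths.

## Reachability

Forward reachability (B-connectivity) keeps a per-edge countdown of
uncovered tail vertices and explores vertices breadth-first from the
source; an edge fires when its countdown hits zero.  Backward traceability
marks edges whose head contains a traceable vertex and propagates through
their tails.  Both are linear in the incidence size ℓ = Σ(|tail|+|head|) of
the explored subgraph.  State is per-call (fresh dictionaries) rather than
globally initialized fields; the amortized bounds are the same and repeated
calls cannot interfere.  Queues are FIFO with sorted adjacency, so
discovery orders — used as witness orderings and trim orders — are
deterministic.  Every edge of every s,t-hyperpath is both forward reachable
and backward traceable, so all path computations run on the
doubly-reachable subgraph.

## The shortest-hyperpath heuristic

The search is edge-based Dijkstra: a min-heap of hyperedges keyed by the
weight of the best *recovered* hyperpath from s to that edge.  Edges with
tail exactly {s} seed the heap with key ω(e).  Extracting the minimum-key
edge e finalizes its length estimate by re-recovering an s,e-hyperpath;
then, for each edge f whose tail meets head(e), e is appended to f's
inedges list, f's countdown is decremented for newly covered vertices, and
whenever f's tail is fully covered an s,f-hyperpath is recovered to insert
f or decrease its key (the key is recomputed on every inedge arrival, not
only when the countdown reaches zero).  Finalized lengths never change.
At the end, an s,t-hyperpath is recovered for every reached in-edge of the
sink and the minimum-weight one is returned.

Recovery is two-phase.  Phase I collects an s,e-superpath by tracing
backward through the recorded inedges lists (every recorded in-edge
touching a needed tail vertex is taken, which is what guarantees the
optimality argument on singleton-tail inputs).  Phase II trims the
superpath greedily, attempting removals in decreasing order of the
finalized length estimates — not of raw edge weights, which would tie
everywhere on unit-weight reaction networks — keeping an edge whenever its
removal breaks reachability of the target.  For intermediate s,e
recoveries the target edge is protected and the predicate is "tail(e)
still coverable"; for the final sink recoveries the predicate is "sink
still reachable" and the sink in-edge itself is a trim candidate.  The
latter matters: when one sink in-edge lies inside the superpath recovered
for another, protecting the target could return a superpath that is not
minimal *as an s,t-superpath*.  Trimming against sink-reachability makes
every returned object a certified hyperpath.

Guarantees carried by the test suite rather than asserted in code:
feasibility (a hyperpath is returned iff the sink is forward reachable),
upper-boundedness (never below the enumerated optimum), and exact
optimality on singleton-tail hypergraphs, where the recovered estimates
provably equal true distances.  On general hypergraphs the heuristic can
be suboptimal because inedges lists only contain earlier-extracted edges
and greedy trimming can discard an edge of an optimal path.

### Numerical and tie-break choices

- Heap: binary heap with lazy deletion.  The amortized decrease-key bound
  of a Fibonacci heap is irrelevant at the sizes this package targets; the
  asserted contract is only min-extraction, FIFO tie-break on earliest
  insertion, and decrease-only keys (an attempted increase is a no-op).
- Trim ties (equal length estimates, e.g. all-unit weights): descending
  edge id.  Final sink-edge ties: smaller weight, then lexicographically
  smallest sorted edge list.
- Zero weights are legal everywhere; they arise from the supersource/sink
  wiring edges.  Negative weights are rejected at construction and parse
  time.
- Witness orderings are the edge-discovery order of a forward sweep over
  the final edge set; by minimality the sink-covering edge lands last.

## Enumeration

All s,t-hyperpaths are generated through out-set-constrained subproblems
(Out, Keep): find a hyperpath avoiding Out, where descendants may not
forbid edges in Keep.  A solved subproblem with hyperpath P spawns one
child per edge of P outside Keep (in witness order), each child forbidding
its edge and keeping the edges handed to earlier siblings.  This makes all
out-sets pairwise distinct, bounding subproblems by 2^m; in-set
constraints are deliberately avoided (deciding hyperpath existence with a
required in-set is NP-complete).  One subproblem is solved by restricting
to the forward-reachable edges minus Out and greedily removing edges in
reverse discovery order while the sink stays reachable.  The same
hyperpath can arise from different subproblems, so results are
deduplicated by edge set; only first occurrences are packaged with witness
orderings and cycle flags (duplicates cost one reachability sweep each).
The subproblem budget defaults to 10⁶ and overflow raises rather than
returning a silent partial answer.

## Synthetic instances

`GenSpec`/`random_hypergraph` draw m hyperedges over n vertices with tail
sizes uniform on 1–3 (mean 2) and head sizes uniform on a small range
(defaults 1–2), mirroring the sparsity of curated pathway hypergraphs,
which have small reactant/product sets and fewer hyperedges than vertices.
Random matrices in the tests therefore keep m ≤ n (sparse regime) unless a
test explicitly needs denser graphs.  The generator emulates only the
*structural* regime — set-size and density statistics — not the modular
pathway organization, hub proteins, or unit-weight conventions of real
databases; passing tests demonstrate algorithmic correctness on this
regime, not biological fidelity.  Optional knobs force singleton tails
(the provably optimal class) or inject self-loops.  Identical specs yield
byte-identical serializations.

Fixed gadgets cover the qualitative phenomena: an AND-gadget requiring
both branches, a two-route choice, a trim gadget where greedy removal must
discard the heavy branch, and a cyclic gadget whose unique hyperpath is
cyclic — the situation where any acyclic-only method finds nothing but the
heuristic still succeeds.

## Problem sizes used by the default test run and acceptance script

Chosen to exercise each property at the scale where its exhaustive oracle
is exact and fast:

- enumeration vs. subset brute force: 100 instances, n ≤ 12, m ≤ 10
  (the 2^m scan is the bottleneck);
- singleton-tail optimality vs. enumeration: 200 instances, n ≤ 30,
  m ≤ min(n, 60), weights uniform on [0, 10];
- feasibility: 500 instances, n ≤ 15, m ≤ 14;
- upper bound / equality rate: the co-run subset with m ≤ 12.

## Known limitations

- The heuristic's suboptimality on general hypergraphs is inherent (the
  problem is inapproximable unless P = NP); no lower-bound certificate is
  produced.
- Enumeration is exponential in the worst case; the budget makes this loud
  rather than slow.
- No BioPAX/SBML parsing: instances enter via HGR-TSV or the generators.
- Stoichiometry, reaction rates, and negative regulation are outside the
  model; a regulator is simply a tail member.
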