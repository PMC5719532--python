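# Methods

## Model and semantics

A Boolean network assigns each node a state in {0, 1} and an update rule
over its regulators. All causal claims in this package concern *sustained*
regulator states and long-run target states: an edge or relation of type
"sufficient" from A to B asserts that holding A ON forces B to stabilize ON
regardless of the rest of the network. Each of the six edge types is
formalized as a set of implications over (source state → forced target
state):

| type | implications |
|---|---|
| sufficient | ON → ON |
| necessary | OFF → OFF |
| sufficient & necessary | ON → ON, OFF → OFF |
| sufficient inhibitory | ON → OFF |
| necessary inhibitory | OFF → ON |
| sufficient & necessary inhibitory | ON → OFF, OFF → ON |

Everything else is derived from this implication algebra. The *path chain
function* is relation composition of two implication sets, and the
*subgraph chain function* follows from gate semantics: all necessary
regulators ON (or all sufficient inhibitors OFF) force an AND-gated target
ON; all sufficient regulators OFF (necessary inhibitors ON) force an
OR-gated target OFF. Both tables are regenerated from these semantics at
import time and asserted against hard-coded copies, so a transcription
error in either direction fails immediately.

## Causal graph construction

Rules are parsed into sympy boolean expressions. Each rule's prime
implicants and prime implicates are computed by Quine–McCluskey expansion
over the rule's support (biological rules have small fan-in; a 16-literal
budget guards the exponential case). Per target, whichever form needs
fewer mediators plus edges is rendered (DNF on ties): a single clause
gates the target directly; with several clauses, singleton clauses attach
directly and every multi-literal clause becomes a mediator node, named
deterministically (`_m1`, `_m2`, … in sorted-target order; the `_m` prefix
is reserved and rejected in input). Using *all* prime implicants, not a
minimal cover, is what makes the edge labels complete: every implicant
that could certify a sufficiency is represented.

Rules that simplify to a constant mark the node CONSTANT (kept, with a
logged warning), so downstream percolation sees them.

## Relation search

For a fixed source, the engine saturates facts "the source has a relation
of type τ to node v" under four rules: (1) a direct edge; (2) chaining a
fact over an outgoing edge with the path chain function; (3) *closure*: if
every in-regulator of a node pairs its fact with its edge — subgraph chain
function where defined, path chain function otherwise — and all agree on
one resulting type, that type holds for the node (the source acts as its
own sufficient&necessary regulator); (4) a node certified in both the
sufficient and the necessary direction carries the combined type. Facts
are derived in rounds against a snapshot of the previous round, so every
certificate is a well-founded derivation; the engine is polynomial,
deterministic and independent of iteration order. Each fact carries a
witness subgraph (union of the contributing edges). Queries report the
strongest certified type (combined types before pure ones).

Two semantic guards matter:

* cyclic facts at the source are restricted to the self-consistent types
  (sufficient, necessary, both). A "clamp ON forces itself OFF" cycle is
  vacuous under sustained clamping, and chaining it onward would certify
  false implications.
* closures are refused at CONSTANT nodes: their value does not follow from
  their in-edges.

The search is sound but deliberately not complete — it certifies what the
chain algebra can derive, which is the method's point; percolation can
force states the chain algebra cannot express.

## Oracles

*Percolation* iterates constant propagation of a clamped partial state to
a fixed point; constancy of a restricted rule is decided semantically (a
truth table over the residual support), so non-canonical rule text cannot
hide a forced value. The gate-level twin operates directly on the causal
graph; the two agree on every built graph, which is itself a test.

*Attractor enumeration* compiles rules to truth tables and enumerates the
full state space (numpy-vectorized; guarded at 20 free nodes synchronous,
15 general-asynchronous). Synchronous attractors are the cycles of the
successor map; general-asynchronous attractors are the terminal strongly
connected components of the one-node-at-a-time transition graph
(scipy.sparse.csgraph). The general-asynchronous scheme is the reference
oracle because the framework's claims are update-order independent.

*Random Boolean networks* are drawn uniformly given a node and edge count:
the edge budget is allocated multinomially (capped at n−1 per node,
overflow redistributed), regulators are distinct non-self nodes, and truth
tables are uniform *conditioned on every regulator being essential* —
without that conditioning half of all 1-input tables ignore their
regulator and the network would not actually have the requested edge
count. Test ensembles use 12 nodes at mean in-degree 1.5 (200 networks for
soundness, 50 for reduction preservation), sizes at which exhaustive
attractor enumeration is still exact.

## Stable motifs

A cyclic relation of sufficient (necessary) type at node v certifies the
motif reached by percolating {v: ON} ({v: OFF}); the closure is checked to
be a partial fixed point and reported maximal-by-percolation — the state
set is the driver clamp's full domain of influence, which may merge
several minimal self-sustaining loops plus what they force downstream.
Motifs with identical state sets are merged; all certifying nodes are the
drivers. Collective drivers are found by enumerating node-state sets
(size ≤ k, within non-trivial strongly connected components) whose
percolation closure is itself a partial fixed point, skipping anything a
single node already certifies and any superset of an accepted set.
External drivers are outside nodes whose clamp percolates some driver to
its motif state.

## Reduction

Three methods iterate round-robin to a fixed point, scanning in
lexicographic order (different orders give different, logically equivalent
condensations): transitive reduction of logic-typed edges, collapse of
nodes with identical typed neighborhoods (gate-aware: only nodes computing
the same function of the same regulators merge, and two independent input
signals never merge), and absorption of lone-regulator copy nodes with
out-edges re-typed through the chain function. Contradictory parallel
edges produced by a merge make the target's gate a pointwise tautology or
contradiction; the node is marked CONSTANT (ON for the OR-gated tautology,
OFF for the AND-gated dual) and keeps its in-edges, each of which remains
individually consistent with the constant.

Deleting an in-edge of an AND/OR gate relaxes the all-regulator closure
condition, which can certify implications in the reduced graph that fail
in the original (the removed regulator may float in a complex attractor,
where fixed-point contrapositive reasoning does not apply). Transitive
reduction therefore deletes such an edge only when the remaining
regulators' collective values already force the removed regulator — then
the surviving gate stays semantically complete, and a gate left with one
regulator is retyped to the lone-regulator sufficient&necessary edge.
Finally, the reduction enforces its defining property directly: with
critical nodes declared, every elementary operation is kept only if the
logic-relation table among the critical nodes is unchanged (reverted
otherwise). Critical edges are never deleted; critical nodes are never
removed and keep their names through merges.

## Backbone and driver fraction

Backbone vertices are the in-degree-0 real nodes (signals, considered at
their causative state, ON by default and configurable per signal), the
stable motifs, and the out-degree-0 real nodes (outputs). Percolation is
the authoritative edge semantics — a sufficient edge signal → motif means
the signal's domain of influence contains the whole motif state — with
witness subgraphs from the relation search attached where found (the
search may miss relations percolation certifies; the discrepancy is
logged, never reversed). Motif → output edges are labeled by the forced
output state (sufficient for ON, sufficient-inhibitory for OFF). An
optional transitive-reduction pass prunes the backbone for presentation.

The driver fraction takes the motifs whose stabilization percolates into a
goal assignment, counts the distinct driver nodes (plus collective-driver
members; external drivers behind a flag, off by default), and divides by
the number of regulated (non-signal) nodes.

## Synthetic data: what it does and does not emulate

The bundled fixtures encode the worked examples that define the method's
behavior (the six single-edge motifs, the mediator construction, a
mixed-type linear chain, sufficient/necessary subgraphs with closures, a
cycle–subgraph intersection, a nine-node stable motif, and a minimal
signal → motif → output cascade). Fixtures specified by drawn edge types
rather than printed rules introduce phantom extra regulators (inputs named
`x<Node>`) exactly where a stated edge is weaker than a lone regulator
would force; two of them are transcriptions constrained but not fully
determined by their source drawings. The RBN ensemble covers uniform
random logic, which is *harder* than real biological rules (it includes
XOR-like rules that defeat the chain algebra); passing soundness there
says every certified relation is true, not that the search finds every
relation a real network satisfies. Neither fixtures nor RBNs emulate
multi-valued logic, timed updates, or oscillatory source states, all of
which are out of scope.

## Numerical and engineering choices

* Simple-path enumeration (used by transitive reduction) is a pruned DFS
  over descendants(source) ∩ ancestors(target) with path and step budgets
  (500 paths / 20 000 steps per pair); truncation can only make a deletion
  condition fail, never fabricate one.
* Attractor-oracle checks group relations by (source, state) clamp so each
  state-transition graph is built once.
* All randomness flows from explicit integer seeds (numpy
  `default_rng`); identical seeds give identical networks, searches and
  reductions.
* Determinism everywhere else comes from sorted iteration: node order,
  clause order, mediator numbering, scan order in reductions.

## Known limitations

* The relation search is incomplete by design; percolation and attractor
  analysis remain the authority on what a clamp forces.
* Motifs are not decomposed into minimal self-sustaining loops; the
  reported state set is the maximal percolation closure.
* Collective-driver search is exhaustive only within strongly connected
  components and up to the requested set size.
* Oscillatory logic (complex attractors as motifs, transiently acting
  regulators) is not modeled; all claims are about sustained states.
* The verified-preservation reduction recomputes the critical relation
  table per candidate operation; on networks far larger than the tested
  sizes this is the dominant cost and can be disabled
  (`verify_preservation=False`), reverting to the purely local conditions.
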