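# logicbackbone

Causal-logic analysis of Boolean regulatory networks — for systems
biologists who model gene regulation and signal transduction with Boolean
rules and want to know *which distant nodes control which*, without
simulating trajectories.

A Boolean model assigns each molecular species a state in {0, 1} and an
update rule `f_Node` over its regulators. The structure alone ("X activates
Y") does not say whether X's activity *suffices* to switch Y on or is
merely *required*. This package makes that explicit and exploits it:

* **Causal edge types.** Each regulator–target edge is labeled with one of
  six types by its role in the rule: sufficient (`f_B = A OR x`), necessary
  (`f_B = A AND x`), sufficient inhibitory (`f_B = NOT A AND x`), necessary
  inhibitory (`f_B = NOT A OR x`), and the sufficient&necessary
  (-inhibitory) edges of a lone regulator. Rules are normalized to prime
  implicant (or prime implicate) form, and every multi-literal clause
  becomes an AND/OR-gated *mediator node*, so all in-edges of any node share
  one gate.
* **Chaining.** Two consecutive edges (or paths) compose through the *chain
  function*: e.g. sufficient ∘ sufficient-inhibitory = sufficient
  inhibitory. Where a linear chain breaks, a *subgraph* can still certify an
  implication: if a source is, say, sufficient for **every** necessary
  regulator of a target, it is sufficient for the target (the *subgraph
  chain function*). `find_logic_relation` certifies such long-range
  implications together with a witness subgraph.
* **Stable motifs and drivers.** A sufficient (necessary) cyclic subgraph is
  self-sustaining: clamping its start node ON (OFF) locks a whole partial
  state in place regardless of the rest of the network — a *stable motif*.
  The nodes that can do this are its *driver nodes*; motifs needing several
  simultaneously clamped nodes have *collective drivers*, and outside nodes
  that force a driver are *external drivers*.
* **Logic-preserving reduction.** Logical binary transitive reduction
  (drop an edge paralleled by an equally-typed path), logical vertex
  collapse (merge nodes with identical typed neighborhoods) and edge
  collapse (absorb a lone-regulator copy node) shrink the network while the
  logic-relation table among user-declared critical nodes is verifiably
  unchanged.
* **The logic backbone.** Signals (in-degree-0 nodes), stable motifs and
  outputs, connected by percolation-certified logic edges: a sufficient
  edge from a signal to a motif means the sustained signal stabilizes the
  motif. The *driver fraction* p = n_d / n estimates the probability that a
  random state-changing mutation drives the system into a given attractor.

Everything is checked against two independent oracles: *percolation*
(iterated constant propagation of a clamped state) and exhaustive attractor
enumeration (synchronous and general-asynchronous) for small networks. A
seeded random-Boolean-network generator provides ensembles for property
testing.

## Worked example

The model `f_A = B OR NOT C`, `f_C = B`, `f_D = A OR (B AND C)` (signal B,
output D) is bundled as the fixture `mediator_demo`:

```python
import logicbackbone as lb

rules, graph = lb.fixture("mediator_demo")
for u, v, t in graph.edges():
    print(f"{u} -> {v}: {t.value}")
print(lb.percolate(rules, {"B": 1}))
print(lb.find_logic_relation(graph, "B", "D").etype.value)
```

prints

```
A -> D: sufficient
B -> A: sufficient
B -> C: sufficient_necessary
B -> _m1: necessary
C -> A: necessary_inhibitory
C -> _m1: necessary
_m1 -> D: sufficient
{'B': 1, 'A': 1, 'C': 1, 'D': 1}
sufficient
```

The conjunctive clause `B AND C` appears as the mediator node `_m1` with two
necessary in-edges and a sufficient edge into D; sustaining the signal B
forces every node ON, and the search certifies the long-range sufficient
relation B → D.

The same analyses are available from the shell:

```
logicbackbone fixtures --name motif_demo > motif.txt
logicbackbone find-subgraph motif.txt --source A --target A
logicbackbone find-motifs motif.txt
logicbackbone backbone motif.txt
logicbackbone build motif.txt --dot motif.dot   # red/blue/black edge colors
```

`find-subgraph` with source = target reports the sufficient cyclic subgraph
through all nine nodes of that example — its stable motif — with the
witness node and edge lists as JSON.

## Documentation

`docs/methods.md` describes the model, the algorithms, the numerical and
design choices, and known limitations.
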