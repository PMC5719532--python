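"""The causal graph: typed edges, AND/OR-gated nodes, and mediator nodes.

``build_causal_graph`` renders each rule's prime-implicant DNF or
prime-implicate CNF (whichever needs fewer mediator nodes plus edges; DNF on
ties) into typed edges:

* single-clause DNF -> AND-gated target; positive literals are necessary
  edges, negated literals sufficient-inhibitory edges;
* multi-clause DNF -> OR-gated target; singleton clauses attach directly
  (sufficient / necessary-inhibitory), every multi-literal clause becomes an
  AND-gated *mediator node* with a sufficient edge into the target;
* CNF is rendered dually (OR-gated mediators, necessary edges into an
  AND-gated target);
* a rule with a single literal yields the sufficient&necessary (or
  sufficient&necessary-inhibitory) edge of a lone regulator.

Mediators guarantee that all in-edges of any node share one gate, which is
what makes edge labels compose: a sufficient regulator can only coexist with
necessary inhibitors (OR gate), a necessary regulator only with sufficient
inhibitors (AND gate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import networkx as nx
import sympy
from sympy import And, Not, Or, Symbol

from .chaining import EdgeType
from .rules import MEDIATOR_PREFIX, ImplicantForm, RuleSet, prime_forms

__all__ = ["Gate", "CausalGraph", "build_causal_graph", "validate_compatibility"]

logger = logging.getLogger(__name__)


class Gate(Enum):
    AND = "and"
    OR = "or"
    COPY = "copy"  # single regulator
    INPUT = "input"  # no regulators
    CONSTANT = "constant"


@dataclass
class CausalGraph:
    """Directed graph with causal-logic edge types.

    Thin wrapper over :class:`networkx.DiGraph`.  Node attributes: ``kind``
    ("real" or "mediator"), ``gate`` (:class:`Gate`), and ``value`` for
    CONSTANT nodes.  Edge attribute: ``etype`` (:class:`EdgeType`).
    """

    g: nx.DiGraph = field(default_factory=nx.DiGraph)
    ruleset: RuleSet | None = None

    # -- construction helpers ------------------------------------------------
    def add_node(self, name: str, kind: str = "real", gate: Gate = Gate.INPUT,
                 value: int | None = None) -> None:
        self.g.add_node(name, kind=kind, gate=gate, value=value)

    def add_edge(self, u: str, v: str, etype: EdgeType) -> None:
        for n in (u, v):
            if n not in self.g:
                self.add_node(n)
        self.g.add_edge(u, v, etype=etype)

    # -- queries -------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.g.nodes)

    @property
    def real_nodes(self) -> list[str]:
        return sorted(n for n, d in self.g.nodes(data=True) if d["kind"] == "real")

    @property
    def mediator_nodes(self) -> list[str]:
        return sorted(n for n, d in self.g.nodes(data=True) if d["kind"] == "mediator")

    def gate(self, node: str) -> Gate:
        return self.g.nodes[node]["gate"]

    def kind(self, node: str) -> str:
        return self.g.nodes[node]["kind"]

    def constant_value(self, node: str) -> int | None:
        return self.g.nodes[node].get("value")

    def edge_type(self, u: str, v: str) -> EdgeType:
        try:
            return self.g.edges[u, v]["etype"]
        except KeyError:
            raise KeyError(f"no edge {u} -> {v}") from None

    def edges(self) -> Iterator[tuple[str, str, EdgeType]]:
        for u, v, d in sorted(self.g.edges(data=True)):
            yield u, v, d["etype"]

    def in_edges(self, node: str) -> list[tuple[str, EdgeType]]:
        return sorted((u, d["etype"]) for u, _, d in self.g.in_edges(node, data=True))

    def out_edges(self, node: str) -> list[tuple[str, EdgeType]]:
        return sorted((v, d["etype"]) for _, v, d in self.g.out_edges(node, data=True))

    def signals(self) -> list[str]:
        """In-degree-0 real nodes."""
        return sorted(
            n for n in self.real_nodes
            if self.g.in_degree(n) == 0 and self.gate(n) is not Gate.CONSTANT
        )

    def outputs(self) -> list[str]:
        """Out-degree-0 real nodes."""
        return sorted(n for n in self.real_nodes if self.g.out_degree(n) == 0)

    def copy(self) -> "CausalGraph":
        return CausalGraph(g=self.g.copy(), ruleset=self.ruleset)

    # -- semantics -----------------------------------------------------------
    def node_expression(self, node: str) -> sympy.Basic | None:
        """Boolean expression re-derived from the node's gate and in-edges.

        None for INPUT nodes; constants for CONSTANT nodes.  For graphs built
        from a rule set this is logically equivalent to the original rule
        (with mediator symbols substituted by their own expressions).
        """
        gate = self.gate(node)
        if gate is Gate.INPUT:
            return None
        if gate is Gate.CONSTANT:
            return sympy.true if self.constant_value(node) else sympy.false
        ins = self.in_edges(node)
        if gate is Gate.COPY:
            (u, t), = ins
            return Symbol(u) if t is EdgeType.SUFF_NECC else Not(Symbol(u))
        lits = []
        for u, t in ins:
            if gate is Gate.AND:
                lits.append(Symbol(u) if t is EdgeType.NECC else Not(Symbol(u)))
            else:  # OR
                lits.append(Symbol(u) if t is EdgeType.SUFF else Not(Symbol(u)))
        return And(*lits) if gate is Gate.AND else Or(*lits)

    def to_ruleset(self) -> RuleSet:
        """Rule set over *all* nodes (mediators included) from gate semantics."""
        rules: dict[str, sympy.Basic] = {}
        inputs: list[str] = []
        for n in self.nodes:
            expr = self.node_expression(n)
            if expr is None:
                inputs.append(n)
            else:
                rules[n] = expr
        return RuleSet(rules=rules, inputs=tuple(sorted(inputs)))


# ---------------------------------------------------------------------------
# builder


def _literal_edge_types(polarity: str) -> dict[bool, EdgeType]:
    """Edge type of a direct (singleton-clause) literal by form polarity."""
    if polarity == "DNF":  # OR-gated target
        return {True: EdgeType.SUFF, False: EdgeType.NECC_INH}
    return {True: EdgeType.NECC, False: EdgeType.SUFF_INH}  # CNF, AND-gated


def _clause_edge_types(polarity: str) -> dict[bool, EdgeType]:
    """Edge type into an AND-gated (DNF) / OR-gated (CNF) clause mediator."""
    if polarity == "DNF":
        return {True: EdgeType.NECC, False: EdgeType.SUFF_INH}
    return {True: EdgeType.SUFF, False: EdgeType.NECC_INH}


def _form_cost(form: ImplicantForm) -> tuple[int, int]:
    """(mediators, edges) needed to render the form."""
    clauses = form.clauses
    if len(clauses) <= 1:
        lits = sum(len(c) for c in clauses)
        return 0, lits
    mediators = sum(1 for c in clauses if len(c) > 1)
    edges = sum(len(c) + 1 if len(c) > 1 else 1 for c in clauses)
    return mediators, edges


def _sorted_clauses(form: ImplicantForm) -> list[list[tuple[str, bool]]]:
    return sorted((sorted(c) for c in form.clauses), key=lambda c: (len(c), c))


def build_causal_graph(rules: RuleSet) -> CausalGraph:
    """Render a rule set into its causal-logic graph.

    The per-target normal form (prime DNF vs prime CNF) is chosen to
    minimize mediators + edges, preferring DNF on ties.  Rules that simplify
    to a constant mark the target CONSTANT with a logged warning.  Mediator
    names are deterministic: the reserved prefix plus a counter assigned in
    sorted target order.
    """
    cg = CausalGraph(ruleset=rules)
    for name in rules.inputs:
        cg.add_node(name, kind="real", gate=Gate.INPUT)
    for name in rules.targets:
        cg.add_node(name, kind="real", gate=Gate.INPUT)  # gate set below

    mediator_counter = 0
    for target in rules.targets:
        dnf, cnf = prime_forms(rules.rules[target])
        if not dnf.clauses or frozenset() in dnf.clauses:
            value = 1 if frozenset() in dnf.clauses else 0
            logger.warning("rule for %s simplifies to the constant %d", target, value)
            cg.g.nodes[target].update(gate=Gate.CONSTANT, value=value)
            continue
        form = min((dnf, cnf), key=lambda f: sum(_form_cost(f)))  # DNF wins ties
        clauses = _sorted_clauses(form)

        if len(clauses) == 1:
            clause = clauses[0]
            if len(clause) == 1:
                (name, pos), = clause
                cg.g.nodes[target]["gate"] = Gate.COPY
                cg.add_edge(name, target,
                            EdgeType.SUFF_NECC if pos else EdgeType.SUFF_NECC_INH)
            else:
                gate = Gate.AND if form.polarity == "DNF" else Gate.OR
                cg.g.nodes[target]["gate"] = gate
                emap = _clause_edge_types(form.polarity)
                for name, pos in clause:
                    cg.add_edge(name, target, emap[pos])
            continue

        cg.g.nodes[target]["gate"] = Gate.OR if form.polarity == "DNF" else Gate.AND
        direct = _literal_edge_types(form.polarity)
        into_med = _clause_edge_types(form.polarity)
        med_gate = Gate.AND if form.polarity == "DNF" else Gate.OR
        med_out = EdgeType.SUFF if form.polarity == "DNF" else EdgeType.NECC
        for clause in clauses:
            if len(clause) == 1:
                (name, pos), = clause
                cg.add_edge(name, target, direct[pos])
            else:
                mediator_counter += 1
                med = f"{MEDIATOR_PREFIX}{mediator_counter}"
                cg.add_node(med, kind="mediator", gate=med_gate)
                for name, pos in clause:
                    cg.add_edge(name, med, into_med[pos])
                cg.add_edge(med, target, med_out)
    return cg


# ---------------------------------------------------------------------------
# validation


_AND_TYPES = {EdgeType.NECC, EdgeType.SUFF_INH}
_OR_TYPES = {EdgeType.SUFF, EdgeType.NECC_INH}
_COPY_TYPES = {EdgeType.SUFF_NECC, EdgeType.SUFF_NECC_INH}


def validate_compatibility(graph: CausalGraph) -> list[str]:
    """Check the gate/edge-type compatibility invariants; [] means valid.

    Checks per node: a lone in-edge must be sufficient&necessary(-inhibitory);
    AND gates admit only necessary / sufficient-inhibitory in-edges, OR gates
    only sufficient / necessary-inhibitory ones (so no node mixes a
    sufficient with an independent necessary regulator); mediators have
    exactly one out-edge.
    """
    violations: list[str] = []
    for node in graph.nodes:
        ins = graph.in_edges(node)
        types = {t for _, t in ins}
        gate = graph.gate(node)
        if gate is Gate.CONSTANT:
            continue
        if len(ins) == 1 and not types <= _COPY_TYPES:
            violations.append(
                f"{node}: lone regulator must be sufficient&necessary, got "
                f"{next(iter(types)).value}"
            )
        if len(ins) > 1:
            if gate is Gate.AND and not types <= _AND_TYPES:
                violations.append(f"{node}: AND gate with in-edge types "
                                  f"{sorted(t.value for t in types)}")
            elif gate is Gate.OR and not types <= _OR_TYPES:
                violations.append(f"{node}: OR gate with in-edge types "
                                  f"{sorted(t.value for t in types)}")
            elif gate in (Gate.COPY, Gate.INPUT):
                violations.append(f"{node}: {gate.value} gate with multiple in-edges")
            if {EdgeType.SUFF, EdgeType.NECC} <= types:
                violations.append(
                    f"{node}: independent sufficient and necessary regulators"
                )
        if graph.kind(node) == "mediator" and graph.g.out_degree(node) != 1:
            violations.append(f"{node}: mediator with out-degree "
                              f"{graph.g.out_degree(node)}")
    return violations
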