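"""Shared independent oracles for the test suite.

These deliberately avoid the chaining/search machinery they are used to
check: relations are verified against rule-level percolation and against
exhaustive attractor enumeration of the clamped network.
"""

from __future__ import annotations

import networkx as nx

from logicbackbone import enumerate_attractors, percolate
from logicbackbone.chaining import EdgeType
from logicbackbone.graph import CausalGraph
from logicbackbone.rules import RuleSet
from logicbackbone.search import LogicRelation


def percolation_confirms(rules: RuleSet, rel: LogicRelation) -> bool:
    """Every implication of the relation holds under percolation."""
    for src_state, implied in sorted(rel.etype.implications):
        forced = percolate(rules, {rel.source: src_state})
        if forced.get(rel.target) != implied:
            return False
    return True


def attractors_confirm(rules: RuleSet, rel: LogicRelation,
                       cache: dict | None = None) -> bool:
    """The target holds its implied value in every state of every
    general-asynchronous attractor of the source-clamped network."""
    for src_state, implied in sorted(rel.etype.implications):
        key = (rel.source, src_state)
        if cache is not None and key in cache:
            atts = cache[key]
        else:
            atts = enumerate_attractors(rules, {rel.source: src_state})
            if cache is not None:
                cache[key] = atts
        for att in atts:
            if any(s[rel.target] != implied for s in att.states):
                return False
    return True


def necessary_cycles(graph: CausalGraph) -> list[set[tuple[str, str]]]:
    """Edge sets of necessary cycles: every edge necessary, so the cycle
    chains around to a necessary implication (a self-sustaining OFF loop)."""
    out = []
    for cyc in nx.simple_cycles(graph.g):
        edges = [(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))]
        if all(graph.edge_type(u, v) is EdgeType.NECC for u, v in edges):
            out.append(set(edges))
    return out


def brute_force_is_implicant(expr, clause, all_names) -> bool:
    """A clause (set of signed literals) is an implicant of expr: every
    assignment satisfying the clause satisfies expr."""
    from logicbackbone.rules import evaluate

    names = sorted(all_names)
    fixed = dict(clause)
    free = [n for n in names if n not in fixed]
    for bits in range(1 << len(free)):
        assign = dict(fixed)
        assign.update({n: (bits >> i) & 1 for i, n in enumerate(free)})
        if not evaluate(expr, assign):
            return False
    return True
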