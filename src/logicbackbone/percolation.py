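"""Logic percolation (constant propagation) and partial-fixed-point checks.

Percolation answers: given a clamped partial state, which node states are
forced regardless of the rest of the network?  A node joins the forced set
when its rule, restricted by the current forced set, becomes constant.  The
result is the clamp's *logical domain of influence*; it is monotone in the
clamp, idempotent, and reaches its fixed point in at most one sweep per
node.

``percolate_graph`` is the gate-level counterpart on a causal graph: an
AND-gated node is forced ON when all its necessary in-neighbors are ON and
all its sufficient inhibitors OFF (dually for OR), and forced to the
blocking value as soon as a single in-neighbor blocks it.  On graphs built
from rules the two agree.
"""

from __future__ import annotations

from typing import Mapping

import sympy

from .chaining import EdgeType
from .graph import CausalGraph, Gate
from .rules import RuleSet, restrict, truth_vector

__all__ = ["percolate", "percolate_graph", "is_partial_fixed_point"]


def _as_int(value) -> int:
    return 1 if value else 0


def _constant_of(expr: sympy.Basic) -> int | None:
    """Semantic constancy: 0/1 if expr is constant over its support, else None.

    Constant propagation alone can miss residual tautologies when the rule
    text is not in a canonical form; the truth-table check closes that gap
    (supports are small after restriction).
    """
    if expr is sympy.true:
        return 1
    if expr is sympy.false:
        return 0
    support = sorted(s.name for s in expr.free_symbols)
    if len(support) > 16:
        return None
    tv = truth_vector(expr, support)
    if tv.all():
        return 1
    if not tv.any():
        return 0
    return None


def percolate(rules: RuleSet, clamp: Mapping[str, int]) -> dict[str, int]:
    """Maximal forced assignment (including the clamp) under the rules.

    Nodes whose rules are constant join the forced set unconditionally.

    Raises
    ------
    KeyError
        If the clamp mentions a node the rule set does not know.
    """
    known = set(rules.nodes)
    unknown = set(clamp) - known
    if unknown:
        raise KeyError(f"clamp of unknown node(s): {sorted(unknown)}")

    forced: dict[str, int] = {k: _as_int(v) for k, v in clamp.items()}
    pending = [t for t in rules.targets if t not in forced]
    changed = True
    while changed:
        changed = False
        still = []
        for target in pending:
            reduced = restrict(rules.rules[target], forced)
            value = _constant_of(reduced)
            if value is not None:
                forced[target] = value
                changed = True
            else:
                still.append(target)
        pending = still
    return forced


def percolate_graph(graph: CausalGraph, clamp: Mapping[str, int]) -> dict[str, int]:
    """Gate-level percolation over a causal graph (mediators included)."""
    unknown = set(clamp) - set(graph.g.nodes)
    if unknown:
        raise KeyError(f"clamp of unknown node(s): {sorted(unknown)}")
    forced: dict[str, int] = {k: _as_int(v) for k, v in clamp.items()}
    for n in graph.nodes:
        if graph.gate(n) is Gate.CONSTANT and n not in forced:
            forced[n] = _as_int(graph.constant_value(n))

    def determined(node: str) -> int | None:
        gate = graph.gate(node)
        ins = graph.in_edges(node)
        if gate in (Gate.INPUT, Gate.CONSTANT) or not ins:
            return None
        if gate is Gate.COPY:
            (u, t), = ins
            if u not in forced:
                return None
            on = forced[u]
            return on if t is EdgeType.SUFF_NECC else 1 - on
        if gate is Gate.AND:
            blocking = any(
                (t is EdgeType.NECC and forced.get(u) == 0)
                or (t is EdgeType.SUFF_INH and forced.get(u) == 1)
                for u, t in ins
            )
            if blocking:
                return 0
            allowing = all(
                (t is EdgeType.NECC and forced.get(u) == 1)
                or (t is EdgeType.SUFF_INH and forced.get(u) == 0)
                for u, t in ins
            )
            return 1 if allowing else None
        # OR gate
        activating = any(
            (t is EdgeType.SUFF and forced.get(u) == 1)
            or (t is EdgeType.NECC_INH and forced.get(u) == 0)
            for u, t in ins
        )
        if activating:
            return 1
        silencing = all(
            (t is EdgeType.SUFF and forced.get(u) == 0)
            or (t is EdgeType.NECC_INH and forced.get(u) == 1)
            for u, t in ins
        )
        return 0 if silencing else None

    changed = True
    while changed:
        changed = False
        for node in graph.nodes:
            if node in forced:
                continue
            val = determined(node)
            if val is not None:
                forced[node] = val
                changed = True
    return forced


def is_partial_fixed_point(rules: RuleSet, states: Mapping[str, int]) -> bool:
    """True iff the partial state is self-sustaining: every assigned node's
    rule, restricted by the assignment, is the constant equal to its state.

    Nodes without rules (inputs) are vacuously consistent only if unassigned;
    an assigned input cannot sustain itself and yields False.
    """
    for node, value in states.items():
        if node not in rules.rules:
            return False
        reduced = restrict(rules.rules[node], states)
        if _constant_of(reduced) != _as_int(value):
            return False
    return True
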