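"""Logic-preserving network condensation.

Three methods, iterated round-robin to a fixed point:

* **l-BTR** (logical binary transitive reduction): delete an edge when an
  alternate simple path with the same direction and logic type exists.
* **LVC** (logical vertex collapse): merge two nodes with identical typed
  in- and out-neighborhoods.
* **edge collapse**: a sufficient&necessary(-inhibitory) edge means the
  target simply copies (negates) its lone regulator; the two nodes merge,
  with the target's out-edges re-typed through the path chain function.

Critical nodes and edges are never removed; the merged node keeps the
critical participant's name where one exists.  Scan order is lexicographic
throughout, so the output is deterministic (different orders can yield
different, logically equivalent condensations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .chaining import EdgeType, chain_path, implication_set_to_type
from .graph import CausalGraph, Gate
from .search import _bounded_simple_paths

__all__ = ["ReductionConfig", "lbtr", "lvc", "edge_collapse", "reduce_graph"]

logger = logging.getLogger(__name__)

_ALT_PATH_CAP = 500
_ALT_STEP_CAP = 20_000


@dataclass(frozen=True)
class ReductionConfig:
    """``verify_preservation`` (default on) makes every elementary operation
    conditional on the logic-relation table among the critical nodes being
    unchanged — the defining property of the reduction; operations that
    would alter any critical-pair relation are reverted.  With no critical
    nodes the check is vacuous."""

    critical_nodes: frozenset[str] = frozenset()
    critical_edges: frozenset[tuple[str, str]] = frozenset()
    methods: tuple[str, ...] = ("lbtr", "lvc", "edge_collapse")
    max_rounds: int = 100
    verify_preservation: bool = True

    def validate(self, graph: CausalGraph) -> None:
        missing = set(self.critical_nodes) - set(graph.g.nodes)
        missing_e = {e for e in self.critical_edges if not graph.g.has_edge(*e)}
        if missing or missing_e:
            raise KeyError(
                f"critical elements not in graph: nodes {sorted(missing)}, "
                f"edges {sorted(missing_e)}"
            )


#: collective forcing value of a regulator by its edge type: all necessary
#: regulators ON / sufficient inhibitors OFF force an AND gate ON; all
#: sufficient regulators OFF / necessary inhibitors ON force an OR gate OFF
_AND_COLLECTIVE = {EdgeType.NECC: 1, EdgeType.SUFF_INH: 0}
_OR_COLLECTIVE = {EdgeType.SUFF: 0, EdgeType.NECC_INH: 1}


def _deletion_closure_safe(graph: CausalGraph, u: str, v: str,
                           etype: EdgeType) -> bool:
    """Whether deleting (u, v) can enable a new collective closure at v.

    Removing an in-edge of an AND/OR gate relaxes the "all regulators"
    condition of the subgraph chain function and can certify implications
    that do not hold in the unreduced network (the lost regulator may float
    in a complex attractor).  Deletion is safe when clamping the remaining
    regulators at their collective values already forces u to its own
    collective value, so nothing new becomes derivable.  Nodes without a
    declared AND/OR gate (hand-built graphs, constants) are exempt.
    """
    from .percolation import percolate_graph

    if graph.gate(v) not in (Gate.AND, Gate.OR) or u == v:
        return True
    remaining = [(w, tw) for w, tw in graph.in_edges(v) if w != u]
    if not remaining:
        return True
    types = {etype} | {tw for _, tw in remaining}
    if types <= set(_AND_COLLECTIVE):
        cv = _AND_COLLECTIVE
    elif types <= set(_OR_COLLECTIVE):
        cv = _OR_COLLECTIVE
    else:
        return False
    pruned = CausalGraph(g=nx.restricted_view(graph.g, [], [(u, v)]).copy())
    forced = percolate_graph(pruned, {w: cv[tw] for w, tw in remaining})
    return forced.get(u) == cv[etype]


_SINGLE_RETYPE = {
    Gate.AND: {EdgeType.NECC: EdgeType.SUFF_NECC,
               EdgeType.SUFF_INH: EdgeType.SUFF_NECC_INH},
    Gate.OR: {EdgeType.SUFF: EdgeType.SUFF_NECC,
              EdgeType.NECC_INH: EdgeType.SUFF_NECC_INH},
}


def _normalize_single_regulators(out: CausalGraph) -> None:
    """Retype the lone surviving in-edge of an AND/OR gate.

    Reductions only strip a gate's in-edge when the removed regulator's
    collective state remains forced by the survivors, so the surviving gate
    stays semantically complete; a gate left with one regulator therefore
    just copies (or negates) it, which is the sufficient&necessary edge of
    a lone regulator.  Built graphs never have this shape (a lone regulator
    is rendered as a COPY gate from the start)."""
    for n in out.nodes:
        gate = out.gate(n)
        if gate not in _SINGLE_RETYPE or out.g.in_degree(n) != 1:
            continue
        (u, t), = out.in_edges(n)
        new_t = _SINGLE_RETYPE[gate].get(t)
        if new_t is not None:
            out.g.edges[u, n]["etype"] = new_t
            out.g.nodes[n]["gate"] = Gate.COPY


def _critical_relation_table(graph: CausalGraph, config: ReductionConfig):
    """Logic-relation types among critical-node pairs (None where absent)."""
    from .search import find_logic_relation

    crit = sorted(n for n in config.critical_nodes if n in graph.g)
    table = {}
    for a in crit:
        for b in crit:
            if a == b:
                continue
            rel = find_logic_relation(graph, a, b)
            table[(a, b)] = rel.etype if rel else None
    return table


class _PreservationChecker:
    """Accept or revert elementary operations against the reference table."""

    def __init__(self, graph: CausalGraph, config: ReductionConfig):
        self.config = config
        self.active = bool(config.critical_nodes) and config.verify_preservation
        self.reference = (
            _critical_relation_table(graph, config) if self.active else None
        )

    def accepts(self, candidate: CausalGraph) -> bool:
        if not self.active:
            return True
        return _critical_relation_table(candidate, self.config) == self.reference


def _has_alternate_path(graph: CausalGraph, u: str, v: str,
                        etype: EdgeType) -> bool:
    g = nx.restricted_view(graph.g, [], [(u, v)])
    for path in _bounded_simple_paths(g, u, v, _ALT_PATH_CAP, _ALT_STEP_CAP):
        acc = None
        for a, b in zip(path, path[1:]):
            t = graph.edge_type(a, b)
            acc = t if acc is None else chain_path(acc, t)
            if acc is None:
                break
        if acc == etype:
            return True
    return False


def lbtr(graph: CausalGraph, config: ReductionConfig | None = None) -> CausalGraph:
    """Delete non-critical edges paralleled by an equally-typed path."""
    config = config or ReductionConfig()
    checker = _PreservationChecker(graph, config)
    out = graph.copy()
    out.ruleset = None  # the reduced graph no longer realizes the rules
    changed = True
    while changed:
        changed = False
        for u, v, t in list(out.edges()):
            if (u, v) in config.critical_edges or not out.g.has_edge(u, v):
                continue
            if not (_has_alternate_path(out, u, v, t)
                    and _deletion_closure_safe(out, u, v, t)):
                continue
            candidate = out.copy()
            candidate.g.remove_edge(u, v)
            _normalize_single_regulators(candidate)
            if checker.accepts(candidate):
                out = candidate
                changed = True
    return out


def _neighborhood(graph: CausalGraph, n: str, other: str):
    """Merge signature of n with `other` mapped onto n, so mutual edges
    within the pair compare structurally.  The gate (and constant value)
    is part of the signature: only nodes computing the same function of
    the same regulators are interchangeable."""
    def canon(x: str) -> str:
        return n if x == other else x
    ins = frozenset((canon(u), t) for u, t in graph.in_edges(n))
    outs = frozenset((canon(v), t) for v, t in graph.out_edges(n))
    return graph.gate(n), graph.constant_value(n), ins, outs


def _mergeable(graph: CausalGraph, n: str) -> bool:
    # two regulator-less non-constant nodes (inputs) are independent
    # signals and must never be identified with each other
    return graph.g.in_degree(n) > 0 or graph.gate(n) is Gate.CONSTANT


def lvc(graph: CausalGraph, config: ReductionConfig | None = None) -> CausalGraph:
    """Merge node pairs with identical typed in- and out-neighborhoods.

    Two critical nodes are never merged (skipped with a log message); when
    one of the pair is critical the merged node keeps the critical name.
    """
    config = config or ReductionConfig()
    checker = _PreservationChecker(graph, config)
    out = graph.copy()
    out.ruleset = None  # the reduced graph no longer realizes the rules
    changed = True
    while changed:
        changed = False
        nodes = out.nodes
        for a, b in ((x, y) for i, x in enumerate(nodes) for y in nodes[i + 1:]):
            if a not in out.g or b not in out.g:
                continue
            if not (_mergeable(out, a) and _mergeable(out, b)):
                continue
            if _neighborhood(out, a, b) != _neighborhood(out, b, a):
                continue
            a_crit = a in config.critical_nodes
            b_crit = b in config.critical_nodes
            if a_crit and b_crit:
                logger.info("lvc: not merging critical nodes %s and %s", a, b)
                continue
            drop = a if (b_crit and not a_crit) else b
            candidate = out.copy()
            candidate.g.remove_node(drop)
            _normalize_single_regulators(candidate)
            if checker.accepts(candidate):
                out = candidate
                changed = True
    return out


def _add_edge_combining(out: CausalGraph, u: str, v: str,
                        etype: EdgeType) -> None:
    """Add u -> v, combining with an existing edge of a different type.

    The union of the two implication sets either is one of the six types,
    or it forces the target in every source state — a tautology (constant
    ON, e.g. sufficient plus necessary-inhibitory into an OR gate) or a
    contradiction (constant OFF, the AND-gated dual) — in which case the
    target is marked CONSTANT and stripped of its in-edges.
    """
    if out.gate(v) is Gate.CONSTANT:
        value = out.constant_value(v)
        if all(b == value for _, b in etype.implications):
            if not out.g.has_edge(u, v):
                out.add_edge(u, v, etype)
        return  # drop implications inconsistent with the constant
    if not out.g.has_edge(u, v):
        out.add_edge(u, v, etype)
        return
    old = out.edge_type(u, v)
    if old is etype:
        return
    union = old.implications | etype.implications
    forced_on = {(1, 1), (0, 1)} <= union
    forced_off = {(1, 0), (0, 0)} <= union
    if forced_on or forced_off:
        # tautology (constant ON, e.g. w OR NOT w) or contradiction
        # (constant OFF, w AND NOT w); the node keeps its in-edges — each
        # remains individually consistent with the constant value and paths
        # through the node stay certifiable
        value = 1 if forced_on else 0
        logger.warning(
            "edge_collapse: parallel edges of contradictory polarity onto %s; "
            "marking it CONSTANT %d", v, value,
        )
        out.g.nodes[v].update(gate=Gate.CONSTANT, value=value)
        return
    merged = implication_set_to_type(union)
    if merged is None:  # same source state forcing both values: unrealizable
        logger.warning(
            "edge_collapse: inconsistent parallel edges %s -> %s (%s vs %s); "
            "marking target CONSTANT 1", u, v, old.value, etype.value,
        )
        out.g.nodes[v].update(gate=Gate.CONSTANT, value=1)
        return
    out.g.add_edge(u, v, etype=merged)


def edge_collapse(graph: CausalGraph,
                  config: ReductionConfig | None = None) -> CausalGraph:
    """Collapse sufficient&necessary edges: merge the lone regulator and its
    target into one node carrying the regulator's name.

    The target's out-edges become out-edges of the merged node, re-typed by
    chaining the collapsed edge type with each original type (those rows of
    the path chain function are total).  The collapse is skipped when the
    edge is critical or the target node is critical.
    """
    config = config or ReductionConfig()
    checker = _PreservationChecker(graph, config)
    out = graph.copy()
    out.ruleset = None  # the reduced graph no longer realizes the rules
    rejected: set[tuple[str, str]] = set()
    changed = True
    while changed:
        changed = False
        for a, b, t in list(out.edges()):
            if t not in (EdgeType.SUFF_NECC, EdgeType.SUFF_NECC_INH):
                continue
            if (a, b) in config.critical_edges or b in config.critical_nodes:
                continue
            if (a, b) in rejected or a == b:
                continue
            if Gate.CONSTANT in (out.gate(a), out.gate(b)):
                continue  # a constant is not equivalent to its regulator
            if out.g.in_degree(b) != 1:
                continue  # only a lone regulator can be collapsed
            candidate = out.copy()
            b_out = candidate.out_edges(b)
            candidate.g.remove_node(b)
            for v, vt in b_out:
                if v == b:
                    continue
                new_t = chain_path(t, vt)
                assert new_t is not None  # suff&necc rows always chain
                _add_edge_combining(candidate, a, v, new_t)
            _normalize_single_regulators(candidate)
            if checker.accepts(candidate):
                out = candidate
                changed = True
                break  # re-scan after a merge
            rejected.add((a, b))
    return out


def reduce_graph(graph: CausalGraph,
                 config: ReductionConfig | None = None) -> CausalGraph:
    """Apply the enabled methods round-robin until a full round changes
    nothing or the iteration cap is reached."""
    config = config or ReductionConfig()
    config.validate(graph)
    methods = {"lbtr": lbtr, "lvc": lvc, "edge_collapse": edge_collapse}
    out = graph
    for _ in range(config.max_rounds):
        before = (set(out.g.nodes), set(out.g.edges(data="etype")))
        for name in config.methods:
            out = methods[name](out, config)
        if (set(out.g.nodes), set(out.g.edges(data="etype"))) == before:
            return out
    logger.warning("reduction iteration cap reached")
    return out
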