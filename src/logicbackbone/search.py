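"""Search for logic paths and subgraphs between node pairs.

For a fixed source S, the engine saturates the set of certifiable facts
"S has a relation of type tau to node v" under four derivation rules:

1. an edge S -> v of type t certifies t;
2. a certified relation to u chained with an edge u -> v through the path
   chain function certifies the chained type;
3. *subgraph closure*: if every in-regulator of v pairs its certified
   relation with its edge into v — through the subgraph chain function,
   or the path chain function on the cells where the pairing is a plain
   path — and all regulators agree on one resulting type, that type is
   certified for v (the source itself counts as its own
   sufficient&necessary regulator);
4. a node certified both sufficient and necessary (or both inhibitory
   directions) carries the combined sufficient&necessary type.

Facts are derived round by round against a snapshot of the previous round,
so every certificate rests on a well-founded derivation — sound under
percolation — and the result is independent of iteration order.  Each fact
carries a witness subgraph: the union of the contributing edges.

A relation query returns the strongest certified type (sufficient&necessary
before pure types), with cyclic queries (source == target) certifying
stable motifs.  Closures are refused at CONSTANT nodes, whose value does
not follow from their in-edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .chaining import (
    EdgeType,
    chain_closure,
    chain_path,
)
from .graph import CausalGraph, Gate

__all__ = ["LogicRelation", "find_logic_relation", "find_all_relations"]

logger = logging.getLogger(__name__)

#: caps for the bounded simple-path enumerator (used by the reduction's
#: transitive-reduction step; the relation engine itself is polynomial)
MAX_PATHS = 5000
MAX_STEPS = 200_000

#: deterministic strength order for reporting one relation per query
_PRIORITY = (
    EdgeType.SUFF_NECC,
    EdgeType.SUFF_NECC_INH,
    EdgeType.SUFF,
    EdgeType.NECC,
    EdgeType.SUFF_INH,
    EdgeType.NECC_INH,
)


def _bounded_simple_paths(g: nx.DiGraph, source: str, target: str,
                          max_paths: int, max_steps: int = MAX_STEPS):
    """Simple paths source -> target by explicit DFS with a step budget.

    The graph is first pruned to descendants(source) & ancestors(target);
    successors are visited in sorted order, so output is deterministic.
    A truncated enumeration can only miss paths, never invent one."""
    relevant = (nx.descendants(g, source) | {source}) & (
        nx.ancestors(g, target) | {target}
    )
    if source not in relevant or target not in relevant:
        return []
    sub = g.subgraph(relevant)
    succ = {n: sorted(sub.successors(n)) for n in sub}
    paths: list[list[str]] = []
    path = [source]
    on_path = {source}
    stack = [iter(succ[source])]
    steps = 0
    while stack:
        if len(paths) >= max_paths or steps >= max_steps:
            if steps >= max_steps:
                logger.warning(
                    "path enumeration budget hit for %s -> %s", source, target
                )
            break
        advanced = False
        for w in stack[-1]:
            steps += 1
            if w == target:
                paths.append(path + [target])
                if len(paths) >= max_paths:
                    break
                continue
            if w in on_path:
                continue
            path.append(w)
            on_path.add(w)
            stack.append(iter(succ[w]))
            advanced = True
            break
        if not advanced:
            stack.pop()
            on_path.discard(path.pop())
    return paths


@dataclass(frozen=True)
class LogicRelation:
    """A certified long-range implication ``source -> target`` of a given
    type, with the witness subgraph (union of contributing paths/closures)."""

    source: str
    target: str
    etype: EdgeType
    witness_nodes: frozenset[str]
    witness_edges: frozenset[tuple[str, str]]

    def to_json_dict(self) -> dict:
        return {
            "source": self.source,
            "target": self.target,
            "logic": self.etype.value,
            "witness_nodes": sorted(self.witness_nodes),
            "witness_edges": sorted(map(list, self.witness_edges)),
        }


_Witness = tuple[frozenset[str], frozenset[tuple[str, str]]]


class _SourceAnalysis:
    """All certifiable relations from one source node."""

    def __init__(self, graph: CausalGraph, source: str):
        self.graph = graph
        self.g = graph.g
        self.source = source
        # facts[v][etype] = witness
        self.facts: dict[str, dict[EdgeType, _Witness]] = {}
        self._closure_nodes = [
            v for v in sorted(self.g.nodes)
            if self.g.in_degree(v) > 0 and graph.gate(v) is not Gate.CONSTANT
        ]
        self._saturated = False

    # -- derivation ----------------------------------------------------------

    _CYCLIC_OK = frozenset(
        {EdgeType.SUFF, EdgeType.NECC, EdgeType.SUFF_NECC}
    )

    def _add(self, new, v: str, etype: EdgeType, witness: _Witness) -> None:
        if v == self.source and etype not in self._CYCLIC_OK:
            # a contradictory cyclic implication (clamp ON forces itself OFF)
            # is vacuous under the sustained-clamp semantics; recording it
            # would poison everything chained after it
            return
        if etype in self.facts.get(v, {}):
            return
        new.setdefault(v, {}).setdefault(etype, witness)

    def saturate(self) -> None:
        if self._saturated:
            return
        new: dict[str, dict[EdgeType, _Witness]] = {}
        for v, t in self.graph.out_edges(self.source):
            self._add(new, v, t,
                      (frozenset({self.source, v}), frozenset({(self.source, v)})))
        while new:
            for v, items in new.items():
                self.facts.setdefault(v, {}).update(items)
            snapshot = self.facts
            new = {}
            # rule 2: chain every fact over every outgoing edge
            for u in sorted(snapshot):
                for tau, wit in sorted(snapshot[u].items(), key=lambda i: i[0].value):
                    for v, t in self.graph.out_edges(u):
                        chained = chain_path(tau, t)
                        if chained is not None:
                            self._add(
                                new, v, chained,
                                (wit[0] | {v}, wit[1] | {(u, v)}),
                            )
            # rule 3: subgraph closure at every gated node
            for v in self._closure_nodes:
                for etype, witness in self._closure(v):
                    self._add(new, v, etype, witness)
            # rule 4: combine complementary directions
            for v, items in self.facts.items():
                have = set(items)
                for a, b, c in (
                    (EdgeType.SUFF, EdgeType.NECC, EdgeType.SUFF_NECC),
                    (EdgeType.SUFF_INH, EdgeType.NECC_INH,
                     EdgeType.SUFF_NECC_INH),
                ):
                    if a in have and b in have and c not in have:
                        wa, wb = items[a], items[b]
                        self._add(new, v, c, (wa[0] | wb[0], wa[1] | wb[1]))
        self._saturated = True

    def _closure(self, v: str):
        """Closure outcomes at v with, per outcome, a combined witness."""
        regs = sorted(self.g.predecessors(v))
        per_reg: list[tuple[str, EdgeType, dict[EdgeType, _Witness]]] = []
        for r in regs:
            edge_t = self.graph.edge_type(r, v)
            if r == self.source:
                avail = {EdgeType.SUFF_NECC:
                         (frozenset({self.source}), frozenset())}
            else:
                avail = self.facts.get(r)
                if not avail:
                    return []
            per_reg.append((r, edge_t, avail))
        # outcomes achievable by each regulator
        outcome_sets = []
        for r, edge_t, avail in per_reg:
            outs: dict[EdgeType, EdgeType] = {}
            for tau in sorted(avail, key=lambda t: t.value):
                for c in chain_closure(tau, edge_t):
                    outs.setdefault(c, tau)
            if not outs:
                return []
            outcome_sets.append(outs)
        common = set(outcome_sets[0])
        for outs in outcome_sets[1:]:
            common &= set(outs)
        results = []
        for c in common:
            nodes = {v}
            edges = set()
            for (r, edge_t, avail), outs in zip(per_reg, outcome_sets):
                tau = outs[c]
                wit = avail[tau]
                nodes |= wit[0]
                nodes.add(r)
                edges |= wit[1]
                edges.add((r, v))
            results.append((c, (frozenset(nodes), frozenset(edges))))
        return results

    # -- queries -------------------------------------------------------------

    def relation(self, target: str,
                 wanted: set[EdgeType] | None = None) -> LogicRelation | None:
        self.saturate()
        items = self.facts.get(target, {})
        for t in _PRIORITY:
            if t in items and (wanted is None or t in wanted):
                nodes, edges = items[t]
                return LogicRelation(self.source, target, t, nodes, edges)
        return None


def find_logic_relation(
    graph: CausalGraph,
    source: str,
    target: str,
    wanted: set[EdgeType] | None = None,
) -> LogicRelation | None:
    """Find a logic path or subgraph from source to target.

    ``source == target`` searches for a cyclic relation (a stable-motif
    certificate).  ``wanted`` restricts the accepted relation types.
    Returns None when nothing is certifiable; among certified types the
    strongest (sufficient&necessary first) is reported.
    """
    for n in (source, target):
        if n not in graph.g:
            raise KeyError(f"unknown node {n!r}")
    return _SourceAnalysis(graph, source).relation(target, wanted)


def find_all_relations(
    graph: CausalGraph,
    pairs: list[tuple[str, str]] | None = None,
) -> list[LogicRelation]:
    """Relations for each requested ordered pair (default: all ordered pairs
    of distinct real nodes), in deterministic order, omitting pairs with no
    relation.  The saturated per-source fact table is shared across targets."""
    if pairs is None:
        real = graph.real_nodes
        pairs = [(s, t) for s in real for t in real if s != t]
    by_source: dict[str, _SourceAnalysis] = {}
    out: list[LogicRelation] = []
    for s, t in pairs:
        analysis = by_source.get(s)
        if analysis is None:
            analysis = by_source[s] = _SourceAnalysis(graph, s)
        rel = analysis.relation(t)
        if rel is not None:
            out.append(rel)
    return out
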