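"""Stable motifs: cyclic logic subgraphs, their driver nodes, collective
drivers and external drivers.

A cyclic subgraph that is sufficient (necessary) for its own source node
certifies that clamping the source ON (OFF) stabilizes every node the clamp
percolates to — a partial fixed point that holds regardless of the rest of
the network.  All nodes whose cyclic relation certifies the same stabilized
state set are that motif's driver nodes.  Motifs are reported
maximal-by-percolation: the state set is the full logical domain of
influence of a driver clamp, which may be a union of minimal self-sustaining
loops plus everything they force downstream.

Some motifs cannot be stabilized by any single node; a *collective driver*
is a minimal set of node states (searched inside non-trivial strongly
connected components) whose percolation closure is itself a partial fixed
point.  An *external driver* is a node outside the motif whose clamped
state percolates a driver to its motif state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx

from .chaining import EdgeType
from .graph import CausalGraph
from .percolation import is_partial_fixed_point, percolate
from .rules import RuleSet
from .search import find_logic_relation

__all__ = [
    "StableMotif",
    "find_cyclic_subgraphs",
    "find_collective_motifs",
    "find_external_drivers",
    "find_motifs",
]

_ON_TYPES = frozenset({EdgeType.SUFF, EdgeType.SUFF_NECC})
_OFF_TYPES = frozenset({EdgeType.NECC, EdgeType.SUFF_NECC})


@dataclass
class StableMotif:
    """A self-sustaining partial state with its driver structure.

    ``states`` covers real nodes only (mediator states are derivable);
    ``drivers`` are single nodes whose clamped motif state percolates the
    whole motif, ``collective_drivers`` minimal node-state sets doing the
    same jointly, ``external_drivers`` (node, state) pairs outside the motif
    that force a driver.
    """

    states: dict[str, int]
    drivers: set[str] = field(default_factory=set)
    collective_drivers: list[dict[str, int]] = field(default_factory=list)
    external_drivers: set[tuple[str, int]] = field(default_factory=set)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.states)

    def key(self) -> frozenset[tuple[str, int]]:
        return frozenset(self.states.items())

    def to_json_dict(self) -> dict:
        return {
            "states": dict(sorted(self.states.items())),
            "drivers": sorted(self.drivers),
            "collective_drivers": [
                dict(sorted(c.items())) for c in self.collective_drivers
            ],
            "external_drivers": sorted(map(list, self.external_drivers)),
        }


def _motif_rules(graph: CausalGraph) -> RuleSet:
    """Rule set used for motif-state percolation: the originating rules when
    available, else gate semantics (mediators become explicit nodes)."""
    return graph.ruleset if graph.ruleset is not None else graph.to_ruleset()


def _real_states(graph: CausalGraph, forced: dict[str, int]) -> dict[str, int]:
    real = set(graph.real_nodes)
    return {n: v for n, v in forced.items() if n in real}


def find_cyclic_subgraphs(graph: CausalGraph) -> list[StableMotif]:
    """Stable motifs certified by single-driver cyclic subgraphs.

    For each real node v, searches a cyclic relation v -> v that is
    sufficient (motif state v=ON) or necessary (v=OFF); the motif's full
    state set is the percolation closure of the driving clamp.  Motifs with
    identical state sets are merged and accumulate their drivers.
    """
    rules = _motif_rules(graph)
    found: dict[frozenset, StableMotif] = {}
    for v in graph.real_nodes:
        for state, wanted in ((1, _ON_TYPES), (0, _OFF_TYPES)):
            rel = find_logic_relation(graph, v, v, wanted=set(wanted))
            if rel is None:
                continue
            closure = percolate(rules, {v: state})
            if not is_partial_fixed_point(rules, closure):
                continue
            motif = StableMotif(states=_real_states(graph, closure))
            existing = found.setdefault(motif.key(), motif)
            existing.drivers.add(v)
    return sorted(found.values(), key=lambda m: sorted(m.states.items()))


def find_collective_motifs(
    graph: CausalGraph, max_set_size: int = 2
) -> list[StableMotif]:
    """Motifs that need two or more clamped nodes (collective drivers).

    Candidate node sets of size 2..max_set_size are drawn from non-trivial
    strongly connected components; a state combination qualifies when its
    percolation closure is a partial fixed point.  Motifs already certified
    by a single driver (or by a smaller collective set, or by one candidate
    node alone) are not reported again.
    """
    if max_set_size < 2:
        raise ValueError("max_set_size must be at least 2")
    rules = _motif_rules(graph)
    real = set(graph.real_nodes)
    single = {m.key(): m for m in find_cyclic_subgraphs(graph)}
    singles_closures: set[frozenset] = set(single)
    for v in real:
        for state in (0, 1):
            if v not in rules.rules:
                continue
            closure = percolate(rules, {v: state})
            if is_partial_fixed_point(rules, closure):
                singles_closures.add(frozenset(
                    _real_states(graph, closure).items()))

    found: dict[frozenset, StableMotif] = {}
    accepted_sets: list[set[tuple[str, int]]] = []
    for scc in nx.strongly_connected_components(graph.g):
        if len(scc) < 2:
            continue  # a collective driver needs a non-trivial SCC
        candidates = sorted(n for n in scc & real if n in rules.rules)
        if len(candidates) < 2:
            continue
        for size in range(2, min(max_set_size, len(candidates)) + 1):
            for group in combinations(candidates, size):
                for states in product((0, 1), repeat=size):
                    assign = dict(zip(group, states))
                    key_assign = set(assign.items())
                    if any(a <= key_assign for a in accepted_sets):
                        continue  # a smaller collective set already works
                    closure = percolate(rules, assign)
                    if not is_partial_fixed_point(rules, closure):
                        continue
                    states_key = frozenset(_real_states(graph, closure).items())
                    if states_key in singles_closures:
                        continue  # single-driver motif already covers it
                    accepted_sets.append(key_assign)
                    motif = found.setdefault(
                        states_key,
                        StableMotif(states=dict(sorted(states_key))),
                    )
                    motif.collective_drivers.append(dict(sorted(assign.items())))
    return sorted(found.values(), key=lambda m: sorted(m.states.items()))


def find_external_drivers(
    graph: CausalGraph, motif: StableMotif
) -> set[tuple[str, int]]:
    """(node, state) pairs outside the motif whose clamp percolates some
    driver of the motif to its motif state."""
    rules = _motif_rules(graph)
    out: set[tuple[str, int]] = set()
    drivers = motif.drivers or {
        n for c in motif.collective_drivers for n in c
    }
    outside = [n for n in graph.real_nodes if n not in motif.nodes]
    for node in outside:
        for state in (0, 1):
            closure = percolate(rules, {node: state})
            if any(closure.get(d) == motif.states[d] for d in drivers):
                out.add((node, state))
    return out


def find_motifs(
    graph: CausalGraph,
    collective_max: int | None = None,
    with_external: bool = True,
) -> list[StableMotif]:
    """Full motif report: single-driver cyclic subgraphs, optionally
    collective-driver motifs, each annotated with its external drivers."""
    motifs = find_cyclic_subgraphs(graph)
    if collective_max is not None and collective_max >= 2:
        motifs += find_collective_motifs(graph, collective_max)
    if with_external:
        for m in motifs:
            m.external_drivers = find_external_drivers(graph, m)
    return motifs
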