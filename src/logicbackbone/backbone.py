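"""The logic backbone: signals, stable motifs and outputs, with logic-typed
edges, plus the driver-fraction statistic.

Backbone edges are certified by percolation, the authoritative semantics:
a sufficient edge from a signal to a motif means the sustained signal's
logical domain of influence contains the whole motif state; a motif-to-
motif edge means stabilizing one forces the other; a motif-to-output edge
is labeled by the forced output state (sufficient when the output locks ON,
sufficient-inhibitory when it locks OFF).  Witness subgraphs from the
path/subgraph search are attached where the search finds them — percolation
may certify edges the path-based search misses, never the reverse.

The driver fraction estimates mutation sensitivity: with n non-signal
nodes of which n_d are drivers of motifs that force a goal attractor, a
random state-changing mutation reaches the goal with probability
p = n_d / n and stays localized with probability 1 - p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .chaining import EdgeType
from .graph import CausalGraph
from .motifs import StableMotif
from .percolation import percolate
from .reduction import ReductionConfig, lbtr
from .rules import RuleSet
from .search import LogicRelation, find_logic_relation

__all__ = ["Backbone", "DriverStats", "build_backbone", "driver_fraction"]

logger = logging.getLogger(__name__)


@dataclass
class Backbone:
    """Condensed graph over signal, motif and output vertices.

    Vertex attributes: ``kind`` in {signal, motif, output} and, for motif
    vertices, the :class:`StableMotif`.  Edge attributes: ``etype`` and an
    optional witness :class:`LogicRelation`.
    """

    g: nx.DiGraph = field(default_factory=nx.DiGraph)
    motifs: list[StableMotif] = field(default_factory=list)

    def vertices(self, kind: str | None = None) -> list[str]:
        return sorted(
            n for n, d in self.g.nodes(data=True)
            if kind is None or d["kind"] == kind
        )

    def edges(self) -> list[tuple[str, str, EdgeType]]:
        return sorted((u, v, d["etype"]) for u, v, d in self.g.edges(data=True))

    def to_json_dict(self) -> dict:
        return {
            "vertices": [
                {"name": n, "kind": d["kind"],
                 **({"motif": d["motif"].to_json_dict()}
                    if d["kind"] == "motif" else {})}
                for n, d in sorted(self.g.nodes(data=True))
            ],
            "edges": [
                {"source": u, "target": v, "logic": t.value}
                for u, v, t in self.edges()
            ],
        }


@dataclass(frozen=True)
class DriverStats:
    """Driver-fraction statistic over the non-signal nodes."""

    n: int
    n_d: int

    @property
    def p(self) -> float:
        return self.n_d / self.n

    @property
    def p_prime(self) -> float:
        return 1.0 - self.p


def _forces(closure: Mapping[str, int], states: Mapping[str, int]) -> bool:
    return all(closure.get(k) == v for k, v in states.items())


def build_backbone(
    graph: CausalGraph,
    rules: RuleSet,
    motifs: list[StableMotif],
    signal_states: Mapping[str, int] | None = None,
    apply_lbtr: bool = False,
) -> Backbone:
    """Assemble the backbone from precomputed motifs.

    Signals are the in-degree-0 real nodes, considered at their causative
    state (ON unless overridden in ``signal_states``); outputs the
    out-degree-0 real nodes.  ``apply_lbtr`` prunes edges paralleled by
    equally-typed backbone paths, for presentation.
    """
    bb = Backbone(motifs=list(motifs))
    signals = graph.signals()
    outputs = set(graph.outputs())
    signal_states = dict(signal_states or {})
    motif_names = {}
    for i, m in enumerate(motifs, start=1):
        name = f"motif{i}"
        motif_names[name] = m
        bb.g.add_node(name, kind="motif", motif=m)
    for s in signals:
        bb.g.add_node(s, kind="signal")
    for o in outputs:
        if o not in bb.g:
            bb.g.add_node(o, kind="output")

    closures: dict[str, dict[str, int]] = {}
    for s in signals:
        closures[s] = percolate(rules, {s: signal_states.get(s, 1)})
    for name, m in motif_names.items():
        closures[name] = percolate(rules, dict(m.states))

    def output_edges(vertex: str, closure: Mapping[str, int]) -> None:
        for o in sorted(outputs):
            if o == vertex:
                continue
            val = closure.get(o)
            if val is not None:
                etype = EdgeType.SUFF if val == 1 else EdgeType.SUFF_INH
                bb.g.add_edge(vertex, o, etype=etype, witness=None)

    for s in signals:
        closure = closures[s]
        for name, m in motif_names.items():
            if _forces(closure, m.states):
                witness = _signal_witness(graph, s, m)
                bb.g.add_edge(s, name, etype=EdgeType.SUFF, witness=witness)
        output_edges(s, closure)
    for name, m in motif_names.items():
        closure = closures[name]
        for other, m2 in motif_names.items():
            if other != name and _forces(closure, m2.states):
                bb.g.add_edge(name, other, etype=EdgeType.SUFF, witness=None)
        output_edges(name, closure)

    if apply_lbtr:
        pruned = lbtr(
            CausalGraph(g=bb.g.copy()), ReductionConfig()
        )
        keep = set(pruned.g.edges)
        for e in list(bb.g.edges):
            if e not in keep:
                bb.g.remove_edge(*e)
    return bb


def _signal_witness(graph: CausalGraph, signal: str,
                    motif: StableMotif) -> LogicRelation | None:
    """Best-effort witness: a sufficient subgraph from the signal to some
    driver of the motif (percolation stays authoritative when none is
    found; the discrepancy is logged, never reversed)."""
    for d in sorted(motif.drivers):
        wanted = {EdgeType.SUFF} if motif.states.get(d) == 1 else {EdgeType.NECC}
        rel = find_logic_relation(graph, signal, d, wanted=wanted)
        if rel is not None:
            return rel
    logger.info(
        "backbone: percolation certifies %s -> motif with drivers %s but the "
        "path search found no witness", signal, sorted(motif.drivers),
    )
    return None


def driver_fraction(
    rules: RuleSet,
    motifs: list[StableMotif],
    goal: Mapping[str, int],
    include_external: bool = False,
) -> DriverStats:
    """Fraction of non-signal nodes that are drivers of motifs driving the
    goal (a partial state defining the attractor of interest).

    A motif qualifies when percolating its states forces every goal
    assignment.  ``include_external`` adds external driver nodes to the
    count.  Raises ZeroDivisionError-style ValueError when there are no
    non-signal nodes.
    """
    n = len(rules.targets)
    if n == 0:
        raise ValueError("no non-signal nodes: driver fraction undefined")
    drivers: set[str] = set()
    for m in motifs:
        closure = percolate(rules, dict(m.states))
        if not _forces(closure, goal):
            continue
        drivers |= m.drivers
        for group in m.collective_drivers:
            drivers |= set(group)
        if include_external:
            drivers |= {node for node, _ in m.external_drivers}
    drivers -= set(rules.inputs)
    return DriverStats(n=n, n_d=len(drivers))
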