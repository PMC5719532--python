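"""Causal edge types and the path / subgraph chain functions.

Six causal edge types label regulator->target edges.  Each type is a set of
state implications ``source state -> forced target state``:

============================  ==========================
type                          implications
============================  ==========================
SUFF (sufficient)             ON -> ON
NECC (necessary)              OFF -> OFF
SUFF_NECC                     ON -> ON, OFF -> OFF
SUFF_INH (suff. inhibitory)   ON -> OFF
NECC_INH (necc. inhibitory)   OFF -> ON
SUFF_NECC_INH                 ON -> OFF, OFF -> ON
============================  ==========================

The *path chain function* composes two consecutive implications (relation
composition of the two implication sets).  The *subgraph chain function*
pairs a source-to-regulator relation with a regulator->target edge: when the
pairing holds with the same outcome for *every* regulator of the target, the
collectively forced regulators determine the target through its AND/OR gate.
Both tables are generated from these semantics at import time and asserted
against hard-coded copies, protecting against transcription drift in either
direction.
"""

from __future__ import annotations

from enum import Enum

__all__ = [
    "EdgeType",
    "chain_path",
    "chain_subgraph",
    "chain_closure",
    "closure_candidates",
    "edge_implication",
    "classify_path",
    "implication_set_to_type",
    "PATH_CHAIN_TABLE",
    "SUBGRAPH_CHAIN_TABLE",
]


class EdgeType(Enum):
    """Causal logic type of an edge, path or subgraph."""

    SUFF = "sufficient"
    NECC = "necessary"
    SUFF_NECC = "sufficient_necessary"
    SUFF_INH = "sufficient_inhibitory"
    NECC_INH = "necessary_inhibitory"
    SUFF_NECC_INH = "sufficient_necessary_inhibitory"

    @property
    def implications(self) -> frozenset[tuple[int, int]]:
        """Implication set as (source_state, forced_target_state) pairs."""
        return _IMPLICATIONS[self]

    @property
    def inhibitory(self) -> bool:
        return self in (EdgeType.SUFF_INH, EdgeType.NECC_INH, EdgeType.SUFF_NECC_INH)

    @property
    def parts(self) -> frozenset["EdgeType"]:
        """Decomposition into pure single-implication types."""
        return _PARTS[self]


_IMPLICATIONS = {
    EdgeType.SUFF: frozenset({(1, 1)}),
    EdgeType.NECC: frozenset({(0, 0)}),
    EdgeType.SUFF_NECC: frozenset({(1, 1), (0, 0)}),
    EdgeType.SUFF_INH: frozenset({(1, 0)}),
    EdgeType.NECC_INH: frozenset({(0, 1)}),
    EdgeType.SUFF_NECC_INH: frozenset({(1, 0), (0, 1)}),
}

_BY_IMPLICATIONS = {v: k for k, v in _IMPLICATIONS.items()}

_PARTS = {
    EdgeType.SUFF: frozenset({EdgeType.SUFF}),
    EdgeType.NECC: frozenset({EdgeType.NECC}),
    EdgeType.SUFF_INH: frozenset({EdgeType.SUFF_INH}),
    EdgeType.NECC_INH: frozenset({EdgeType.NECC_INH}),
    EdgeType.SUFF_NECC: frozenset({EdgeType.SUFF, EdgeType.NECC}),
    EdgeType.SUFF_NECC_INH: frozenset({EdgeType.SUFF_INH, EdgeType.NECC_INH}),
}

PURE_TYPES = (EdgeType.SUFF, EdgeType.NECC, EdgeType.SUFF_INH, EdgeType.NECC_INH)


def implication_set_to_type(imps: frozenset[tuple[int, int]]) -> EdgeType | None:
    """Map an implication set back to an EdgeType; None for the empty set."""
    return _BY_IMPLICATIONS.get(imps)


def edge_implication(etype: EdgeType, source_state: int) -> int | None:
    """Forced target state given the source state, or None (undetermined)."""
    for a, b in etype.implications:
        if a == source_state:
            return b
    return None


# ---------------------------------------------------------------------------
# path chain function


def _compose(prev: EdgeType, nxt: EdgeType) -> EdgeType | None:
    composed = frozenset(
        (a, c) for a, b in prev.implications for b2, c in nxt.implications if b == b2
    )
    return _BY_IMPLICATIONS.get(composed) if composed else None


#: Generated path chain table: (preceding, succeeding) -> resulting type or None.
PATH_CHAIN_TABLE: dict[tuple[EdgeType, EdgeType], EdgeType | None] = {
    (p, q): _compose(p, q) for p in EdgeType for q in EdgeType
}


def chain_path(prev: EdgeType, nxt: EdgeType) -> EdgeType | None:
    """Logic type of two concatenated edges/paths, or None if they do not chain."""
    return PATH_CHAIN_TABLE[(prev, nxt)]


# Hard-coded copy of the printed 6x6 path chain table (rows: preceding).
_S, _N, _SN, _SI, _NI, _SNI = (
    EdgeType.SUFF,
    EdgeType.NECC,
    EdgeType.SUFF_NECC,
    EdgeType.SUFF_INH,
    EdgeType.NECC_INH,
    EdgeType.SUFF_NECC_INH,
)
_PRINTED_PATH_TABLE = {
    _S: (_S, None, _S, _SI, None, _SI),
    _N: (None, _N, _N, None, _NI, _NI),
    _SN: (_S, _N, _SN, _SI, _NI, _SNI),
    _SI: (None, _SI, _SI, None, _S, _S),
    _NI: (_NI, None, _NI, _N, None, _N),
    _SNI: (_NI, _SI, _SNI, _N, _S, _SN),
}
_COL_ORDER = (_S, _N, _SN, _SI, _NI, _SNI)


# ---------------------------------------------------------------------------
# subgraph chain function

# Collective forcing through a gate: when *all* same-typed regulators of a
# target hold value v, the gate forces the target to _GATE_FORCED[edge][v]
# (None where a single regulator at v already forces the target, which is
# the single-path case of the path chain table).
_GATE_FORCED = {
    _N: {1: 1},  # AND gate: all necessary regulators ON -> target ON
    _SI: {0: 1},  # AND gate: all sufficient inhibitors OFF -> target ON
    _S: {0: 0},  # OR gate: all sufficient regulators OFF -> target OFF
    _NI: {1: 0},  # OR gate: all necessary inhibitors ON -> target OFF
}


def _subgraph_cell(prev: EdgeType, nxt: EdgeType) -> EdgeType | None:
    ((a, v),) = tuple(prev.implications)  # pure types carry one implication
    forced = _GATE_FORCED[nxt].get(v)
    if forced is None:
        return None
    return _BY_IMPLICATIONS[frozenset({(a, forced)})]


#: Generated subgraph chain table over the four pure types.
SUBGRAPH_CHAIN_TABLE: dict[tuple[EdgeType, EdgeType], EdgeType | None] = {
    (p, q): _subgraph_cell(p, q) for p in PURE_TYPES for q in PURE_TYPES
}


def chain_subgraph(prev: EdgeType, nxt: EdgeType) -> EdgeType | None:
    """Subgraph pairing of a source->regulator relation with a
    regulator->target edge; both must be pure (no sufficient&necessary) types."""
    if prev not in PURE_TYPES or nxt not in PURE_TYPES:
        raise ValueError("subgraph chain function is defined on pure types only")
    return SUBGRAPH_CHAIN_TABLE[(prev, nxt)]


_PRINTED_SUBGRAPH_TABLE = {
    _S: (None, _S, None, _SI),
    _N: (_N, None, _NI, None),
    _SI: (_SI, None, _S, None),
    _NI: (None, _NI, None, _N),
}
_SUB_COL_ORDER = (_S, _N, _SI, _NI)


def _verify_tables() -> None:
    for row, cells in _PRINTED_PATH_TABLE.items():
        for col, want in zip(_COL_ORDER, cells):
            got = PATH_CHAIN_TABLE[(row, col)]
            assert got == want, f"path chain table drift at ({row}, {col})"
    for row, cells in _PRINTED_SUBGRAPH_TABLE.items():
        for col, want in zip(_SUB_COL_ORDER, cells):
            got = SUBGRAPH_CHAIN_TABLE[(row, col)]
            assert got == want, f"subgraph chain table drift at ({row}, {col})"


_verify_tables()


# ---------------------------------------------------------------------------
# closure pairing used by the subgraph search


def chain_closure(rel: EdgeType, edge: EdgeType) -> set[EdgeType]:
    """Possible outcomes of pairing a source->regulator relation with the
    regulator->target edge: the subgraph chain where defined, the path chain
    otherwise, decomposing composite (sufficient&necessary) types into parts.
    """
    out: set[EdgeType] = set()
    for p in rel.parts:
        for q in edge.parts:
            cell = SUBGRAPH_CHAIN_TABLE.get((p, q))
            if cell is None:
                cell = PATH_CHAIN_TABLE[(p, q)]
            if cell is not None:
                out.add(cell)
    return out


def closure_candidates(outcomes: list[set[EdgeType]]) -> EdgeType | None:
    """Combine per-regulator pairing outcomes: all regulators must agree.

    If both the sufficient and the necessary outcome (or both inhibitory
    outcomes) are common, the stronger combined type is returned; otherwise
    the first common pure type in a fixed deterministic order.
    """
    if not outcomes:
        return None
    common = set.intersection(*outcomes)
    if not common:
        return None
    if {_S, _N} <= common:
        return _SN
    if {_SI, _NI} <= common:
        return _SNI
    for t in (_S, _N, _SI, _NI):
        if t in common:
            return t
    return None


def classify_path(graph, nodes) -> EdgeType | None:
    """Left fold of the path chain function over a node sequence's edges.

    ``graph`` is a :class:`~logicbackbone.graph.CausalGraph`; consecutive
    nodes must be joined by edges.  Returns None as soon as a pair fails to
    chain.
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("a path needs at least one edge")
    acc: EdgeType | None = None
    for u, v in zip(nodes, nodes[1:]):
        t = graph.edge_type(u, v)  # raises on missing edge
        acc = t if acc is None else chain_path(acc, t)
        if acc is None:
            return None
    return acc
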