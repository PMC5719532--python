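"""Edge-type semantics and the path / subgraph chain functions."""

import pytest

from logicbackbone import (
    chain_path,
    chain_subgraph,
    classify_path,
    edge_implication,
    parse_rules,
    percolate,
)
from logicbackbone.chaining import (
    EdgeType,
    PATH_CHAIN_TABLE,
    SUBGRAPH_CHAIN_TABLE,
    _PRINTED_PATH_TABLE,
    _PRINTED_SUBGRAPH_TABLE,
    _COL_ORDER,
    _SUB_COL_ORDER,
    PURE_TYPES,
)

S, N, SN = EdgeType.SUFF, EdgeType.NECC, EdgeType.SUFF_NECC
SI, NI, SNI = EdgeType.SUFF_INH, EdgeType.NECC_INH, EdgeType.SUFF_NECC_INH


class TestEdgeImplication:
    @pytest.mark.parametrize("etype, state, want", [
        (N, 0, 0), (N, 1, None),
        (S, 1, 1), (S, 0, None),
        (NI, 0, 1), (NI, 1, None),
        (SI, 1, 0), (SI, 0, None),
        (SN, 1, 1), (SN, 0, 0),
        (SNI, 1, 0), (SNI, 0, 1),
    ])
    def test_forcing_table(self, etype, state, want):
        assert edge_implication(etype, state) == want


class TestPathChainTable:
    def test_regenerated_table_matches_printed_copy(self):
        """All 36 cells of the composed-implication table equal the printed
        chain function."""
        cells = 0
        for row, printed in _PRINTED_PATH_TABLE.items():
            for col, want in zip(_COL_ORDER, printed):
                assert PATH_CHAIN_TABLE[(row, col)] == want
                cells += 1
        assert cells == 36

    @pytest.mark.parametrize("a, b, want", [
        (S, S, S),
        (SI, NI, S),
        (S, N, None),
        (SI, N, SI),
        (SNI, SNI, SN),
    ])
    def test_worked_cells(self, a, b, want):
        assert chain_path(a, b) == want

    @pytest.mark.parametrize("x", list(EdgeType))
    def test_sufficient_necessary_is_the_identity(self, x):
        assert chain_path(SN, x) == x
        assert chain_path(x, SN) == x

    def test_associativity_where_defined(self):
        """Composition of implication sets is associative, so chaining must
        agree on both parenthesizations of every triple."""
        for a in EdgeType:
            for b in EdgeType:
                for c in EdgeType:
                    ab = chain_path(a, b)
                    bc = chain_path(b, c)
                    left = chain_path(ab, c) if ab else None
                    right = chain_path(a, bc) if bc else None
                    if left is not None and right is not None:
                        assert left == right


# two-level rule templates realizing a pure-typed relation into a regulator
_REL_TEMPLATE = {
    S: "{r} *= SRC or x{r}",
    N: "{r} *= SRC and x{r}",
    SI: "{r} *= (not SRC) and x{r}",
    NI: "{r} *= (not SRC) or x{r}",
}
# gate templates for the regulator->target edge type
_GATE_TEMPLATE = {
    N: "T *= r1 and r2",
    SI: "T *= (not r1) and (not r2)",
    S: "T *= r1 or r2",
    NI: "T *= (not r1) or (not r2)",
}


class TestSubgraphChainTable:
    def test_regenerated_table_matches_printed_copy(self):
        cells = 0
        for row, printed in _PRINTED_SUBGRAPH_TABLE.items():
            for col, want in zip(_SUB_COL_ORDER, printed):
                assert SUBGRAPH_CHAIN_TABLE[(row, col)] == want
                cells += 1
        assert cells == 16

    @pytest.mark.parametrize("p, q", [(p, q) for p in PURE_TYPES
                                      for q in PURE_TYPES])
    def test_cells_match_gate_forcing_semantics(self, p, q):
        """Each defined cell is realized by a two-level network: a source
        related to both regulators of a suitably gated target forces the
        target per the cell; '-' cells are instead plain path chains."""
        text = "\n".join([
            _REL_TEMPLATE[p].format(r="r1"),
            _REL_TEMPLATE[p].format(r="r2"),
            _GATE_TEMPLATE[q],
        ])
        rules = parse_rules(text)
        cell = chain_subgraph(p, q)
        (src_state, reg_state), = p.implications
        forced = percolate(rules, {"SRC": src_state})
        if cell is not None:
            (a, b), = cell.implications
            assert a == src_state
            assert forced.get("T") == b, (p, q, forced)
        else:
            # the pairing is a single path: the path chain must be defined
            # and the percolation must agree with it
            path_cell = chain_path(p, q)
            assert path_cell is not None
            (a, b), = path_cell.implications
            assert forced.get("T") == b

    def test_pure_types_partition_path_and_subgraph_cells(self):
        """For pure types, exactly one of the two chain functions applies."""
        for p in PURE_TYPES:
            for q in PURE_TYPES:
                assert (chain_path(p, q) is None) != (
                    chain_subgraph(p, q) is None
                )


class TestClassifyPath:
    def test_caption_classifications(self, chain_demo):
        _, graph = chain_demo
        expected = {
            "ABC": S, "ABCD": SI, "DEF": N, "DEFG": NI, "ABCDEFG": S,
        }
        for path, want in expected.items():
            assert classify_path(graph, list(path)) == want

    def test_missing_edge_raises(self, chain_demo):
        _, graph = chain_demo
        with pytest.raises(KeyError):
            classify_path(graph, ["A", "G"])
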