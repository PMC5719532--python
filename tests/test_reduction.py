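"""Logic-preserving reduction: l-BTR, LVC, edge collapse."""

import numpy as np
import pytest

from logicbackbone import (
    CausalGraph,
    Gate,
    ReductionConfig,
    edge_collapse,
    find_logic_relation,
    lbtr,
    lvc,
    reduce_graph,
)
from logicbackbone.chaining import EdgeType

from conftest import rbn_graph

S, N, SN = EdgeType.SUFF, EdgeType.NECC, EdgeType.SUFF_NECC
SI, NI, SNI = EdgeType.SUFF_INH, EdgeType.NECC_INH, EdgeType.SUFF_NECC_INH


def _triangle(third_type):
    g = CausalGraph()
    g.add_edge("A", "B", S)
    g.add_edge("B", "C", S)
    g.add_edge("A", "C", third_type)
    return g


class TestLbtr:
    def test_parallel_same_type_edge_removed(self):
        red = lbtr(_triangle(S))
        assert ("A", "C") not in red.g.edges

    def test_different_type_kept(self):
        red = lbtr(_triangle(N))
        assert ("A", "C") in red.g.edges

    def test_critical_edge_never_removed(self):
        cfg = ReductionConfig(critical_edges=frozenset({("A", "C")}))
        red = lbtr(_triangle(S), cfg)
        assert ("A", "C") in red.g.edges


class TestLvc:
    def _pair(self, t_in_x, t_in_y):
        g = CausalGraph()
        g.add_edge("R", "X", t_in_x)
        g.add_edge("R", "Y", t_in_y)
        g.add_edge("X", "T", S)
        g.add_edge("Y", "T", S)
        return g

    def test_identical_neighborhoods_merge(self):
        red = lvc(self._pair(N, N))
        assert ("X" in red.g) != ("Y" in red.g)

    def test_type_mismatch_blocks_merge(self):
        red = lvc(self._pair(N, S))
        assert "X" in red.g and "Y" in red.g

    def test_critical_name_kept(self):
        g = CausalGraph()
        g.add_edge("R", "K", N)
        g.add_edge("R", "X", N)
        g.add_edge("K", "T", S)
        g.add_edge("X", "T", S)
        red = lvc(g, ReductionConfig(critical_nodes=frozenset({"K"})))
        assert "K" in red.g and "X" not in red.g

    def test_independent_inputs_not_identified(self):
        g = CausalGraph()
        g.add_edge("X", "T", N)
        g.add_edge("Y", "T", N)
        red = lvc(g)
        assert "X" in red.g and "Y" in red.g


class TestEdgeCollapse:
    def test_tautology_marks_constant_on(self, mediator_demo):
        """Collapsing the lone-regulator edge B->C makes both of A's
        regulators the same node with opposite polarity: A locks ON."""
        _, g = mediator_demo
        red = edge_collapse(g)
        assert red.gate("A") is Gate.CONSTANT
        assert red.constant_value("A") == 1

    def test_inverted_collapse_retypes_out_edges(self):
        g = CausalGraph()
        g.add_edge("A", "B", SNI)
        g.add_edge("B", "C", S)
        g.add_edge("X", "C", S)  # keeps C multi-regulated
        red = edge_collapse(g)
        assert "B" not in red.g
        assert red.edge_type("A", "C") == NI

    def test_chain_of_copies_collapses_to_one_node(self):
        g = CausalGraph()
        g.add_edge("A", "B", SN)
        g.add_edge("B", "C", SN)
        red = edge_collapse(g)
        assert red.nodes == ["A"]

    def test_critical_target_not_collapsed(self):
        g = CausalGraph()
        g.add_edge("A", "B", SN)
        cfg = ReductionConfig(critical_nodes=frozenset({"B"}))
        assert "B" in edge_collapse(g, cfg).g


class TestReduce:
    def test_demo_reduces_to_few_nodes(self, mediator_demo):
        _, g = mediator_demo
        red = reduce_graph(g)
        assert len(red.nodes) <= 4

    def test_all_critical_unchanged(self, mediator_demo):
        _, g = mediator_demo
        cfg = ReductionConfig(
            critical_nodes=frozenset(g.nodes),
            critical_edges=frozenset((u, v) for u, v, _ in g.edges()),
        )
        red = reduce_graph(g, cfg)
        assert set(red.g.nodes) == set(g.g.nodes)
        assert set(red.g.edges) == set(g.g.edges)

    def test_unknown_critical_raises(self, mediator_demo):
        _, g = mediator_demo
        with pytest.raises(KeyError):
            reduce_graph(g, ReductionConfig(critical_nodes=frozenset({"zz"})))

    def test_counts_non_increasing_and_deterministic(self):
        for seed in range(8):
            _, g = rbn_graph(seed)
            r1 = reduce_graph(g)
            r2 = reduce_graph(g)
            assert len(r1.nodes) <= len(g.nodes)
            assert r1.g.number_of_edges() <= g.g.number_of_edges()
            assert set(r1.g.edges(data="etype")) == set(r2.g.edges(data="etype"))
            assert set(r1.g.nodes) == set(r2.g.nodes)

    @pytest.mark.parametrize("seed", range(10))
    def test_critical_relations_preserved(self, seed):
        """Relation types among critical nodes are identical before and
        after reduction (full 50-network ensemble in the acceptance suite)."""
        _, g = rbn_graph(seed)
        rng = np.random.default_rng(1000 + seed)
        crit = sorted(rng.choice(g.real_nodes, size=5, replace=False).tolist())
        red = reduce_graph(g, ReductionConfig(critical_nodes=frozenset(crit)))
        for a in crit:
            for b in crit:
                if a == b:
                    continue
                before = find_logic_relation(g, a, b)
                after = find_logic_relation(red, a, b)
                assert (before.etype if before else None) == \
                    (after.etype if after else None)
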