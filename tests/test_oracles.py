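"""Ground-truth engines: percolation, partial fixed points, attractor
enumeration, and the random-network generator."""

import pytest

from logicbackbone import (
    RBNSpec,
    enumerate_attractors,
    generate_rbn,
    is_partial_fixed_point,
    parse_rules,
    percolate,
    percolate_graph,
)

from conftest import rbn_graph


class TestPercolate:
    def test_signal_on_forces_everything(self, mediator_demo):
        rules, _ = mediator_demo
        assert percolate(rules, {"B": 1}) == {"B": 1, "A": 1, "C": 1, "D": 1}

    def test_signal_off_rescues_through_inhibition(self, mediator_demo):
        rules, _ = mediator_demo
        assert percolate(rules, {"B": 0}) == {"B": 0, "C": 0, "A": 1, "D": 1}

    def test_empty_clamp_forces_only_constants(self):
        rules = parse_rules("A *= B or not B\nC *= A and D\n")
        assert percolate(rules, {}) == {"A": 1}

    def test_motif_demo_states(self, motif_demo):
        rules, _ = motif_demo
        forced = percolate(rules, {"A": 1})
        want_on = {"A", "B", "C", "D", "E", "I"}
        want_off = {"G", "F", "H"}
        assert all(forced[n] == 1 for n in want_on)
        assert all(forced[n] == 0 for n in want_off)

    def test_unknown_clamp_raises(self, mediator_demo):
        rules, _ = mediator_demo
        with pytest.raises(KeyError):
            percolate(rules, {"Z": 1})

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_and_idempotent(self, seed):
        rules, _ = rbn_graph(seed)
        small = percolate(rules, {"n01": 1})
        extra = next((n for n in rules.nodes if n not in small), None)
        if extra is not None:
            big = percolate(rules, dict(small, **{extra: 0}))
            # monotone: a compatible larger clamp forces a superset
            assert all(big[k] == v for k, v in small.items())
        # idempotent: percolating the forced set reproduces it exactly
        assert percolate(rules, small) == small

    @pytest.mark.parametrize("seed", range(40))
    def test_gate_level_agrees_with_rule_level(self, seed):
        """Gate percolation on the causal graph forces exactly the same real
        node states as rule percolation."""
        rules, graph = rbn_graph(seed)
        real = set(rules.nodes)
        for node in ("n01", "n05"):
            for state in (0, 1):
                by_rules = percolate(rules, {node: state})
                by_gates = percolate_graph(graph, {node: state})
                assert {k: v for k, v in by_gates.items() if k in real} \
                    == by_rules

    def test_gate_level_on_fixtures(self, motif_demo):
        rules, graph = motif_demo
        real = set(rules.nodes)
        by_rules = percolate(rules, {"A": 1})
        by_gates = percolate_graph(graph, {"A": 1})
        assert {k: v for k, v in by_gates.items() if k in real} == by_rules


class TestPartialFixedPoint:
    def test_motif_demo_caption_state(self, motif_demo):
        rules, _ = motif_demo
        states = {"A": 1, "B": 1, "C": 1, "D": 1, "E": 1, "I": 1,
                  "G": 0, "F": 0, "H": 0}
        assert is_partial_fixed_point(rules, states)

    def test_positive_self_loop(self):
        rules = parse_rules("A *= A")
        assert is_partial_fixed_point(rules, {"A": 1})
        assert is_partial_fixed_point(rules, {"A": 0})

    def test_negative_self_loop(self):
        rules = parse_rules("A *= not A")
        assert not is_partial_fixed_point(rules, {"A": 1})


class TestAttractors:
    def test_mutual_inhibition_has_two_fixed_points(self):
        rules = parse_rules("A *= not B\nB *= not A\n")
        atts = enumerate_attractors(rules)
        fps = {frozenset(a.states[0].items()) for a in atts if a.is_fixed_point}
        assert fps == {
            frozenset({("A", 1), ("B", 0)}),
            frozenset({("A", 0), ("B", 1)}),
        }

    def test_negation_cycles_synchronously(self):
        rules = parse_rules("A *= not A")
        atts = enumerate_attractors(rules, scheme="synchronous")
        assert [len(a.states) for a in atts] == [2]

    def test_clamped_demo_has_unique_fixed_point(self, mediator_demo):
        rules, _ = mediator_demo
        atts = enumerate_attractors(rules, {"B": 1})
        assert len(atts) == 1 and atts[0].is_fixed_point
        assert atts[0].states[0] == {"A": 1, "B": 1, "C": 1, "D": 1}

    def test_size_guard(self):
        rules = generate_rbn(RBNSpec(n=16, k_in=1.0, seed=0))
        with pytest.raises(ValueError):
            enumerate_attractors(rules, scheme="general_asynchronous")

    @pytest.mark.parametrize("seed", range(30))
    def test_percolation_consistent_with_attractors(self, seed):
        """Every percolation-forced node holds its forced value in every
        attractor of the clamped system."""
        rules, _ = rbn_graph(seed, n=10, k_in=1.5)
        clamp = {"n01": seed % 2}
        forced = percolate(rules, clamp)
        for att in enumerate_attractors(rules, clamp):
            for state in att.states:
                for node, value in forced.items():
                    assert state[node] == value


class TestRandomNetworks:
    def test_seed_reproducibility(self):
        spec = RBNSpec(n=20, k_in=1.5, seed=1)
        assert generate_rbn(spec) == generate_rbn(spec)

    def test_edge_budget_is_exact(self):
        rules = generate_rbn(RBNSpec(n=12, k_in=1.5, seed=3))
        assert sum(len(rules.regulators(t)) for t in rules.targets) == 18

    def test_single_unregulated_node(self):
        rules = generate_rbn(RBNSpec(n=1, edges=0, seed=7))
        assert rules.targets == () and rules.inputs == ("n1",)

    def test_infeasible_edge_count(self):
        with pytest.raises(ValueError):
            generate_rbn(RBNSpec(n=3, edges=7, seed=0))

    def test_every_regulator_is_essential(self):
        rules = generate_rbn(RBNSpec(n=10, k_in=2.0, seed=5))
        for t in rules.targets:
            # free symbols match the structural regulator draw exactly
            assert len(rules.regulators(t)) >= 1
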