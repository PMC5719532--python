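"""Rule parsing, evaluation, restriction and prime normal forms."""

import pytest
from hypothesis import given, settings, strategies as st
from sympy import And, Not, Or, Symbol
import sympy

from logicbackbone import evaluate, parse_boolnet, parse_rules, prime_forms, restrict
from logicbackbone.rules import (
    RuleSyntaxError,
    expressions_equivalent,
    format_expression,
    parse_expression,
    truth_vector,
)

from lb_oracles import brute_force_is_implicant


class TestParsing:
    def test_targets_and_inputs(self):
        rs = parse_rules("A *= B or not C\nC *= B\nD *= A or (B and C)\n")
        assert rs.targets == ("A", "C", "D")
        assert rs.inputs == ("B",)

    def test_self_regulation_has_no_inputs(self):
        rs = parse_rules("A *= A")
        assert rs.targets == ("A",) and rs.inputs == ()

    def test_plain_equals_and_comments(self):
        rs = parse_rules("# a comment\nA = B and not C  # trailing\n")
        assert evaluate(rs.rules["A"], {"B": 1, "C": 0}) == 1

    @pytest.mark.parametrize("bad, line", [
        ("A *= B or", 1),
        ("C *= B\nA *= (B\n", 2),
        ("A *= B\nA *= C", 2),
        ("A *= and B", 1),
    ])
    def test_syntax_errors_carry_line_numbers(self, bad, line):
        with pytest.raises(RuleSyntaxError) as err:
            parse_rules(bad)
        assert err.value.line == line

    def test_reserved_mediator_prefix_rejected(self):
        with pytest.raises(RuleSyntaxError):
            parse_rules("_m1 *= B")

    def test_boolnet_dialect(self):
        rs = parse_boolnet("targets, factors\nA, B & !C\nC, B\n")
        assert rs.targets == ("A", "C")
        assert evaluate(rs.rules["A"], {"B": 1, "C": 0}) == 1

    def test_round_trip_through_text(self):
        rs = parse_rules("A *= B or not C\nC *= B\n")
        again = parse_rules(rs.to_text())
        assert all(
            expressions_equivalent(rs.rules[t], again.rules[t])
            for t in rs.targets
        )


class TestEvaluate:
    @pytest.mark.parametrize("expr, assignment, want", [
        ("B or not C", {"B": 0, "C": 0}, 1),
        ("B or not C", {"B": 0, "C": 1}, 0),
        ("1", {}, 1),
        ("A or (B and C)", {"A": 0, "B": 1, "C": 1}, 1),
    ])
    def test_examples(self, expr, assignment, want):
        assert evaluate(parse_expression(expr), assignment) == want

    def test_missing_assignment(self):
        with pytest.raises(KeyError):
            evaluate(parse_expression("A and B"), {"A": 1})


class TestRestrict:
    def test_partial_simplification(self):
        expr = parse_expression("B or not C")
        assert restrict(expr, {"C": 1}) == Symbol("B")
        assert restrict(expr, {"C": 0}) is sympy.true

    def test_empty_restriction_is_identity(self):
        expr = parse_expression("B or not C")
        assert restrict(expr, {}) == expr


def _clauses(form):
    return {frozenset(c) for c in form.clauses}


class TestPrimeForms:
    def test_or_of_and(self):
        dnf, cnf = prime_forms(parse_expression("A or (B and C)"))
        assert _clauses(dnf) == {
            frozenset({("A", True)}),
            frozenset({("B", True), ("C", True)}),
        }
        assert _clauses(cnf) == {
            frozenset({("A", True), ("B", True)}),
            frozenset({("A", True), ("C", True)}),
        }

    def test_consensus_reduces_to_single_literal(self):
        dnf, _ = prime_forms(parse_expression("(A and B) or (not A and B)"))
        assert _clauses(dnf) == {frozenset({("B", True)})}

    def test_contradiction_has_empty_dnf(self):
        dnf, cnf = prime_forms(parse_expression("A and not A"))
        assert dnf.clauses == frozenset()
        assert cnf.clauses == frozenset([frozenset()])

    def test_literal_budget(self):
        names = [f"v{i}" for i in range(17)]
        expr = Or(*[Symbol(n) for n in names])
        with pytest.raises(ValueError):
            prime_forms(expr)


# random boolean expressions over a small variable pool
_names = st.sampled_from(["A", "B", "C", "D"])


def _exprs(depth=3):
    leaf = _names.map(Symbol)
    return st.recursive(
        leaf,
        lambda inner: st.one_of(
            st.tuples(inner, inner).map(lambda p: And(*p)),
            st.tuples(inner, inner).map(lambda p: Or(*p)),
            inner.map(Not),
        ),
        max_leaves=8,
    )


@settings(max_examples=80, derandomize=True, deadline=None)
@given(_exprs())
def test_prime_forms_equivalent_to_input(expr):
    """Both Blake forms evaluate identically to the original expression."""
    if expr in (sympy.true, sympy.false):
        return
    dnf, cnf = prime_forms(expr)
    assert expressions_equivalent(dnf.to_expression(), expr)
    assert expressions_equivalent(cnf.to_expression(), expr)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(_exprs())
def test_dnf_clauses_are_minimal_implicants(expr):
    """Every DNF clause is an implicant and dropping any literal breaks it."""
    dnf, _ = prime_forms(expr)
    names = {s.name for s in expr.free_symbols}
    for clause in dnf.clauses:
        assert brute_force_is_implicant(expr, clause, names)
        for lit in clause:
            smaller = set(clause) - {lit}
            assert not brute_force_is_implicant(expr, smaller, names)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(_exprs(), st.dictionaries(_names, st.integers(0, 1)))
def test_restrict_commutes_with_evaluate(expr, partial):
    """restrict-then-evaluate equals evaluate on the union assignment."""
    names = sorted({s.name for s in expr.free_symbols})
    free = [n for n in names if n not in partial]
    reduced = restrict(expr, partial)
    for bits in range(1 << len(free)):
        rest = {n: (bits >> i) & 1 for i, n in enumerate(free)}
        full = dict(partial, **rest)
        assert evaluate(reduced, full) == evaluate(expr, full)


def test_truth_vector_matches_pointwise_evaluation():
    expr = parse_expression("(A or not B) and C")
    names = ["A", "B", "C"]
    tv = truth_vector(expr, names)
    for i in range(8):
        assign = {n: (i >> j) & 1 for j, n in enumerate(names)}
        assert bool(tv[i]) == bool(evaluate(expr, assign))


def test_format_expression_round_trips():
    text = "(A and not B) or C"
    expr = parse_expression(text)
    assert expressions_equivalent(parse_expression(format_expression(expr)), expr)
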