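"""Boolean regulatory rules: parsing, evaluation, restriction and prime normal forms.

A Boolean model is a set of update rules, one per regulated node, written in a
plain-text format with one rule per line::

    # comment
    A *= B or not C
    C *= B
    D *= A or (B and C)

``A = expr`` is accepted as a synonym of ``A *= expr``.  Operators ``and``,
``or``, ``not`` are case-insensitive; identifiers match ``[A-Za-z0-9_]+``;
the constants ``0``/``1`` (also ``false``/``true``) hold a node OFF/ON.
Nodes that appear only on right-hand sides are the model's inputs (signals).

Expressions are represented as sympy boolean expressions over
:class:`sympy.Symbol` leaves, which gives evaluation and constant
propagation for free.  Prime implicants and prime implicates (the Blake
canonical DNF/CNF) are computed by Quine-McCluskey expansion over the
rule's support; regulatory rules have small fan-in, so the exponential
cost is acceptable and guarded by a literal budget.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import sympy
from sympy import And, Not, Or, Symbol
from sympy.logic.boolalg import BooleanFalse, BooleanTrue

__all__ = [
    "RuleSet",
    "ImplicantForm",
    "RuleSyntaxError",
    "MEDIATOR_PREFIX",
    "parse_rules",
    "parse_boolnet",
    "evaluate",
    "restrict",
    "prime_forms",
    "truth_vector",
    "expressions_equivalent",
]

#: Reserved prefix for mediator node names generated by the causal-graph builder.
MEDIATOR_PREFIX = "_m"

_IDENT_RE = re.compile(r"[A-Za-z0-9_]+")
_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<ident>[A-Za-z0-9_]+))")


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class RuleSet:
    """A Boolean model: one update rule per regulated node.

    Attributes
    ----------
    rules:
        Mapping target node -> sympy boolean expression.
    inputs:
        Nodes referenced by some rule but never regulated themselves
        (in-degree-0 signals), in sorted order.
    """

    rules: dict[str, sympy.Basic]
    inputs: tuple[str, ...]

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node names (targets and inputs), sorted."""
        return tuple(sorted(set(self.rules) | set(self.inputs)))

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(sorted(self.rules))

    def regulators(self, target: str) -> tuple[str, ...]:
        """Sorted support of the target's rule."""
        return tuple(sorted(s.name for s in self.rules[target].free_symbols))

    def to_text(self) -> str:
        """Render back into the rule text format."""
        lines = [f"{t} *= {format_expression(self.rules[t])}" for t in self.targets]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ImplicantForm:
    """A set of clauses over signed literals: either all prime implicants
    (``polarity == "DNF"``) or all prime implicates (``polarity == "CNF"``).

    Each clause is a frozenset of ``(node, positive)`` pairs.  An empty DNF is
    the constant 0 and a DNF containing the empty clause is the constant 1
    (dually for CNF).
    """

    clauses: frozenset[frozenset[tuple[str, bool]]]
    polarity: str  # "DNF" | "CNF"

    def __post_init__(self):
        if self.polarity not in ("DNF", "CNF"):
            raise ValueError(f"polarity must be DNF or CNF, got {self.polarity!r}")

    def to_expression(self) -> sympy.Basic:
        inner, outer = (And, Or) if self.polarity == "DNF" else (Or, And)
        terms = [
            inner(*[Symbol(n) if pos else Not(Symbol(n)) for n, pos in sorted(c)])
            for c in sorted(self.clauses, key=lambda c: sorted(c))
        ]
        return outer(*terms) if terms else (
            sympy.false if self.polarity == "DNF" else sympy.true
        )


# ---------------------------------------------------------------------------
# parsing


class _Parser:
    """Recursive-descent parser for one rule right-hand side."""

    def __init__(self, tokens: list[str], line: int):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", self.line)
        self.pos += 1
        return tok

    def parse(self) -> sympy.Basic:
        expr = self.expr()
        if self.peek() is not None:
            raise RuleSyntaxError(f"unexpected token {self.peek()!r}", self.line)
        return expr

    def expr(self) -> sympy.Basic:
        terms = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            terms.append(self.term())
        return Or(*terms)

    def term(self) -> sympy.Basic:
        factors = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            factors.append(self.factor())
        return And(*factors)

    def factor(self) -> sympy.Basic:
        tok = self.take()
        low = tok.lower()
        if low == "not":
            return Not(self.factor())
        if tok == "(":
            inner = self.expr()
            if self.take() != ")":
                raise RuleSyntaxError("missing closing parenthesis", self.line)
            return inner
        if tok == ")":
            raise RuleSyntaxError("unexpected ')'", self.line)
        if low in ("0", "false"):
            return sympy.false
        if low in ("1", "true"):
            return sympy.true
        if low in ("and", "or"):
            raise RuleSyntaxError(f"unexpected operator {tok!r}", self.line)
        if _IDENT_RE.fullmatch(tok):
            return Symbol(tok)
        raise RuleSyntaxError(f"bad token {tok!r}", self.line)


def _tokenize(text: str, line: int) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            raise RuleSyntaxError(f"bad character {text[pos]!r}", line)
        tokens.append(m.group(m.lastgroup))
        pos = m.end()
    return tokens


def parse_expression(text: str, line: int = 1) -> sympy.Basic:
    """Parse a single Boolean expression in the rule grammar."""
    tokens = _tokenize(text, line)
    if not tokens:
        raise RuleSyntaxError("empty expression", line)
    return _Parser(tokens, line).parse()


def parse_rules(text: str) -> RuleSet:
    """Parse rule text (one ``target *= expression`` per line) into a RuleSet.

    Raises
    ------
    RuleSyntaxError
        On malformed lines, duplicate rules for one target, or node names
        using the reserved mediator prefix.
    """
    rules: dict[str, sympy.Basic] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "*=" in line:
            target, _, rhs = line.partition("*=")
        elif "=" in line:
            target, _, rhs = line.partition("=")
        else:
            raise RuleSyntaxError("missing '*=' or '='", lineno)
        target = target.strip()
        if not _IDENT_RE.fullmatch(target):
            raise RuleSyntaxError(f"bad target name {target!r}", lineno)
        if target in rules:
            raise RuleSyntaxError(f"duplicate rule for {target!r}", lineno)
        rules[target] = parse_expression(rhs, lineno)

    referenced = {s.name for e in rules.values() for s in e.free_symbols}
    for name in sorted(referenced | set(rules)):
        if name.startswith(MEDIATOR_PREFIX):
            raise RuleSyntaxError(
                f"node name {name!r} uses the reserved mediator prefix "
                f"{MEDIATOR_PREFIX!r}",
                1,
            )
    inputs = tuple(sorted(referenced - set(rules)))
    return RuleSet(rules=rules, inputs=inputs)


def parse_boolnet(text: str) -> RuleSet:
    """Read a BoolNet-style ``targets, factors`` table into a RuleSet.

    The first (header) line is ``targets, factors``; each following line is
    ``node, expression`` with ``&``, ``|``, ``!`` accepted as operators.
    """
    lines = [ln for ln in text.splitlines() if ln.split("#", 1)[0].strip()]
    if not lines:
        raise RuleSyntaxError("empty BoolNet table", 1)
    header = [c.strip().lower() for c in lines[0].split(",")]
    body = lines[1:] if header[:2] == ["targets", "factors"] else lines
    out = []
    for ln in body:
        target, _, rhs = ln.partition(",")
        rhs = rhs.replace("&", " and ").replace("|", " or ").replace("!", " not ")
        out.append(f"{target.strip()} *= {rhs}")
    return parse_rules("\n".join(out))


# ---------------------------------------------------------------------------
# evaluation / restriction


def _subs_map(assignment: Mapping[str, int | bool]) -> dict:
    return {
        Symbol(k): (sympy.true if v else sympy.false) for k, v in assignment.items()
    }


def evaluate(expr: sympy.Basic, assignment: Mapping[str, int | bool]) -> int:
    """Evaluate ``expr`` under a complete assignment; returns 0 or 1."""
    missing = {s.name for s in expr.free_symbols} - set(assignment)
    if missing:
        raise KeyError(f"missing assignment for {sorted(missing)}")
    result = expr.xreplace(_subs_map(assignment))
    if isinstance(result, BooleanTrue):
        return 1
    if isinstance(result, BooleanFalse):
        return 0
    # And/Or over constants auto-evaluate; anything left is a logic error.
    raise AssertionError(f"incomplete evaluation: {result}")


def restrict(expr: sympy.Basic, partial: Mapping[str, int | bool]) -> sympy.Basic:
    """Substitute a partial assignment and propagate 0/1 absorption.

    The result is a constant exactly when the partial assignment forces the
    expression's value.
    """
    reduced = expr.xreplace(_subs_map(partial))
    if reduced in (sympy.true, sympy.false) or not reduced.free_symbols:
        return reduced
    # xreplace + auto-evaluation handles absorption; tautologies that survive
    # substitution (e.g. A | ~A) are resolved only by prime_forms, which is
    # deliberate: restrict is pure constant propagation.
    return reduced


def format_expression(expr: sympy.Basic) -> str:
    """Render a sympy boolean expression in the rule grammar."""
    if expr is sympy.true:
        return "1"
    if expr is sympy.false:
        return "0"
    if isinstance(expr, Symbol):
        return expr.name
    if isinstance(expr, Not):
        return f"not {_format_sub(expr.args[0])}"
    if isinstance(expr, And):
        return " and ".join(_format_sub(a) for a in expr.args)
    if isinstance(expr, Or):
        return " or ".join(_format_sub(a) for a in expr.args)
    raise TypeError(f"cannot format {expr!r}")


def _format_sub(expr: sympy.Basic) -> str:
    if isinstance(expr, (And, Or)):
        return f"({format_expression(expr)})"
    return format_expression(expr)


# ---------------------------------------------------------------------------
# truth vectors and prime forms


def truth_vector(expr: sympy.Basic, support: Iterable[str]) -> np.ndarray:
    """Boolean vector of ``expr`` over all assignments of ``support``.

    Assignment ``i`` sets ``support[j]`` to bit ``j`` of ``i`` (LSB first).
    """
    names = list(support)
    n = len(names)
    idx = np.arange(1 << n, dtype=np.int64)
    cols = {name: ((idx >> j) & 1).astype(bool) for j, name in enumerate(names)}

    def rec(e: sympy.Basic) -> np.ndarray:
        if e is sympy.true:
            return np.ones(1 << n, dtype=bool)
        if e is sympy.false:
            return np.zeros(1 << n, dtype=bool)
        if isinstance(e, Symbol):
            return cols[e.name]
        if isinstance(e, Not):
            return ~rec(e.args[0])
        if isinstance(e, And):
            out = np.ones(1 << n, dtype=bool)
            for a in e.args:
                out &= rec(a)
            return out
        if isinstance(e, Or):
            out = np.zeros(1 << n, dtype=bool)
            for a in e.args:
                out |= rec(a)
            return out
        raise TypeError(f"unsupported operator in {e!r}")

    return rec(expr)


def expressions_equivalent(a: sympy.Basic, b: sympy.Basic) -> bool:
    """Exhaustive equivalence check over the union support."""
    support = sorted({s.name for s in a.free_symbols} | {s.name for s in b.free_symbols})
    return bool(np.array_equal(truth_vector(a, support), truth_vector(b, support)))


def _quine_mccluskey(minterms: np.ndarray, n: int) -> set[tuple[int, int]]:
    """All prime implicants of the function with the given minterms.

    Implicants are ``(value, mask)`` pairs over ``n`` variables: ``mask`` bits
    are the cared-for positions, ``value`` their required values.
    """
    if minterms.size == 0:
        return set()
    full_mask = (1 << n) - 1
    current: set[tuple[int, int]] = {(int(m), full_mask) for m in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        by_mask: dict[int, set[int]] = {}
        for val, mask in current:
            by_mask.setdefault(mask, set()).add(val)
        for mask, vals in by_mask.items():
            for val in vals:
                for j in range(n):
                    bit = 1 << j
                    if not (mask & bit):
                        continue
                    if (val ^ bit) in vals:
                        merged.add((val & ~bit, mask & ~bit))
                        used.add((val, mask))
                        used.add((val ^ bit, mask))
        primes |= current - used
        current = merged
    return primes


def _implicant_to_clause(
    val: int, mask: int, names: list[str]
) -> frozenset[tuple[str, bool]]:
    return frozenset(
        (names[j], bool((val >> j) & 1)) for j in range(len(names)) if (mask >> j) & 1
    )


def prime_forms(
    expr: sympy.Basic, literal_budget: int = 16
) -> tuple[ImplicantForm, ImplicantForm]:
    """Blake canonical forms: (all prime implicants as DNF, all prime
    implicates as CNF).

    Both forms are logically equivalent to ``expr``.  Prime implicates are
    obtained as complemented prime implicants of the negation.

    Raises
    ------
    ValueError
        If the support exceeds ``literal_budget`` variables.
    """
    names = sorted(s.name for s in expr.free_symbols)
    n = len(names)
    if n > literal_budget:
        raise ValueError(
            f"rule support of {n} literals exceeds the budget of {literal_budget}"
        )
    tv = truth_vector(expr, names)
    minterms = np.nonzero(tv)[0]
    maxterms = np.nonzero(~tv)[0]

    dnf_clauses = frozenset(
        _implicant_to_clause(v, m, names) for v, m in _quine_mccluskey(minterms, n)
    )
    # prime implicates of f = negated prime implicants of ~f
    cnf_clauses = frozenset(
        frozenset((name, not pos) for name, pos in _implicant_to_clause(v, m, names))
        for v, m in _quine_mccluskey(maxterms, n)
    )
    if minterms.size == tv.size:  # tautology
        dnf_clauses = frozenset([frozenset()])
        cnf_clauses = frozenset()
    elif minterms.size == 0:  # contradiction
        dnf_clauses = frozenset()
        cnf_clauses = frozenset([frozenset()])
    return (
        ImplicantForm(clauses=dnf_clauses, polarity="DNF"),
        ImplicantForm(clauses=cnf_clauses, polarity="CNF"),
    )
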