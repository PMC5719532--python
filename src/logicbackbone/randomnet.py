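"""Random Boolean network (RBN) ensemble: uniform over networks with a given
node and edge count, with uniformly random truth tables.

The edge budget is allocated to nodes as in-degrees by a multinomial draw
capped at n-1 regulators per node (overflow redistributed), each node's
regulators are a uniform distinct sample of the *other* nodes (no
self-loops), and each regulated node receives a uniformly random truth
table over its regulators, conditioned on every regulator being essential
(flipping it changes the function for some context).  Without that
conditioning a drawn "edge" may not be an edge at all — half of all
1-regulator tables ignore their regulator — and the network would not
actually have the requested edge count.  Everything is driven by one seed,
so the same spec reproduces the identical rule set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sympy import And, Not, Or, Symbol
import sympy

from .rules import RuleSet

__all__ = ["RBNSpec", "generate_rbn"]


@dataclass(frozen=True)
class RBNSpec:
    """Ensemble parameters: ``edges`` wins over ``k_in`` when both are given;
    with only ``k_in`` the budget is ``round(n * k_in)``."""

    n: int
    edges: int | None = None
    k_in: float | None = None
    seed: int = 0

    def edge_budget(self) -> int:
        if self.edges is not None:
            return self.edges
        if self.k_in is not None:
            return int(round(self.n * self.k_in))
        raise ValueError("RBNSpec needs either edges or k_in")


def _node_name(i: int, n: int) -> str:
    width = len(str(n))
    return f"n{i + 1:0{width}d}"


def generate_rbn(spec: RBNSpec) -> RuleSet:
    """Draw one RBN.  Raises ValueError on an infeasible edge count."""
    if spec.n < 1:
        raise ValueError("need at least one node")
    m = spec.edge_budget()
    if m < 0 or m > spec.n * (spec.n - 1):
        raise ValueError(f"{m} edges infeasible for {spec.n} nodes")

    rng = np.random.default_rng(spec.seed)
    names = [_node_name(i, spec.n) for i in range(spec.n)]
    cap = spec.n - 1

    degrees = rng.multinomial(m, np.full(spec.n, 1.0 / spec.n))
    while (degrees > cap).any():  # redistribute overflow above the n-1 cap
        excess = int((degrees - np.minimum(degrees, cap)).sum())
        degrees = np.minimum(degrees, cap)
        room = np.nonzero(degrees < cap)[0]
        extra = rng.multinomial(excess, np.full(len(room), 1.0 / len(room)))
        degrees[room] += extra

    rules: dict[str, sympy.Basic] = {}
    for i, name in enumerate(names):
        k = int(degrees[i])
        if k == 0:
            continue  # unregulated node: an input
        others = [j for j in range(spec.n) if j != i]
        regs = sorted(rng.choice(others, size=k, replace=False).tolist())
        table = rng.integers(0, 2, size=1 << k)
        while not _all_regulators_essential(table, k):
            table = rng.integers(0, 2, size=1 << k)
        rules[name] = _table_to_expression([names[j] for j in regs], table)
    inputs = tuple(n for n in names if n not in rules)
    return RuleSet(rules=rules, inputs=inputs)


def _all_regulators_essential(table: np.ndarray, k: int) -> bool:
    """True iff flipping each regulator changes the function somewhere."""
    rows = np.arange(1 << k)
    return all((table != table[rows ^ (1 << j)]).any() for j in range(k))


def _table_to_expression(regs: list[str], table: np.ndarray) -> sympy.Basic:
    """Minterm DNF of a truth table (row r assigns bit j of r to regs[j])."""
    terms = []
    for r in np.nonzero(table)[0]:
        lits = [
            Symbol(reg) if (int(r) >> j) & 1 else Not(Symbol(reg))
            for j, reg in enumerate(regs)
        ]
        terms.append(And(*lits))
    return Or(*terms)
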