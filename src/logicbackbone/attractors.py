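"""Exhaustive attractor enumeration for small Boolean networks.

The state space is enumerated explicitly (guarded: at most 20 free nodes
synchronously, 15 under general-asynchronous update), with rules compiled to
truth tables and all per-node successor maps computed as numpy vectors.

* synchronous: attractors are the cycles of the deterministic successor map;
* general asynchronous: attractors are the terminal strongly connected
  components of the state transition graph in which each transition updates
  one node (SCCs via :func:`scipy.sparse.csgraph.connected_components`).

Clamped nodes keep a constant rule; input nodes (no rule) hold their state,
so every input configuration contributes its own slice of attractors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .rules import RuleSet, truth_vector

__all__ = ["CompiledNetwork", "compile_network", "enumerate_attractors", "Attractor"]

_SYNC_GUARD = 20
_ASYNC_GUARD = 15


@dataclass(frozen=True)
class Attractor:
    """One attractor: a tuple of complete states (dicts node -> 0/1).

    A single-state attractor is a fixed point; otherwise the states form a
    synchronous cycle or a terminal SCC (complex attractor).
    """

    states: tuple[dict[str, int], ...]

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def fixed_nodes(self) -> dict[str, int]:
        """Nodes holding the same value in every state of the attractor."""
        first = self.states[0]
        return {
            n: v
            for n, v in first.items()
            if all(s[n] == v for s in self.states[1:])
        }


@dataclass
class CompiledNetwork:
    """Bit-level form of a clamped rule set: node order and per-node next-value
    vectors over all 2**n states (state i has node j at bit j of i)."""

    nodes: list[str]
    next_values: np.ndarray  # shape (n, 2**n), dtype bool

    def state_dict(self, code: int) -> dict[str, int]:
        return {n: (code >> j) & 1 for j, n in enumerate(self.nodes)}


def compile_network(rules: RuleSet, clamp: Mapping[str, int] | None = None
                    ) -> CompiledNetwork:
    clamp = dict(clamp or {})
    nodes = list(rules.nodes)
    n = len(nodes)
    pos = {name: j for j, name in enumerate(nodes)}
    size = 1 << n
    idx = np.arange(size, dtype=np.int64)
    nxt = np.zeros((n, size), dtype=bool)
    for name, j in pos.items():
        if name in clamp:
            nxt[j, :] = bool(clamp[name])
        elif name not in rules.rules:  # input: holds its state
            nxt[j] = ((idx >> j) & 1).astype(bool)
        else:
            expr = rules.rules[name]
            support = sorted(s.name for s in expr.free_symbols)
            tv = truth_vector(expr, support)
            key = np.zeros(size, dtype=np.int64)
            for k, reg in enumerate(support):
                key |= ((idx >> pos[reg]) & 1) << k
            nxt[j] = tv[key]
    return CompiledNetwork(nodes=nodes, next_values=nxt)


def _synchronous_attractor_states(net: CompiledNetwork) -> np.ndarray:
    n = len(net.nodes)
    succ = np.zeros(1 << n, dtype=np.int64)
    for j in range(n):
        succ |= net.next_values[j].astype(np.int64) << j
    # pointer-doubling: succ^(2**n) maps every state onto its cycle
    reach = succ
    for _ in range(n):
        reach = reach[reach]
    return np.unique(reach)


def _async_terminal_components(net: CompiledNetwork) -> list[np.ndarray]:
    n = len(net.nodes)
    size = 1 << n
    idx = np.arange(size, dtype=np.int64)
    rows, cols = [], []
    for j in range(n):
        target = (idx & ~(1 << j)) | (net.next_values[j].astype(np.int64) << j)
        moved = target != idx
        rows.append(idx[moved])
        cols.append(target[moved])
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    adj = sp.coo_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                        shape=(size, size))
    ncomp, labels = connected_components(adj, directed=True, connection="strong")
    # terminal components: no edge leaves the component
    leaving = labels[rows] != labels[cols]
    has_exit = np.zeros(ncomp, dtype=bool)
    has_exit[labels[rows[leaving]]] = True
    terminal = np.nonzero(~has_exit)[0]
    return [np.nonzero(labels == c)[0] for c in terminal]


def enumerate_attractors(
    rules: RuleSet,
    clamp: Mapping[str, int] | None = None,
    scheme: str = "general_asynchronous",
) -> list[Attractor]:
    """All attractors of the (optionally clamped) network.

    Raises
    ------
    ValueError
        On an unknown scheme or when the free-node count exceeds the size
        guard (20 synchronous / 15 asynchronous).
    """
    if scheme not in ("synchronous", "general_asynchronous"):
        raise ValueError(f"unknown update scheme {scheme!r}")
    clamp = dict(clamp or {})
    free = len(set(rules.nodes) - set(clamp))
    guard = _SYNC_GUARD if scheme == "synchronous" else _ASYNC_GUARD
    if free > guard:
        raise ValueError(f"{free} free nodes exceed the {scheme} guard of {guard}")

    net = compile_network(rules, clamp)
    if scheme == "synchronous":
        states = _synchronous_attractor_states(net)
        # group cycle states into their cycles
        succ = np.zeros(1 << len(net.nodes), dtype=np.int64)
        for j in range(len(net.nodes)):
            succ |= net.next_values[j].astype(np.int64) << j
        seen: set[int] = set()
        attractors = []
        for s in states.tolist():
            if s in seen:
                continue
            cycle = [s]
            seen.add(s)
            cur = int(succ[s])
            while cur != s:
                cycle.append(cur)
                seen.add(cur)
                cur = int(succ[cur])
            attractors.append(Attractor(tuple(net.state_dict(c) for c in cycle)))
        return attractors

    comps = _async_terminal_components(net)
    return [
        Attractor(tuple(net.state_dict(int(c)) for c in comp.tolist()))
        for comp in comps
    ]
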