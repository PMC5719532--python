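"""Built-in example networks used throughout the documentation and tests.

Each fixture is a small rule set whose causal-graph rendering exercises a
specific feature of the framework: the six edge types, mediator
construction, path chaining, subgraph closure, cycle/subgraph intersection,
and a sufficient cyclic subgraph (stable motif).

Where a fixture is defined by its drawn edge types rather than by printed
rules, the rules introduce phantom extra regulators (inputs named
``x<Node>``) exactly where an edge's stated logic is weaker than what a lone
regulator would impose — a node with a single regulator always carries a
sufficient&necessary edge, so e.g. a plain *sufficient* edge into a node
requires a second, unconstrained regulator.  ``example_a`` and
``example_intersect`` are transcriptions constrained by their source
drawings; the phantom regulators are part of the transcription.
"""

from __future__ import annotations

from .graph import CausalGraph, build_causal_graph
from .rules import RuleSet, parse_rules

__all__ = ["fixture", "fixture_names", "fixture_text"]


_FIXTURES: dict[str, str] = {
    # single-edge networks: the six causal edge types
    "edge_necessary": "B *= A and x\n",
    "edge_sufficient": "B *= A or x\n",
    "edge_necessary_inhibitory": "B *= (not A) or x\n",
    "edge_sufficient_inhibitory": "B *= (not A) and x\n",
    "edge_sufficient_necessary": "B *= A\n",
    "edge_sufficient_necessary_inhibitory": "B *= not A\n",
    # four real nodes, one mediator; B is the signal, D the output
    "mediator_demo": (
        "A *= B or (not C)\n"
        "C *= B\n"
        "D *= A or (B and C)\n"
    ),
    # linear chain exercising every pure edge type:
    # A->B suff, B->C suff, C-|D suff-inh, D->E necc, E->F necc, F-|G necc-inh
    "chain_demo": (
        "B *= A or xB\n"
        "C *= B or xC\n"
        "D *= (not C) and xD\n"
        "E *= D and xE\n"
        "F *= E and xF\n"
        "G *= (not F) or xG\n"
    ),
    # sufficient and necessary subgraphs: J necessary for F through its
    # sufficient regulators; A sufficient for D through the necessary
    # regulators C, F, G; A sufficient for K through E and NOT L
    "example_a": (
        "A *= J and xA\n"
        "I *= J and xI\n"
        "H *= A\n"
        "F *= I or A or H\n"
        "B *= A or xB\n"
        "G *= B or xG\n"
        "C *= H or xC\n"
        "D *= C and F and G\n"
        "E *= D or xE\n"
        "N *= A or xN\n"
        "M *= N or xM\n"
        "L *= (not M) and xL\n"
        "K *= E and (not L)\n"
    ),
    # a necessary cycle C->D->E->C intersecting the sufficient path ABCDFG
    # (the shared edge C->D follows the sufficient-inhibitory section ABC)
    "example_intersect": (
        "B *= A or xB\n"
        "C *= (not B) and E\n"
        "D *= C and xD\n"
        "E *= D and xE\n"
        "F *= (not D) or xF\n"
        "G *= F or xG\n"
    ),
    # nine-node network with a sufficient cyclic subgraph at A (a stable
    # motif): stabilized states A,B,C,D,E,I ON and F,G,H OFF
    "motif_demo": (
        "B *= A or xB\n"
        "C *= B or xC\n"
        "D *= A or xD\n"
        "E *= C and D\n"
        "G *= not D\n"
        "F *= G or (not E)\n"
        "H *= F and xH\n"
        "I *= (not H) or xI\n"
        "A *= E and I\n"
    ),
    # a minimal signal -> motif -> output cascade for the backbone
    "demo_backbone": (
        "A *= S or B\n"
        "B *= A\n"
        "O *= B\n"
    ),
}

def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture_text(name: str) -> str:
    """Rule text of a named example network."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}") from None


def fixture(name: str) -> tuple[RuleSet, CausalGraph]:
    """Return (rules, causal graph) for a named example network."""
    rules = parse_rules(fixture_text(name))
    return rules, build_causal_graph(rules)
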