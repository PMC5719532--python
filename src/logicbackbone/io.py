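"""Serialization: GraphML, DOT, SIF and JSON views of causal graphs.

The edge-type vocabulary in every format is the six lowercase strings
``sufficient``, ``necessary``, ``sufficient_necessary``,
``sufficient_inhibitory``, ``necessary_inhibitory``,
``sufficient_necessary_inhibitory`` (edge attribute ``edge_logic``).  DOT
output follows the red/blue/black color convention (sufficient red,
necessary blue, sufficient&necessary black) with tee arrowheads on
inhibitory edges.  GraphML round-trips through networkx; DOT and SIF are
write-only text renderings.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .chaining import EdgeType
from .graph import CausalGraph, Gate

__all__ = [
    "write_graphml",
    "read_graphml",
    "write_dot",
    "write_sif",
    "graph_to_json_dict",
]

_DOT_COLOR = {
    EdgeType.SUFF: "red",
    EdgeType.SUFF_INH: "red",
    EdgeType.NECC: "blue",
    EdgeType.NECC_INH: "blue",
    EdgeType.SUFF_NECC: "black",
    EdgeType.SUFF_NECC_INH: "black",
}

_BY_VALUE = {t.value: t for t in EdgeType}


def _export_graph(graph: CausalGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in graph.nodes:
        g.add_node(n, kind=graph.kind(n), gate=graph.gate(n).value,
                   value=-1 if graph.constant_value(n) is None
                   else int(graph.constant_value(n)))
    for u, v, t in graph.edges():
        g.add_edge(u, v, edge_logic=t.value)
    return g


def write_graphml(graph: CausalGraph, path: str | Path) -> None:
    nx.write_graphml(_export_graph(graph), str(path))


def read_graphml(path: str | Path) -> CausalGraph:
    raw = nx.read_graphml(str(path))
    cg = CausalGraph()
    for n, d in raw.nodes(data=True):
        value = d.get("value", -1)
        cg.add_node(
            str(n),
            kind=d.get("kind", "real"),
            gate=Gate(d.get("gate", "input")),
            value=None if value in (-1, "-1", None) else int(value),
        )
    for u, v, d in raw.edges(data=True):
        cg.add_edge(str(u), str(v), _BY_VALUE[d["edge_logic"]])
    return cg


def write_dot(graph: CausalGraph, path: str | Path) -> None:
    lines = ["digraph causal_logic {"]
    for n in graph.nodes:
        shape = "ellipse" if graph.kind(n) == "real" else "box"
        extra = ', style="filled", fillcolor="lightblue"' \
            if graph.kind(n) == "mediator" else ""
        lines.append(f'  "{n}" [shape={shape}{extra}];')
    for u, v, t in graph.edges():
        head = "tee" if t.inhibitory else "normal"
        lines.append(
            f'  "{u}" -> "{v}" [color={_DOT_COLOR[t]}, arrowhead={head}, '
            f'edge_logic="{t.value}"];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_sif(graph: CausalGraph, path: str | Path) -> None:
    lines = [f"{u}\t{t.value}\t{v}" for u, v, t in graph.edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def graph_to_json_dict(graph: CausalGraph) -> dict:
    return {
        "nodes": [
            {
                "name": n,
                "kind": graph.kind(n),
                "gate": graph.gate(n).value,
                **(
                    {"value": graph.constant_value(n)}
                    if graph.gate(n) is Gate.CONSTANT else {}
                ),
            }
            for n in graph.nodes
        ],
        "edges": [
            {"source": u, "target": v, "edge_logic": t.value}
            for u, v, t in graph.edges()
        ],
    }


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
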