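"""Summary-network extraction: typed directed graph plus a self-contained
interactive HTML rendering (no external assets)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .._errors import DataError
from .parsers import parse_edge_lines

#: crude node typing by name; pathway-ish names vs gene symbols
_PATHWAY_HINTS = ("pathway", "signaling", "signalling", "cascade", "cycle",
                  "response", "metabolism", "apoptosis")
_REGULATOR_RELATIONS = ("regulates", "activates", "represses", "inhibits",
                        "induces", "suppresses")


@dataclass
class NetworkGraph:
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return [
            (u, v, d.get("relation", "")) for u, v, d in self.graph.edges(data=True)
        ]

    def node_type(self, name: str) -> str:
        return self.graph.nodes[name].get("type", "gene/target")

    def validate(self) -> None:
        for u, v in self.graph.edges:
            if u == v:
                raise DataError(f"self-loop on {u}")


def graph_from_text(text: str) -> NetworkGraph:
    """Build a typed directed graph from ``source|relation|target`` lines."""
    edges = parse_edge_lines(text)
    g = nx.DiGraph()
    for src, rel, dst in edges:
        g.add_edge(src, dst, relation=rel)
    for node in g.nodes:
        g.nodes[node]["type"] = _classify(node, g)
    net = NetworkGraph(graph=g)
    net.validate()
    return net


def _classify(node: str, g: nx.DiGraph) -> str:
    low = node.lower()
    if any(h in low for h in _PATHWAY_HINTS):
        return "pathway"
    out_relations = [d.get("relation", "").lower()
                     for _, _, d in g.out_edges(node, data=True)]
    if any(r in _REGULATOR_RELATIONS for r in out_relations):
        return "regulator"
    return "gene/target"


_HTML_SHELL = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Summary network</title>
<style>
body {{ font-family: sans-serif; margin: 0; }}
svg {{ width: 100vw; height: 100vh; }}
.edge {{ stroke: #888; stroke-width: 1.5; marker-end: url(#arrow); }}
.edge-label {{ font-size: 10px; fill: #555; }}
.node circle {{ stroke: #333; stroke-width: 1; cursor: pointer; }}
.node text {{ font-size: 12px; }}
.pathway {{ fill: #9ecae1; }}
.regulator {{ fill: #fdae6b; }}
.gene {{ fill: #a1d99b; }}
</style>
</head>
<body>
<svg id="net" viewBox="0 0 900 700">
<defs>
<marker id="arrow" viewBox="0 0 10 10" refX="22" refY="5"
        markerWidth="6" markerHeight="6" orient="auto-start-reverse">
<path d="M 0 0 L 10 5 L 0 10 z" fill="#888"/>
</marker>
</defs>
</svg>
<script>
const data = {data_json};
const svg = document.getElementById("net");
const ns = "http://www.w3.org/2000/svg";
const cx = 450, cy = 350, r = 280;
const pos = {{}};
data.nodes.forEach((n, i) => {{
  const a = 2 * Math.PI * i / data.nodes.length;
  pos[n.id] = [cx + r * Math.cos(a), cy + r * Math.sin(a)];
}});
data.edges.forEach(e => {{
  const [x1, y1] = pos[e.source], [x2, y2] = pos[e.target];
  const line = document.createElementNS(ns, "line");
  line.setAttribute("class", "edge");
  line.setAttribute("x1", x1); line.setAttribute("y1", y1);
  line.setAttribute("x2", x2); line.setAttribute("y2", y2);
  const title = document.createElementNS(ns, "title");
  title.textContent = e.source + " " + e.relation + " " + e.target;
  line.appendChild(title);
  svg.appendChild(line);
  const label = document.createElementNS(ns, "text");
  label.setAttribute("class", "edge-label");
  label.setAttribute("x", (x1 + x2) / 2);
  label.setAttribute("y", (y1 + y2) / 2 - 4);
  label.textContent = e.relation;
  svg.appendChild(label);
}});
data.nodes.forEach(n => {{
  const [x, y] = pos[n.id];
  const g = document.createElementNS(ns, "g");
  g.setAttribute("class", "node");
  const c = document.createElementNS(ns, "circle");
  c.setAttribute("cx", x); c.setAttribute("cy", y); c.setAttribute("r", 14);
  c.setAttribute("class",
    n.type === "pathway" ? "pathway" :
    n.type === "regulator" ? "regulator" : "gene");
  const title = document.createElementNS(ns, "title");
  title.textContent = n.id + " (" + n.type + ")";
  c.appendChild(title);
  g.appendChild(c);
  const t = document.createElementNS(ns, "text");
  t.setAttribute("x", x + 16); t.setAttribute("y", y + 4);
  t.textContent = n.id;
  g.appendChild(t);
  svg.appendChild(g);
}});
</script>
</body>
</html>
"""


def write_html(net: NetworkGraph, path: str | Path) -> Path:
    """Write a self-contained interactive HTML view of the network."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "nodes": [
            {"id": n, "type": net.node_type(n)} for n in sorted(net.nodes)
        ],
        "edges": [
            {"source": u, "target": v, "relation": rel}
            for u, v, rel in net.edges
        ],
    }
    path.write_text(
        _HTML_SHELL.format(data_json=json.dumps(data)), encoding="utf-8"
    )
    return path
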