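"""Serialize pathway graphs to standard formats and render SVG diagrams.

Supported targets: GraphML (typed attribute keys, positions as numeric
attributes), Cytoscape.js JSON (the ``elements`` dialect with per-element
``data`` and ``position``), SIF with a sidecar attribute table (SIF itself
is lossy by design), and static SVG that reproduces the drawn diagram —
boxes, round boxes, ellipses, colored polylines for global-map lines, and
labels, in KGML image coordinates (y grows downward, as in SVG).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
from lxml import etree

from .graph import GraphEdge, GraphNode, PathwayGraph
from .style import VisualStyle, apply_style, style_from_graph, style_to_json

__all__ = [
    "ExportBundle",
    "to_graphml",
    "from_graphml",
    "to_cyjs",
    "from_cyjs",
    "to_sif",
    "sif_attribute_table",
    "render_svg",
]

EXPORT_FORMATS = ("graphml", "cyjs", "sif", "svg")


@dataclass
class ExportBundle:
    graph_document: str
    style_document: str
    format_name: str


_NODE_ATTRS: list[tuple[str, str]] = [
    ("entry_id", "string"),
    ("names", "string"),
    ("entry_type", "string"),
    ("label", "string"),
    ("x", "double"),
    ("y", "double"),
    ("width", "double"),
    ("height", "double"),
    ("shape_type", "string"),
    ("fg_color", "string"),
    ("bg_color", "string"),
    ("reaction_names", "string"),
    ("is_ko_annotated", "boolean"),
]
_EDGE_ATTRS: list[tuple[str, str]] = [
    ("interaction", "string"),
    ("relation_type", "string"),
    ("subtype_names", "string"),
    ("via_compound_id", "string"),
    ("direction", "string"),
    ("fg_color", "string"),
    ("line_width", "double"),
    ("names", "string"),
]

_LIST_SEP = "|"


def _node_data(node: GraphNode) -> dict[str, str | float | bool]:
    return {
        "entry_id": "" if node.entry_id is None else str(node.entry_id),
        "names": _LIST_SEP.join(node.names),
        "entry_type": node.entry_type,
        "label": node.label,
        "x": node.x,
        "y": node.y,
        "width": node.width,
        "height": node.height,
        "shape_type": node.shape_type,
        "fg_color": node.fg_color,
        "bg_color": node.bg_color,
        "reaction_names": _LIST_SEP.join(node.reaction_names),
        "is_ko_annotated": node.is_ko_annotated,
    }


def _edge_data(edge: GraphEdge) -> dict[str, str | float]:
    return {
        "interaction": edge.interaction,
        "relation_type": edge.relation_type,
        "subtype_names": _LIST_SEP.join(edge.subtype_names),
        "via_compound_id": (
            "" if edge.via_compound_id is None else str(edge.via_compound_id)
        ),
        "direction": edge.direction,
        "fg_color": edge.fg_color,
        "line_width": edge.line_width,
        "names": _LIST_SEP.join(edge.names),
    }


def to_graphml(graph: PathwayGraph, style: VisualStyle | None = None) -> str:
    """GraphML text: every node/edge with typed data keys, declared once."""
    ns = "http://graphml.graphdrawing.org/xmlns"
    root = etree.Element("graphml", nsmap={None: ns})
    for i, (name, gtype) in enumerate(_NODE_ATTRS):
        key = etree.SubElement(root, f"{{{ns}}}key")
        key.set("id", f"n{i}")
        key.set("for", "node")
        key.set("attr.name", name)
        key.set("attr.type", gtype)
    for i, (name, gtype) in enumerate(_EDGE_ATTRS):
        key = etree.SubElement(root, f"{{{ns}}}key")
        key.set("id", f"e{i}")
        key.set("for", "edge")
        key.set("attr.name", name)
        key.set("attr.type", gtype)
    g = etree.SubElement(root, f"{{{ns}}}graph")
    g.set("id", graph.pathway_name or "pathway")
    g.set("edgedefault", "directed")
    node_key_ids = {name: f"n{i}" for i, (name, _) in enumerate(_NODE_ATTRS)}
    edge_key_ids = {name: f"e{i}" for i, (name, _) in enumerate(_EDGE_ATTRS)}
    for node in graph.nodes:
        n = etree.SubElement(g, f"{{{ns}}}node")
        n.set("id", node.node_key)
        for name, value in _node_data(node).items():
            d = etree.SubElement(n, f"{{{ns}}}data")
            d.set("key", node_key_ids[name])
            d.text = str(value).lower() if isinstance(value, bool) else str(value)
    for edge in graph.edges:
        e = etree.SubElement(g, f"{{{ns}}}edge")
        e.set("source", edge.source_key)
        e.set("target", edge.target_key)
        for name, value in _edge_data(edge).items():
            d = etree.SubElement(e, f"{{{ns}}}data")
            d.set("key", edge_key_ids[name])
            d.text = str(value)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def from_graphml(document: str) -> PathwayGraph:
    """Rebuild a PathwayGraph from exported GraphML (via networkx)."""
    g = nx.parse_graphml(document)
    graph = PathwayGraph(pathway_name=g.graph.get("id", ""), title="", org="")
    # networkx stores the graph id under .name
    graph.pathway_name = g.name or ""
    for key, data in g.nodes(data=True):
        graph.nodes.append(GraphNode(
            node_key=key,
            entry_id=int(data["entry_id"]) if data.get("entry_id") else None,
            names=data["names"].split(_LIST_SEP) if data.get("names") else [],
            entry_type=data.get("entry_type", ""),
            label=data.get("label", ""),
            x=float(data["x"]),
            y=float(data["y"]),
            width=float(data["width"]),
            height=float(data["height"]),
            shape_type=data.get("shape_type", ""),
            fg_color=data.get("fg_color", ""),
            bg_color=data.get("bg_color", ""),
            reaction_names=(
                data["reaction_names"].split(_LIST_SEP)
                if data.get("reaction_names") else []
            ),
            is_ko_annotated=bool(data.get("is_ko_annotated", False)),
        ))
    for src, tgt, data in g.edges(data=True):
        graph.edges.append(GraphEdge(
            source_key=src,
            target_key=tgt,
            interaction=data.get("interaction", ""),
            relation_type=data.get("relation_type", ""),
            subtype_names=(
                data["subtype_names"].split(_LIST_SEP)
                if data.get("subtype_names") else []
            ),
            via_compound_id=(
                int(data["via_compound_id"])
                if data.get("via_compound_id") else None
            ),
            direction=data.get("direction", "directed"),
            fg_color=data.get("fg_color", ""),
            line_width=float(data.get("line_width", 1.0)),
            names=data["names"].split(_LIST_SEP) if data.get("names") else [],
        ))
    return graph


def to_cyjs(graph: PathwayGraph, style: VisualStyle | None = None) -> str:
    """Cytoscape.js JSON: elements with data and position per node.

    When a style is given, the resolved visual properties are embedded per
    element so a web viewer reproduces the diagram without extra styling.
    """
    resolved = None
    if style is not None:
        resolved = apply_style(graph, style)
    nodes = []
    for node in graph.nodes:
        data: dict = {"id": node.node_key}
        data.update(_node_data(node))
        element = {
            "data": data,
            "position": {"x": node.x, "y": node.y},
        }
        if resolved is not None:
            visuals = resolved.loc[node.node_key].drop(
                ["element", "x", "y"]
            ).to_dict()
            element["data"]["visual"] = visuals
        nodes.append(element)
    edges = []
    for i, edge in enumerate(graph.edges):
        data = {
            "id": f"edge{i}",
            "source": edge.source_key,
            "target": edge.target_key,
        }
        data.update(_edge_data(edge))
        edges.append({"data": data})
    doc = {
        "format_version": "1.0",
        "data": {
            "name": graph.pathway_name,
            "title": graph.title,
            "org": graph.org,
        },
        "elements": {"nodes": nodes, "edges": edges},
    }
    return json.dumps(doc, indent=1)


def from_cyjs(document: str) -> PathwayGraph:
    """Rebuild a PathwayGraph from Cytoscape.js JSON."""
    doc = json.loads(document)
    meta = doc.get("data", {})
    graph = PathwayGraph(
        pathway_name=meta.get("name", ""),
        title=meta.get("title", ""),
        org=meta.get("org", ""),
    )
    for element in doc["elements"]["nodes"]:
        data = element["data"]
        pos = element["position"]
        graph.nodes.append(GraphNode(
            node_key=data["id"],
            entry_id=int(data["entry_id"]) if data.get("entry_id") else None,
            names=data["names"].split(_LIST_SEP) if data.get("names") else [],
            entry_type=data.get("entry_type", ""),
            label=data.get("label", ""),
            x=float(pos["x"]),
            y=float(pos["y"]),
            width=float(data["width"]),
            height=float(data["height"]),
            shape_type=data.get("shape_type", ""),
            fg_color=data.get("fg_color", ""),
            bg_color=data.get("bg_color", ""),
            reaction_names=(
                data["reaction_names"].split(_LIST_SEP)
                if data.get("reaction_names") else []
            ),
            is_ko_annotated=bool(data.get("is_ko_annotated", False)),
        ))
    for element in doc["elements"]["edges"]:
        data = element["data"]
        graph.edges.append(GraphEdge(
            source_key=data["source"],
            target_key=data["target"],
            interaction=data.get("interaction", ""),
            relation_type=data.get("relation_type", ""),
            subtype_names=(
                data["subtype_names"].split(_LIST_SEP)
                if data.get("subtype_names") else []
            ),
            via_compound_id=(
                int(data["via_compound_id"])
                if data.get("via_compound_id") else None
            ),
            direction=data.get("direction", "directed"),
            fg_color=data.get("fg_color", ""),
            line_width=float(data.get("line_width", 1.0)),
            names=data["names"].split(_LIST_SEP) if data.get("names") else [],
        ))
    return graph


def _sif_name(node: GraphNode) -> str:
    return node.names[0] if node.names else node.node_key


def to_sif(graph: PathwayGraph) -> str:
    """Simple interaction format: one line per edge, isolated nodes bare.

    Node names are the first KEGG id; attributes go to the sidecar table
    from :func:`sif_attribute_table`.
    """
    by_key = {n.node_key: n for n in graph.nodes}
    lines = []
    touched: set[str] = set()
    for edge in graph.edges:
        src = _sif_name(by_key[edge.source_key])
        tgt = _sif_name(by_key[edge.target_key])
        lines.append(f"{src}\t{edge.interaction}\t{tgt}")
        touched.update((edge.source_key, edge.target_key))
    for node in graph.nodes:
        if node.node_key not in touched:
            lines.append(_sif_name(node))
    return "\n".join(lines) + "\n"


def sif_attribute_table(graph: PathwayGraph) -> str:
    """TSV of node attributes keyed by the SIF node name."""
    header = ["name", "node_key"] + [a for a, _ in _NODE_ATTRS]
    rows = ["\t".join(header)]
    for node in graph.nodes:
        data = _node_data(node)
        rows.append("\t".join(
            [_sif_name(node), node.node_key]
            + [str(data[a]) for a, _ in _NODE_ATTRS]
        ))
    return "\n".join(rows) + "\n"


SVG_MARGIN = 20.0
ROUND_RADIUS = 6.0


def render_svg(graph: PathwayGraph, style: VisualStyle | None = None) -> str:
    """Static SVG reproducing the diagram layout.

    One shape per non-anchor node at its KGML center coordinates with the
    resolved fill and border, one polyline per line-entry anchor chain in
    the line's color, one text element per nonempty label.  Anchors draw no
    shape.  The KGML image convention (y down) matches SVG, so no axis flip.
    """
    if style is None:
        style = style_from_graph(graph)
    resolved = apply_style(graph, style)

    xs, ys = [], []
    for node in graph.nodes:
        xs += [node.x - node.width / 2, node.x + node.width / 2]
        ys += [node.y - node.height / 2, node.y + node.height / 2]
    x0 = min(xs) - SVG_MARGIN
    y0 = min(ys) - SVG_MARGIN
    x1 = max(xs) + SVG_MARGIN
    y1 = max(ys) + SVG_MARGIN

    ns = "http://www.w3.org/2000/svg"
    root = etree.Element("svg", nsmap={None: ns})
    root.set("version", "1.1")
    root.set("viewBox", f"{x0:g} {y0:g} {x1 - x0:g} {y1 - y0:g}")
    root.set("width", f"{x1 - x0:g}")
    root.set("height", f"{y1 - y0:g}")

    # polylines first (under the boxes), one per line entry's anchor chain
    chains: dict[int, list[GraphNode]] = {}
    for node in graph.nodes:
        if node.entry_type == "anchor":
            chains.setdefault(node.entry_id, []).append(node)
    for entry_id, anchors in sorted(chains.items()):
        pl = etree.SubElement(root, f"{{{ns}}}polyline")
        pl.set("points", " ".join(f"{a.x:g},{a.y:g}" for a in anchors))
        pl.set("fill", "none")
        pl.set("stroke", anchors[0].fg_color)
        pl.set("stroke-width", "2")

    for node in graph.nodes:
        if node.entry_type == "anchor":
            continue
        visual = resolved.loc[node.node_key]
        shape = visual["shape"]
        if shape == "ellipse":
            el = etree.SubElement(root, f"{{{ns}}}ellipse")
            el.set("cx", f"{node.x:g}")
            el.set("cy", f"{node.y:g}")
            el.set("rx", f"{node.width / 2:g}")
            el.set("ry", f"{node.height / 2:g}")
        else:
            el = etree.SubElement(root, f"{{{ns}}}rect")
            el.set("x", f"{node.x - node.width / 2:g}")
            el.set("y", f"{node.y - node.height / 2:g}")
            el.set("width", f"{node.width:g}")
            el.set("height", f"{node.height:g}")
            if shape == "round-rectangle":
                el.set("rx", f"{ROUND_RADIUS:g}")
                el.set("ry", f"{ROUND_RADIUS:g}")
        el.set("fill", str(visual["fill"]))
        el.set("stroke", str(visual["border_color"]))
        el.set("stroke-width", f"{float(visual['border_width']):g}")
        if node.label:
            txt = etree.SubElement(root, f"{{{ns}}}text")
            txt.set("x", f"{node.x:g}")
            txt.set("y", f"{node.y:g}")
            txt.set("text-anchor", "middle")
            txt.set("dominant-baseline", "central")
            txt.set("font-size", f"{float(visual['font_size']):g}")
            txt.set("fill", str(visual["label_color"]))
            txt.text = node.label
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def export(
    graph: PathwayGraph,
    style: VisualStyle | None = None,
    format_name: str = "graphml",
) -> ExportBundle:
    """Dispatch to one of the supported formats."""
    if format_name not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {format_name!r}")
    if style is None:
        style = style_from_graph(graph)
    if format_name == "graphml":
        doc = to_graphml(graph, style)
    elif format_name == "cyjs":
        doc = to_cyjs(graph, style)
    elif format_name == "sif":
        doc = to_sif(graph)
    else:
        doc = render_svg(graph, style)
    return ExportBundle(
        graph_document=doc,
        style_document=style_to_json(style),
        format_name=format_name,
    )
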