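"""Visual styles: defaults plus attribute-to-visual mapping functions.

Instead of stamping colors and shapes directly onto the graph, the drawn
appearance is expressed as a *style*: a set of default visual properties
and a list of mapping functions from data attributes to visual properties
(passthrough, discrete table, or continuous interpolation).  The same
machinery that reproduces the original hand-drawn diagram then also drives
omics overlays, by swapping in different mappings.

Continuous color mappings interpolate linearly per 8-bit sRGB channel with
half-up rounding and clamp outside the anchor range, so a p-value past the
significance cutoff can never produce an out-of-gamut color.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any

import pandas as pd

from .kgml import HEX_COLOR_RE, parse_hex_color

if TYPE_CHECKING:  # pragma: no cover
    from .graph import PathwayGraph

__all__ = [
    "MappingFunction",
    "VisualStyle",
    "style_from_graph",
    "apply_style",
    "node_label",
    "style_to_json",
    "style_from_json",
    "interpolate_color",
]

DEFAULT_FONT_SIZE = 11  # px; KGML carries no font information

NODE_DEFAULTS: dict[str, Any] = {
    "fill": "#FFFFFF",
    "border_color": "#000000",
    "border_width": 1.0,
    "label": "",
    "label_color": "#000000",
    "font_size": DEFAULT_FONT_SIZE,
    "shape": "rectangle",
    "width": 46.0,
    "height": 17.0,
}
EDGE_DEFAULTS: dict[str, Any] = {
    "stroke": "#000000",
    "stroke_width": 1.0,
}

# KGML graphics shape -> renderer shape
SHAPE_TABLE = {
    "rectangle": "rectangle",
    "roundrectangle": "round-rectangle",
    "circle": "ellipse",
    "line": "polyline",
}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def interpolate_color(c1: str, c2: str, t: float) -> str:
    """Linear per-channel blend of two hex colors at fraction ``t``."""
    r1, g1, b1 = parse_hex_color(c1)
    r2, g2, b2 = parse_hex_color(c2)
    chans = (
        _round_half_up(a + (b - a) * t)
        for a, b in ((r1, r2), (g1, g2), (b1, b2))
    )
    return "#%02X%02X%02X" % tuple(min(255, max(0, c)) for c in chans)


def node_label(names_label: str) -> str:
    """Display label from a comma-separated graphics name list.

    The first comma token wins (KGML packs synonyms into one attribute);
    a trailing ellipsis from KEGG's truncated titles is stripped.
    """
    if not names_label:
        return ""
    first = names_label.split(",")[0].strip()
    while first.endswith("..."):
        first = first[:-3].rstrip()
    return first


@dataclass
class MappingFunction:
    """One attribute -> visual-property mapping.

    kind:
        ``passthrough`` copies the attribute value; ``discrete`` looks the
        value up in ``table``; ``continuous`` interpolates between
        ``anchors`` (ordered (attribute value, visual value) pairs),
        clamping outside the range.
    """

    attribute: str
    target: str
    kind: str = "passthrough"
    element: str = "node"
    table: dict[str, Any] = field(default_factory=dict)
    anchors: list[tuple[float, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("passthrough", "discrete", "continuous"):
            raise ValueError(f"unknown mapping kind {self.kind!r}")
        if self.kind == "continuous":
            values = [a for a, _ in self.anchors]
            if sorted(values) != values or len(set(values)) != len(values):
                raise ValueError(
                    "continuous anchors must be strictly increasing"
                )

    def resolve(self, value: Any) -> Any:
        if value is None:
            return None
        if self.kind == "passthrough":
            return value
        if self.kind == "discrete":
            return self.table.get(value)
        return self._continuous(float(value))

    def _continuous(self, x: float) -> Any:
        anchors = self.anchors
        if x <= anchors[0][0]:
            return anchors[0][1]
        if x >= anchors[-1][0]:
            return anchors[-1][1]
        for (x0, v0), (x1, v1) in zip(anchors, anchors[1:]):
            if x0 <= x <= x1:
                t = (x - x0) / (x1 - x0)
                if isinstance(v0, str) and HEX_COLOR_RE.match(v0):
                    return interpolate_color(v0, v1, t)
                return v0 + (v1 - v0) * t
        raise AssertionError("unreachable")  # pragma: no cover


@dataclass
class VisualStyle:
    style_name: str
    node_defaults: dict[str, Any] = field(default_factory=lambda: dict(NODE_DEFAULTS))
    edge_defaults: dict[str, Any] = field(default_factory=lambda: dict(EDGE_DEFAULTS))
    mappings: list[MappingFunction] = field(default_factory=list)

    def copy(self) -> "VisualStyle":
        return style_from_json(style_to_json(self))


def style_from_graph(graph: "PathwayGraph") -> VisualStyle:
    """Synthesize the diagram-faithful style for a pathway graph.

    Passthrough mappings bind each node's stored graphics directly to its
    rendered appearance (fill from the diagram background color, border and
    label color from the foreground color, size and shape from the drawn
    box) and segment edges take the drawn line color as stroke, so the
    resolved view reproduces the hand-drawn layout.
    """
    if not graph.nodes:
        raise ValueError("cannot style an empty graph")
    mappings = [
        MappingFunction("bg_color", "fill"),
        MappingFunction("fg_color", "border_color"),
        MappingFunction("fg_color", "label_color"),
        MappingFunction("label", "label"),
        MappingFunction("width", "width"),
        MappingFunction("height", "height"),
        MappingFunction(
            "shape_type", "shape", kind="discrete", table=dict(SHAPE_TABLE)
        ),
        MappingFunction("fg_color", "stroke", element="edge"),
        MappingFunction("line_width", "stroke_width", element="edge"),
    ]
    return VisualStyle(style_name=graph.pathway_name, mappings=mappings)


_KNOWN_ATTRS = object()


def _attr_value(element: Any, name: str) -> Any:
    if hasattr(element, name):
        value = getattr(element, name)
    else:
        attrs = getattr(element, "attrs", None)
        if attrs is None or name not in attrs:
            return _KNOWN_ATTRS
        value = attrs[name]
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def apply_style(graph: "PathwayGraph", style: VisualStyle) -> pd.DataFrame:
    """Resolve every visual property for every element.

    Returns a table with one row per node and per edge.  Resolution order
    per property: mapping result when the source attribute is present and
    non-missing, otherwise the style default — the fallback chain is total,
    so no cell is ever left unresolved.  Node positions pass through as
    ``x``/``y`` columns in KGML image coordinates.

    Raises ``KeyError`` when a mapping references an attribute that exists
    on no element of its kind.
    """
    node_maps = [m for m in style.mappings if m.element == "node"]
    edge_maps = [m for m in style.mappings if m.element == "edge"]

    for maps, elements, kind in (
        (node_maps, graph.nodes, "node"),
        (edge_maps, graph.edges, "edge"),
    ):
        for m in maps:
            if elements and all(
                _attr_value(e, m.attribute) is _KNOWN_ATTRS for e in elements
            ):
                raise KeyError(
                    f"mapping references unknown {kind} attribute "
                    f"{m.attribute!r}"
                )

    # Every row carries the union of node and edge properties so the table
    # is total (no missing cells); inapplicable properties hold defaults.
    node_base = {**style.edge_defaults, **style.node_defaults}
    edge_base = {**style.node_defaults, **style.edge_defaults}
    positions = {n.node_key: (n.x, n.y) for n in graph.nodes}

    rows = []
    for node in graph.nodes:
        row: dict[str, Any] = {"element": "node", "key": node.node_key}
        resolved = dict(node_base)
        for m in node_maps:
            value = _attr_value(node, m.attribute)
            if value is _KNOWN_ATTRS or value is None:
                continue
            out = m.resolve(value)
            if out is not None:
                resolved[m.target] = out
        row.update(resolved)
        row["x"] = node.x
        row["y"] = node.y
        rows.append(row)
    for i, edge in enumerate(graph.edges):
        row = {
            "element": "edge",
            "key": f"{edge.source_key}->{edge.target_key}#{i}",
        }
        resolved = dict(edge_base)
        for m in edge_maps:
            value = _attr_value(edge, m.attribute)
            if value is _KNOWN_ATTRS or value is None:
                continue
            out = m.resolve(value)
            if out is not None:
                resolved[m.target] = out
        row.update(resolved)
        sx, sy = positions[edge.source_key]
        tx, ty = positions[edge.target_key]
        row["x"] = (sx + tx) / 2
        row["y"] = (sy + ty) / 2
        rows.append(row)
    table = pd.DataFrame(rows).set_index("key")
    return table


def style_to_json(style: VisualStyle) -> str:
    """Serialize a style (name, defaults, mappings) for reuse."""
    doc = {
        "style_name": style.style_name,
        "node_defaults": style.node_defaults,
        "edge_defaults": style.edge_defaults,
        "mappings": [
            {
                "attribute": m.attribute,
                "target": m.target,
                "kind": m.kind,
                "element": m.element,
                "table": m.table,
                "anchors": [[a, v] for a, v in m.anchors],
            }
            for m in style.mappings
        ],
    }
    return json.dumps(doc, indent=2)


def style_from_json(text: str) -> VisualStyle:
    doc = json.loads(text)
    return VisualStyle(
        style_name=doc["style_name"],
        node_defaults=doc["node_defaults"],
        edge_defaults=doc["edge_defaults"],
        mappings=[
            MappingFunction(
                attribute=m["attribute"],
                target=m["target"],
                kind=m["kind"],
                element=m.get("element", "node"),
                table=m.get("table", {}),
                anchors=[(a, v) for a, v in m.get("anchors", [])],
            )
            for m in doc["mappings"]
        ],
    )
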