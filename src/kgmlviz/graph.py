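"""Convert a parsed KGML pathway into an attributed property graph.

The product is a node list plus edge list with all diagram attributes
attached (position, size, shape, colors, KEGG ids), analogous to the
network-plus-attribute-table pair used by desktop network tools.  Three
constructions beyond plain entries/relations need care:

* reactions become substrate -> enzyme -> product edges through the
  catalyzing entry's node, so enzymes mediate compound connectivity as they
  do on the drawn map;
* group entries become an explicit group node plus ``contains`` edges (no
  metanode collapse);
* global-map entries drawn as polylines (line-type graphics with a
  coordinate list) become chains of small invisible anchor nodes joined by
  ``segment`` edges that inherit the line's color and KEGG ids.

Output ordering is deterministic: entries by document order, anchors by
coordinate order, edges grouped by construction rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kgml import KgmlEntry, KgmlPathway, KgmlValidationError, validate_pathway
from .style import node_label

__all__ = [
    "GraphNode",
    "GraphEdge",
    "PathwayGraph",
    "BuildOptions",
    "build_graph",
    "relation_edges",
    "reaction_edges",
    "build_segments",
]

ANCHOR_DIAMETER = 3.0  # px; joints approximating Atlas polylines


@dataclass
class GraphNode:
    node_key: str
    entry_id: int | None
    names: list[str]
    entry_type: str
    label: str
    x: float
    y: float
    width: float
    height: float
    shape_type: str
    fg_color: str
    bg_color: str
    reaction_names: list[str] = field(default_factory=list)
    is_ko_annotated: bool = False
    attrs: dict[str, float | str] = field(default_factory=dict)


@dataclass
class GraphEdge:
    source_key: str
    target_key: str
    interaction: str
    relation_type: str = ""
    subtype_names: list[str] = field(default_factory=list)
    via_compound_id: int | None = None
    direction: str = "directed"
    fg_color: str = "#000000"
    line_width: float = 1.0
    names: list[str] = field(default_factory=list)


@dataclass
class PathwayGraph:
    pathway_name: str
    title: str
    org: str
    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)
    group_membership: dict[str, list[str]] = field(default_factory=dict)

    def node_by_key(self, key: str) -> GraphNode:
        return self._index()[key]

    def _index(self) -> dict[str, GraphNode]:
        return {n.node_key: n for n in self.nodes}


@dataclass
class BuildOptions:
    """Knobs for graph construction; defaults reproduce the drawn diagram."""

    anchor_diameter: float = ANCHOR_DIAMETER


def _entry_key(entry_id: int) -> str:
    return f"entry:{entry_id}"


def _is_ko(entry: KgmlEntry) -> bool:
    return entry.entry_type == "ortholog" or any(
        n.startswith("ko:") for n in entry.names
    )


def _entry_node(entry: KgmlEntry) -> GraphNode:
    g = entry.graphics
    return GraphNode(
        node_key=_entry_key(entry.entry_id),
        entry_id=entry.entry_id,
        names=list(entry.names),
        entry_type=entry.entry_type,
        label=node_label(g.label),
        x=g.x,
        y=g.y,
        width=g.width,
        height=g.height,
        shape_type=g.shape_type,
        fg_color=g.fg_color,
        bg_color=g.bg_color,
        reaction_names=list(entry.reaction_names),
        is_ko_annotated=_is_ko(entry),
    )


def build_segments(
    entry: KgmlEntry, anchor_diameter: float = ANCHOR_DIAMETER
) -> tuple[list[GraphNode], list[GraphEdge]]:
    """Expand a line-graphics entry into an anchor chain.

    k coordinate pairs yield k anchor nodes at those positions and k-1
    ``segment`` edges connecting consecutive anchors.  Segment edges carry
    the entry's foreground color (the drawn line color) and its KEGG ids so
    that omics overlays can still find the reaction line.
    """
    g = entry.graphics
    if g.shape_type != "line":
        raise KgmlValidationError(
            f"entry {entry.entry_id} primary graphics is not a line"
        )
    if len(g.coords) < 2:
        raise KgmlValidationError(
            f"entry {entry.entry_id} line has fewer than 2 coord pairs"
        )
    anchors = [
        GraphNode(
            node_key=f"anchor:{entry.entry_id}:{k}",
            entry_id=entry.entry_id,
            names=list(entry.names),
            entry_type="anchor",
            label="",
            x=x,
            y=y,
            width=anchor_diameter,
            height=anchor_diameter,
            shape_type="circle",
            fg_color=g.fg_color,
            bg_color=g.fg_color,
            reaction_names=list(entry.reaction_names),
            is_ko_annotated=_is_ko(entry),
        )
        for k, (x, y) in enumerate(g.coords)
    ]
    segments = [
        GraphEdge(
            source_key=anchors[k].node_key,
            target_key=anchors[k + 1].node_key,
            interaction="segment",
            fg_color=g.fg_color,
            names=list(entry.names),
        )
        for k in range(len(anchors) - 1)
    ]
    return anchors, segments


def relation_edges(pathway: KgmlPathway) -> list[GraphEdge]:
    """One directed edge entry1 -> entry2 per relation.

    The interaction label is ``<type>:<subtype names comma-joined>`` (bare
    type when there are no subtypes).  A ``compound`` subtype is recorded
    on the edge as ``via_compound_id`` without rerouting the edge through
    the compound node, keeping the drawn relation count stable.
    """
    edges = []
    for rel in pathway.relations:
        subtype_names = [st.name for st in rel.subtypes]
        interaction = rel.relation_type
        if subtype_names:
            interaction += ":" + ",".join(subtype_names)
        via = None
        for st in rel.subtypes:
            if st.name == "compound" and st.value:
                via = int(st.value)
                break
        edges.append(GraphEdge(
            source_key=_entry_key(rel.entry1),
            target_key=_entry_key(rel.entry2),
            interaction=interaction,
            relation_type=rel.relation_type,
            subtype_names=subtype_names,
            via_compound_id=via,
        ))
    return edges


def reaction_edges(pathway: KgmlPathway) -> list[GraphEdge]:
    """Substrate -> enzyme and enzyme -> product edges per reaction.

    All edges of a reversible reaction are flagged ``reversible``; exporters
    may expand those into reciprocal pairs if a target format requires it.
    """
    known = {e.entry_id for e in pathway.entries}
    edges = []
    for rxn in pathway.reactions:
        if rxn.reaction_entry_id not in known:
            raise KgmlValidationError(
                f"reaction {' '.join(rxn.reaction_names)} references missing "
                f"entry {rxn.reaction_entry_id}"
            )
        enzyme_key = _entry_key(rxn.reaction_entry_id)
        direction = (
            "reversible" if rxn.direction == "reversible" else "directed"
        )
        for sid in rxn.substrate_ids:
            edges.append(GraphEdge(
                source_key=_entry_key(sid),
                target_key=enzyme_key,
                interaction="substrate",
                direction=direction,
                names=list(rxn.reaction_names),
            ))
        for pid in rxn.product_ids:
            edges.append(GraphEdge(
                source_key=enzyme_key,
                target_key=_entry_key(pid),
                interaction="product",
                direction=direction,
                names=list(rxn.reaction_names),
            ))
    return edges


def build_graph(
    pathway: KgmlPathway, options: BuildOptions | None = None
) -> PathwayGraph:
    """Build the attributed property graph for a valid pathway.

    Raises :class:`KgmlValidationError` with the full violation list when
    the pathway breaks the model invariants.
    """
    options = options or BuildOptions()
    violations = validate_pathway(pathway)
    if violations:
        raise KgmlValidationError("; ".join(str(v) for v in violations))

    graph = PathwayGraph(
        pathway_name=pathway.name, title=pathway.title, org=pathway.org
    )
    segment_edges: list[GraphEdge] = []
    contains_edges: list[GraphEdge] = []

    for entry in sorted(pathway.entries, key=lambda e: e.entry_id):
        if entry.is_line:
            anchors, segments = build_segments(entry, options.anchor_diameter)
            graph.nodes.extend(anchors)
            segment_edges.extend(segments)
        else:
            graph.nodes.append(_entry_node(entry))
            if entry.entry_type == "group":
                members = [_entry_key(c) for c in entry.component_ids]
                graph.group_membership[_entry_key(entry.entry_id)] = members
                contains_edges.extend(
                    GraphEdge(
                        source_key=_entry_key(entry.entry_id),
                        target_key=m,
                        interaction="contains",
                    )
                    for m in members
                )

    graph.edges.extend(relation_edges(pathway))
    graph.edges.extend(reaction_edges(pathway))
    graph.edges.extend(contains_edges)
    graph.edges.extend(segment_edges)

    keys = [n.node_key for n in graph.nodes]
    if len(keys) != len(set(keys)):
        raise KgmlValidationError("duplicate node keys after construction")
    return graph
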