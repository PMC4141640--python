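"""Object model for KGML (KEGG Markup Language) pathway documents.

KGML encodes both the topology of a pathway diagram (entries, relations,
reactions) and its hand-drawn graphics (positions, shapes, colors) in one
XML document.  This module provides a faithful in-memory model of that
content, a validating reader (:func:`parse_kgml`), a serializer
(:func:`write_kgml`) whose output round-trips losslessly through the
reader, and small field utilities.

Coordinates follow the KGML image convention throughout: the origin is the
top-left corner, y increases downward, and ``(x, y)`` is the *center* of a
graphics element.  Attributes outside the modeled set are preserved in an
``extras`` mapping per element so that dialect drift across KEGG releases
does not lose information.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from lxml import etree

__all__ = [
    "KgmlGraphics",
    "KgmlEntry",
    "KgmlSubtype",
    "KgmlRelation",
    "KgmlReaction",
    "KgmlPathway",
    "Violation",
    "KgmlParseError",
    "KgmlValidationError",
    "parse_kgml",
    "write_kgml",
    "validate_pathway",
    "parse_hex_color",
]

HEX_COLOR_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")

ENTRY_TYPES = frozenset(
    {"ortholog", "enzyme", "reaction", "gene", "group", "compound", "map",
     "brite", "other"}
)
RELATION_TYPES = frozenset({"ECrel", "PPrel", "GErel", "PCrel", "maplink"})
REACTION_DIRECTIONS = frozenset({"reversible", "irreversible"})
SHAPE_TYPES = frozenset({"rectangle", "circle", "roundrectangle", "line"})

# Conventional KEGG enzyme-box geometry, used when a <graphics> element
# omits the optional attributes.
DEFAULT_FG = "#000000"
DEFAULT_BG = "#FFFFFF"
DEFAULT_WIDTH = 46.0
DEFAULT_HEIGHT = 17.0
DEFAULT_SHAPE = "rectangle"


class KgmlParseError(ValueError):
    """Raised for malformed XML or missing required KGML attributes."""


class KgmlValidationError(ValueError):
    """Raised when a pathway violates the KGML model invariants."""


@dataclass
class KgmlGraphics:
    """One ``<graphics>`` block: how an entry is drawn on the diagram."""

    label: str = ""
    fg_color: str = DEFAULT_FG
    bg_color: str = DEFAULT_BG
    shape_type: str = DEFAULT_SHAPE
    x: float = 0.0
    y: float = 0.0
    width: float = DEFAULT_WIDTH
    height: float = DEFAULT_HEIGHT
    coords: list[tuple[float, float]] = field(default_factory=list)
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class KgmlEntry:
    """A diagram element: gene, enzyme, compound, group, linked map, ..."""

    entry_id: int
    names: list[str]
    entry_type: str
    reaction_names: list[str] = field(default_factory=list)
    link_url: str | None = None
    graphics_list: list[KgmlGraphics] = field(default_factory=list)
    component_ids: list[int] = field(default_factory=list)
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def graphics(self) -> KgmlGraphics:
        """Primary graphics (first block wins for layout and style)."""
        return self.graphics_list[0]

    @property
    def is_line(self) -> bool:
        return bool(self.graphics_list) and self.graphics.shape_type == "line"


@dataclass
class KgmlSubtype:
    name: str
    value: str = ""


@dataclass
class KgmlRelation:
    """An edge between two entries (ECrel/PPrel/GErel/PCrel/maplink)."""

    entry1: int
    entry2: int
    relation_type: str
    subtypes: list[KgmlSubtype] = field(default_factory=list)
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class KgmlReaction:
    """A biochemical transformation through a catalyzing entry."""

    reaction_entry_id: int
    reaction_names: list[str]
    direction: str
    substrate_ids: list[int] = field(default_factory=list)
    product_ids: list[int] = field(default_factory=list)
    substrate_names: list[str] = field(default_factory=list)
    product_names: list[str] = field(default_factory=list)
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class KgmlPathway:
    """One KGML document: identity attributes plus all modeled children."""

    name: str
    org: str = ""
    number: str = ""
    title: str = ""
    image_url: str | None = None
    link_url: str | None = None
    entries: list[KgmlEntry] = field(default_factory=list)
    relations: list[KgmlRelation] = field(default_factory=list)
    reactions: list[KgmlReaction] = field(default_factory=list)
    extras: dict[str, str] = field(default_factory=dict)

    def entry_by_id(self, entry_id: int) -> KgmlEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)


@dataclass(frozen=True)
class Violation:
    """One broken invariant: which element kind, which id, which rule."""

    kind: str
    element_id: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind} {self.element_id}: {self.rule}"


def parse_hex_color(text: str) -> tuple[int, int, int]:
    """Convert ``#RRGGBB`` (case-insensitive) into an (r, g, b) triple."""
    if not isinstance(text, str) or not HEX_COLOR_RE.match(text):
        raise ValueError(f"not a #RRGGBB hex color: {text!r}")
    return int(text[1:3], 16), int(text[3:5], 16), int(text[5:7], 16)


def _num(text: str) -> float:
    return float(text)


def _fmt_num(value: float) -> str:
    """Render a coordinate/size: integral values without a decimal point."""
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


_MODELED = {
    "pathway": {"name", "org", "number", "title", "image", "link"},
    "entry": {"id", "name", "type", "reaction", "link"},
    "graphics": {"name", "fgcolor", "bgcolor", "type", "x", "y", "width",
                 "height", "coords"},
    "relation": {"entry1", "entry2", "type"},
    "subtype": {"name", "value"},
    "reaction": {"id", "name", "type"},
}


def _extras(elem: etree._Element, kind: str) -> dict[str, str]:
    return {k: v for k, v in elem.attrib.items() if k not in _MODELED[kind]}


def _require(elem: etree._Element, attr: str) -> str:
    value = elem.get(attr)
    if value is None:
        raise KgmlParseError(
            f"<{elem.tag}> element missing required attribute {attr!r}"
        )
    return value


def _parse_coords(text: str) -> list[tuple[float, float]]:
    parts = [p for p in text.split(",") if p.strip() != ""]
    if len(parts) % 2 != 0:
        raise KgmlParseError(f"odd-length coords list: {text!r}")
    nums = [_num(p) for p in parts]
    return [(nums[i], nums[i + 1]) for i in range(0, len(nums), 2)]


def _parse_graphics(elem: etree._Element) -> KgmlGraphics:
    shape = elem.get("type", DEFAULT_SHAPE)
    coords_text = elem.get("coords")
    coords = _parse_coords(coords_text) if coords_text is not None else []
    g = KgmlGraphics(
        label=elem.get("name", ""),
        fg_color=elem.get("fgcolor", DEFAULT_FG),
        bg_color=elem.get("bgcolor", DEFAULT_BG),
        shape_type=shape,
        x=_num(elem.get("x", "0")),
        y=_num(elem.get("y", "0")),
        width=_num(elem.get("width", str(DEFAULT_WIDTH))),
        height=_num(elem.get("height", str(DEFAULT_HEIGHT))),
        coords=coords,
        extras=_extras(elem, "graphics"),
    )
    return g


def _parse_entry(elem: etree._Element) -> KgmlEntry:
    entry_id = int(_require(elem, "id"))
    name = _require(elem, "name")
    entry_type = _require(elem, "type")
    reaction_attr = elem.get("reaction")
    graphics_list = [_parse_graphics(g) for g in elem.findall("graphics")]
    if not graphics_list:
        graphics_list = [KgmlGraphics()]
    component_ids = [int(_require(c, "id")) for c in elem.findall("component")]
    return KgmlEntry(
        entry_id=entry_id,
        names=name.split(),
        entry_type=entry_type,
        reaction_names=reaction_attr.split() if reaction_attr else [],
        link_url=elem.get("link"),
        graphics_list=graphics_list,
        component_ids=component_ids,
        extras=_extras(elem, "entry"),
    )


def _parse_relation(elem: etree._Element) -> KgmlRelation:
    return KgmlRelation(
        entry1=int(_require(elem, "entry1")),
        entry2=int(_require(elem, "entry2")),
        relation_type=_require(elem, "type"),
        subtypes=[
            KgmlSubtype(name=_require(s, "name"), value=s.get("value", ""))
            for s in elem.findall("subtype")
        ],
        extras=_extras(elem, "relation"),
    )


def _parse_reaction(elem: etree._Element) -> KgmlReaction:
    substrates = elem.findall("substrate")
    products = elem.findall("product")
    extras = _extras(elem, "reaction")
    # `alt` children are not consumed; their names are kept for round-trip.
    alts = [a.get("name", "") for a in elem.findall("substrate/alt")]
    alts += [a.get("name", "") for a in elem.findall("product/alt")]
    if alts:
        extras["alt"] = " ".join(alts)
    return KgmlReaction(
        reaction_entry_id=int(_require(elem, "id")),
        reaction_names=_require(elem, "name").split(),
        direction=_require(elem, "type"),
        substrate_ids=[int(_require(s, "id")) for s in substrates],
        product_ids=[int(_require(p, "id")) for p in products],
        substrate_names=[s.get("name", "") for s in substrates],
        product_names=[p.get("name", "") for p in products],
        extras=extras,
    )


def parse_kgml(document: str | bytes) -> KgmlPathway:
    """Parse a KGML document into a :class:`KgmlPathway`.

    The mapping is lossless with respect to the modeled fields; unmodeled
    attributes land in each element's ``extras``.  The entry ``name``
    attribute is split on whitespace runs into the ``names`` list, order
    preserved.

    Raises
    ------
    KgmlParseError
        For malformed XML (message names line/column) or a missing
        required attribute.
    KgmlValidationError
        For dangling id references (message lists the ids).
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        # DTD references in real KGML headers point at the network; never
        # resolve them.
        parser = etree.XMLParser(resolve_entities=False, no_network=True,
                                 load_dtd=False)
        root = etree.fromstring(document, parser=parser)
    except etree.XMLSyntaxError as exc:
        raise KgmlParseError(f"malformed XML: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlParseError(
            f"root element is <{root.tag}>, expected <pathway>"
        )
    pathway = KgmlPathway(
        name=_require(root, "name"),
        org=root.get("org", ""),
        number=root.get("number", ""),
        title=root.get("title", ""),
        image_url=root.get("image"),
        link_url=root.get("link"),
        entries=[_parse_entry(e) for e in root.findall("entry")],
        relations=[_parse_relation(r) for r in root.findall("relation")],
        reactions=[_parse_reaction(r) for r in root.findall("reaction")],
        extras=_extras(root, "pathway"),
    )
    dangling = [
        v for v in validate_pathway(pathway) if "unresolved" in v.rule
    ]
    if dangling:
        ids = sorted({v.element_id for v in dangling})
        raise KgmlValidationError(
            "dangling id reference(s): " + ", ".join(ids)
        )
    return pathway


def _graphics_element(g: KgmlGraphics) -> etree._Element:
    elem = etree.Element("graphics")
    if g.label:
        elem.set("name", g.label)
    elem.set("fgcolor", g.fg_color)
    elem.set("bgcolor", g.bg_color)
    elem.set("type", g.shape_type)
    elem.set("x", _fmt_num(g.x))
    elem.set("y", _fmt_num(g.y))
    elem.set("width", _fmt_num(g.width))
    elem.set("height", _fmt_num(g.height))
    if g.coords:
        elem.set("coords", ",".join(
            f"{_fmt_num(x)},{_fmt_num(y)}" for x, y in g.coords
        ))
    for k, v in g.extras.items():
        elem.set(k, v)
    return elem


def write_kgml(pathway: KgmlPathway) -> str:
    """Serialize a pathway back to KGML text.

    ``parse_kgml(write_kgml(p))`` equals ``p`` field-by-field for any
    pathway satisfying the model invariants; serialization refuses invalid
    pathways before emitting anything.
    """
    violations = validate_pathway(pathway)
    if violations:
        raise KgmlValidationError(
            "; ".join(str(v) for v in violations)
        )
    root = etree.Element("pathway")
    root.set("name", pathway.name)
    if pathway.org:
        root.set("org", pathway.org)
    if pathway.number:
        root.set("number", pathway.number)
    if pathway.title:
        root.set("title", pathway.title)
    if pathway.image_url is not None:
        root.set("image", pathway.image_url)
    if pathway.link_url is not None:
        root.set("link", pathway.link_url)
    for k, v in pathway.extras.items():
        root.set(k, v)
    for entry in pathway.entries:
        e = etree.SubElement(root, "entry")
        e.set("id", str(entry.entry_id))
        e.set("name", " ".join(entry.names))
        e.set("type", entry.entry_type)
        if entry.reaction_names:
            e.set("reaction", " ".join(entry.reaction_names))
        if entry.link_url is not None:
            e.set("link", entry.link_url)
        for k, v in entry.extras.items():
            e.set(k, v)
        for g in entry.graphics_list:
            e.append(_graphics_element(g))
        for cid in entry.component_ids:
            etree.SubElement(e, "component").set("id", str(cid))
    for rel in pathway.relations:
        r = etree.SubElement(root, "relation")
        r.set("entry1", str(rel.entry1))
        r.set("entry2", str(rel.entry2))
        r.set("type", rel.relation_type)
        for k, v in rel.extras.items():
            r.set(k, v)
        for st in rel.subtypes:
            s = etree.SubElement(r, "subtype")
            s.set("name", st.name)
            if st.value:
                s.set("value", st.value)
    for rxn in pathway.reactions:
        r = etree.SubElement(root, "reaction")
        r.set("id", str(rxn.reaction_entry_id))
        r.set("name", " ".join(rxn.reaction_names))
        r.set("type", rxn.direction)
        for k, v in rxn.extras.items():
            if k == "alt":
                continue
            r.set(k, v)
        for sid, sname in zip(rxn.substrate_ids, rxn.substrate_names):
            s = etree.SubElement(r, "substrate")
            s.set("id", str(sid))
            if sname:
                s.set("name", sname)
        for pid, pname in zip(rxn.product_ids, rxn.product_names):
            p = etree.SubElement(r, "product")
            p.set("id", str(pid))
            if pname:
                p.set("name", pname)
    text = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    return text.decode("utf-8")


def validate_pathway(pathway: KgmlPathway) -> list[Violation]:
    """Check the model invariants; return one record per broken rule.

    An empty list means the pathway is valid.  Nothing is raised here:
    callers that need a hard failure raise on a nonempty result.
    """
    out: list[Violation] = []
    seen_ids: set[int] = set()
    known_ids: set[int] = {e.entry_id for e in pathway.entries}
    compound_ids = {
        e.entry_id for e in pathway.entries
        if e.entry_type in ("compound", "other")
    }

    for entry in pathway.entries:
        eid = str(entry.entry_id)
        if entry.entry_id in seen_ids:
            out.append(Violation("entry", eid, "duplicate entry_id"))
        seen_ids.add(entry.entry_id)
        if not entry.names:
            out.append(Violation("entry", eid, "names is empty"))
        if entry.entry_type not in ENTRY_TYPES:
            out.append(Violation(
                "entry", eid, f"unknown entry type {entry.entry_type!r}"
            ))
        if entry.entry_type == "group" and not entry.component_ids:
            out.append(Violation(
                "entry", eid, "group entry with empty component_ids"
            ))
        if entry.entry_type != "group" and entry.component_ids:
            out.append(Violation(
                "entry", eid, "component_ids on a non-group entry"
            ))
        for cid in entry.component_ids:
            if cid not in known_ids:
                out.append(Violation(
                    "entry", str(cid),
                    f"unresolved component reference from group {eid}"
                ))
        if not entry.graphics_list:
            out.append(Violation("entry", eid, "no graphics block"))
        for g in entry.graphics_list:
            if g.width < 0 or g.height < 0:
                out.append(Violation("graphics", eid, "negative size"))
            for color in (g.fg_color, g.bg_color):
                if color and not HEX_COLOR_RE.match(color):
                    out.append(Violation(
                        "graphics", eid, f"bad hex color {color!r}"
                    ))
            if g.shape_type not in SHAPE_TYPES:
                out.append(Violation(
                    "graphics", eid, f"unknown shape {g.shape_type!r}"
                ))
            if g.coords and g.shape_type != "line":
                out.append(Violation(
                    "graphics", eid, "coords on a non-line graphics"
                ))
            if g.coords and len(g.coords) < 2:
                out.append(Violation(
                    "graphics", eid, "line with fewer than 2 coord pairs"
                ))
            if g.shape_type == "line" and not g.coords:
                out.append(Violation(
                    "graphics", eid, "line graphics without coords"
                ))

    for i, rel in enumerate(pathway.relations):
        rid = f"relation[{i}]"
        if rel.relation_type not in RELATION_TYPES:
            out.append(Violation(
                "relation", rid, f"unknown relation type {rel.relation_type!r}"
            ))
        for endpoint in (rel.entry1, rel.entry2):
            if endpoint not in known_ids:
                out.append(Violation(
                    "relation", str(endpoint),
                    f"unresolved entry reference in {rid}"
                ))
        for st in rel.subtypes:
            if not st.name:
                out.append(Violation("subtype", rid, "empty subtype name"))
            if st.name == "compound" and st.value:
                try:
                    cid = int(st.value)
                except ValueError:
                    out.append(Violation(
                        "subtype", rid,
                        f"non-integer compound value {st.value!r}"
                    ))
                else:
                    if cid not in known_ids:
                        out.append(Violation(
                            "subtype", str(cid),
                            f"unresolved compound reference in {rid}"
                        ))

    for rxn in pathway.reactions:
        rid = str(rxn.reaction_entry_id)
        if rxn.reaction_entry_id not in known_ids:
            out.append(Violation(
                "reaction", rid, "unresolved reaction entry reference"
            ))
        if rxn.direction not in REACTION_DIRECTIONS:
            out.append(Violation(
                "reaction", rid, f"unknown direction {rxn.direction!r}"
            ))
        if not rxn.substrate_ids:
            out.append(Violation("reaction", rid, "no substrates"))
        if not rxn.product_ids:
            out.append(Violation("reaction", rid, "no products"))
        for cid in rxn.substrate_ids + rxn.product_ids:
            if cid not in known_ids:
                out.append(Violation(
                    "reaction", str(cid),
                    f"unresolved compound reference in reaction {rid}"
                ))
            elif cid not in compound_ids:
                out.append(Violation(
                    "reaction", str(cid),
                    f"reaction {rid} participant is not a compound entry"
                ))
    return out
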