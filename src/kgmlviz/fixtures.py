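"""Deterministic synthetic KGML documents and expression matrices.

Three pathway dialects are generated, each structurally shaped like its
real counterpart without mimicking any real biochemistry (organism code
``syn`` marks everything as synthetic):

* metabolic maps — enzyme boxes and compound circles wired by reactions
  and ECrel relations with compound subtypes;
* signaling maps — gene boxes, PPrel/GErel relations with
  activation/inhibition/expression subtypes, group entries, and a linked
  map box;
* global (Atlas-style) maps — reactions drawn as colored polylines (line
  graphics with coordinate lists) with compound circles at the endpoints.

Every generator returns the KGML text together with a
:class:`FixtureTruth` record of what was planted (element counts,
per-reaction arities, line coordinate counts, differentially expressed
rows), so downstream code can be tested against generator-side ground
truth.  One seed drives topology, layout and colors; the same parameters
and seed always produce identical bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import PathwayGraph
from .kgml import (
    KgmlEntry,
    KgmlGraphics,
    KgmlPathway,
    KgmlReaction,
    KgmlRelation,
    KgmlSubtype,
    write_kgml,
)
from .overlay import OmicsTable

__all__ = [
    "GeneratorParams",
    "FixtureTruth",
    "make_metabolic_kgml",
    "make_signaling_kgml",
    "make_global_map_kgml",
    "make_expression_fixture",
]

GRID_SPACING = (92.0, 46.0)  # KEGG-like box pitch, collision-free
GRID_COLUMNS = 8
ENZYME_SIZE = (46.0, 17.0)
COMPOUND_SIZE = (8.0, 8.0)


@dataclass
class GeneratorParams:
    n_enzymes: int = 5
    n_compounds: int = 6
    n_relations: int = 3
    n_reactions: int = 5
    n_groups: int = 0
    n_lines: int = 4
    org: str = "syn"
    seed: int = 0
    grid_spacing: tuple[float, float] = GRID_SPACING

    def __post_init__(self) -> None:
        for name in ("n_enzymes", "n_compounds", "n_relations",
                     "n_reactions", "n_groups", "n_lines"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FixtureTruth:
    entry_count: int = 0
    relation_count: int = 0
    reaction_count: int = 0
    substrate_counts: list[int] = field(default_factory=list)
    product_counts: list[int] = field(default_factory=list)
    group_sizes: list[int] = field(default_factory=list)
    line_coord_counts: list[int] = field(default_factory=list)
    subtype_tally: dict[str, int] = field(default_factory=dict)
    planted_de_rows: set[str] = field(default_factory=set)
    gene_to_node: dict[str, str] = field(default_factory=dict)
    planted_node_keys: set[str] = field(default_factory=set)

    @property
    def expected_nodes(self) -> int:
        """Graph node count implied by the construction rules."""
        n_line = len(self.line_coord_counts)
        return self.entry_count - n_line + sum(self.line_coord_counts)

    @property
    def expected_edges(self) -> int:
        return (
            self.relation_count
            + sum(self.substrate_counts)
            + sum(self.product_counts)
            + sum(self.group_sizes)
            + sum(c - 1 for c in self.line_coord_counts)
        )


def _grid_xy(index: int, spacing: tuple[float, float]) -> tuple[float, float]:
    sx, sy = spacing
    return (
        60.0 + sx * (index % GRID_COLUMNS),
        40.0 + sy * (index // GRID_COLUMNS),
    )


_HEX_DIGITS = "0123456789abcdefABCDEF"


def _random_color(rng: np.random.Generator) -> str:
    """Random hex color with mixed-case digits (round trips must keep case)."""
    return "#" + "".join(
        _HEX_DIGITS[i] for i in rng.integers(0, len(_HEX_DIGITS), size=6)
    )


def _pathway_shell(kind: str, params: GeneratorParams) -> KgmlPathway:
    number = {"metabolic": "00900", "signaling": "04900",
              "global": "01100"}[kind]
    return KgmlPathway(
        name=f"path:{params.org}{number}",
        org=params.org,
        number=number,
        title=f"Synthetic {kind} pathway",
    )


def make_metabolic_kgml(
    params: GeneratorParams | None = None,
) -> tuple[str, FixtureTruth]:
    """Metabolic-map fixture: enzymes, compounds, reactions, ECrel links."""
    params = params or GeneratorParams()
    if params.n_reactions > 0 and params.n_compounds < 2:
        raise ValueError("reactions need at least 2 compounds to wire")
    if params.n_relations > 0 and params.n_enzymes < 2:
        raise ValueError("ECrel relations need at least 2 enzyme entries")
    if params.n_reactions > 0 and params.n_enzymes < 1:
        raise ValueError("reactions need at least 1 enzyme entry")
    rng = np.random.default_rng(params.seed)
    pathway = _pathway_shell("metabolic", params)
    truth = FixtureTruth()

    compound_ids = []
    next_id = 1
    gene_counter = 1
    for i in range(params.n_compounds):
        x, y = _grid_xy(i, params.grid_spacing)
        pathway.entries.append(KgmlEntry(
            entry_id=next_id,
            names=[f"cpd:C{10000 + next_id:05d}"],
            entry_type="compound",
            graphics_list=[KgmlGraphics(
                label=f"C{10000 + next_id:05d}",
                fg_color=_random_color(rng),
                bg_color=_random_color(rng),
                shape_type="circle",
                x=x, y=y,
                width=COMPOUND_SIZE[0], height=COMPOUND_SIZE[1],
            )],
        ))
        compound_ids.append(next_id)
        next_id += 1

    enzyme_ids = []
    for i in range(params.n_enzymes):
        x, y = _grid_xy(params.n_compounds + i, params.grid_spacing)
        n_genes = int(rng.integers(1, 4))
        names = []
        for _ in range(n_genes):
            names.append(f"{params.org}:b{gene_counter:04d}")
            gene_counter += 1
        if rng.random() < 0.3:
            names.append(f"ko:K{10000 + i:05d}")
        pathway.entries.append(KgmlEntry(
            entry_id=next_id,
            names=names,
            entry_type="gene",
            graphics_list=[KgmlGraphics(
                label=", ".join(n.split(":")[1] for n in names),
                fg_color=_random_color(rng),
                bg_color=_random_color(rng),
                shape_type="rectangle",
                x=x, y=y,
                width=ENZYME_SIZE[0], height=ENZYME_SIZE[1],
            )],
        ))
        enzyme_ids.append(next_id)
        next_id += 1

    for r in range(params.n_reactions):
        enzyme = enzyme_ids[r % len(enzyme_ids)]
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        pool = rng.permutation(compound_ids)
        n_sub = min(n_sub, max(1, len(pool) - 1))
        n_prod = min(n_prod, len(pool) - n_sub)
        substrates = [int(c) for c in pool[:n_sub]]
        products = [int(c) for c in pool[n_sub:n_sub + n_prod]]
        direction = "reversible" if rng.random() < 0.5 else "irreversible"
        rname = f"rn:R{90000 + r:05d}"
        pathway.reactions.append(KgmlReaction(
            reaction_entry_id=enzyme,
            reaction_names=[rname],
            direction=direction,
            substrate_ids=substrates,
            product_ids=products,
            substrate_names=[
                pathway.entry_by_id(c).names[0] for c in substrates
            ],
            product_names=[
                pathway.entry_by_id(c).names[0] for c in products
            ],
        ))
        pathway.entry_by_id(enzyme).reaction_names.append(rname)
        truth.substrate_counts.append(n_sub)
        truth.product_counts.append(n_prod)

    for r in range(params.n_relations):
        pair = rng.choice(len(enzyme_ids), size=2, replace=False)
        subtypes = []
        if compound_ids and rng.random() < 0.7:
            via = int(rng.choice(compound_ids))
            subtypes.append(KgmlSubtype(name="compound", value=str(via)))
        pathway.relations.append(KgmlRelation(
            entry1=enzyme_ids[int(pair[0])],
            entry2=enzyme_ids[int(pair[1])],
            relation_type="ECrel",
            subtypes=subtypes,
        ))
        for st in subtypes:
            truth.subtype_tally[st.name] = truth.subtype_tally.get(st.name, 0) + 1

    truth.entry_count = len(pathway.entries)
    truth.relation_count = len(pathway.relations)
    truth.reaction_count = len(pathway.reactions)
    return write_kgml(pathway), truth


_SIGNALING_SUBTYPES = (
    "activation", "inhibition", "expression", "phosphorylation",
    "binding/association",
)


def make_signaling_kgml(
    params: GeneratorParams | None = None,
) -> tuple[str, FixtureTruth]:
    """Signaling-map fixture: genes, PPrel/GErel relations, groups, map box."""
    params = params or GeneratorParams(
        n_enzymes=8, n_compounds=0, n_relations=6, n_reactions=0, n_groups=1
    )
    if params.n_relations > 0 and params.n_enzymes < 2:
        raise ValueError("relations need at least 2 gene entries")
    if params.n_groups > 0 and params.n_enzymes < 2:
        raise ValueError("groups need at least 2 gene entries")
    rng = np.random.default_rng(params.seed)
    pathway = _pathway_shell("signaling", params)
    truth = FixtureTruth()

    gene_ids = []
    next_id = 1
    for i in range(params.n_enzymes):
        x, y = _grid_xy(i, params.grid_spacing)
        names = [f"{params.org}:g{1000 + next_id:04d}"]
        if rng.random() < 0.4:
            names.append(f"ko:K{20000 + i:05d}")
        pathway.entries.append(KgmlEntry(
            entry_id=next_id,
            names=names,
            entry_type="gene",
            graphics_list=[KgmlGraphics(
                label=f"g{1000 + next_id}, alias{next_id}",
                fg_color=_random_color(rng),
                bg_color=_random_color(rng),
                shape_type="rectangle",
                x=x, y=y,
                width=ENZYME_SIZE[0], height=ENZYME_SIZE[1],
            )],
        ))
        gene_ids.append(next_id)
        next_id += 1

    # linked-map box, drawn as a round rectangle
    x, y = _grid_xy(params.n_enzymes, params.grid_spacing)
    pathway.entries.append(KgmlEntry(
        entry_id=next_id,
        names=[f"path:{params.org}04910"],
        entry_type="map",
        graphics_list=[KgmlGraphics(
            label="Linked synthetic pathway...",
            fg_color="#000000",
            bg_color="#FFFFFF",
            shape_type="roundrectangle",
            x=x, y=y, width=110.0, height=34.0,
        )],
    ))
    map_id = next_id
    next_id += 1

    for _ in range(params.n_groups):
        size = int(rng.integers(2, min(4, len(gene_ids)) + 1))
        members = [int(g) for g in rng.choice(gene_ids, size=size,
                                              replace=False)]
        x, y = _grid_xy(next_id, params.grid_spacing)
        pathway.entries.append(KgmlEntry(
            entry_id=next_id,
            names=["undefined"],
            entry_type="group",
            graphics_list=[KgmlGraphics(
                label="",
                shape_type="rectangle",
                x=x, y=y, width=100.0, height=60.0,
            )],
            component_ids=members,
        ))
        truth.group_sizes.append(size)
        next_id += 1

    for r in range(params.n_relations):
        if r == 0 and params.n_relations > 0:
            # one maplink so linked-map boxes participate in the topology
            a = int(rng.choice(gene_ids))
            pathway.relations.append(KgmlRelation(
                entry1=a, entry2=map_id, relation_type="maplink",
                subtypes=[KgmlSubtype(name="indirect effect")],
            ))
            truth.subtype_tally["indirect effect"] = (
                truth.subtype_tally.get("indirect effect", 0) + 1
            )
            continue
        pair = rng.choice(len(gene_ids), size=2, replace=False)
        rel_type = "PPrel" if rng.random() < 0.7 else "GErel"
        subtype = str(rng.choice(_SIGNALING_SUBTYPES))
        if rel_type == "GErel":
            subtype = "expression"
        pathway.relations.append(KgmlRelation(
            entry1=gene_ids[int(pair[0])],
            entry2=gene_ids[int(pair[1])],
            relation_type=rel_type,
            subtypes=[KgmlSubtype(name=subtype)],
        ))
        truth.subtype_tally[subtype] = truth.subtype_tally.get(subtype, 0) + 1

    truth.entry_count = len(pathway.entries)
    truth.relation_count = len(pathway.relations)
    truth.reaction_count = 0
    return write_kgml(pathway), truth


def make_global_map_kgml(
    params: GeneratorParams | None = None,
) -> tuple[str, FixtureTruth]:
    """Atlas-style fixture: colored polylines with compounds at endpoints."""
    params = params or GeneratorParams(n_lines=4, n_compounds=5)
    rng = np.random.default_rng(params.seed)
    pathway = _pathway_shell("global", params)
    truth = FixtureTruth()

    next_id = 1
    compound_ids = []
    for i in range(params.n_compounds):
        x, y = _grid_xy(i, params.grid_spacing)
        pathway.entries.append(KgmlEntry(
            entry_id=next_id,
            names=[f"cpd:C{30000 + next_id:05d}"],
            entry_type="compound",
            graphics_list=[KgmlGraphics(
                label=f"C{30000 + next_id:05d}",
                fg_color=_random_color(rng),
                bg_color=_random_color(rng),
                shape_type="circle",
                x=x, y=y,
                width=COMPOUND_SIZE[0], height=COMPOUND_SIZE[1],
            )],
        ))
        compound_ids.append(next_id)
        next_id += 1

    for i in range(params.n_lines):
        n_coords = int(rng.integers(2, 9))
        if compound_ids:
            start = pathway.entry_by_id(
                int(rng.choice(compound_ids))).graphics
            end = pathway.entry_by_id(
                int(rng.choice(compound_ids))).graphics
            sx, sy = start.x, start.y
            ex, ey = end.x, end.y
        else:
            sx, sy = _grid_xy(i, params.grid_spacing)
            ex, ey = sx + 100, sy + 50
        # polyline wanders between the two endpoint compounds
        coords = [(sx, sy)]
        for k in range(1, n_coords - 1):
            t = k / (n_coords - 1)
            coords.append((
                round(sx + (ex - sx) * t + float(rng.integers(-20, 21)), 1),
                round(sy + (ey - sy) * t + float(rng.integers(-20, 21)), 1),
            ))
        coords.append((ex, ey))
        pathway.entries.append(KgmlEntry(
            entry_id=next_id,
            names=[f"ko:K{30000 + i:05d}"],
            entry_type="ortholog",
            reaction_names=[f"rn:R{80000 + i:05d}"],
            graphics_list=[KgmlGraphics(
                label=f"R{80000 + i:05d}",
                fg_color=_random_color(rng),
                bg_color="#FFFFFF",
                shape_type="line",
                x=0.0, y=0.0, width=0.0, height=0.0,
                coords=coords,
            )],
        ))
        truth.line_coord_counts.append(n_coords)
        next_id += 1

    truth.entry_count = len(pathway.entries)
    return write_kgml(pathway), truth


def make_expression_fixture(
    graph: PathwayGraph,
    n_genes: int = 1000,
    n_per_group: int = 4,
    effect_size: float = 5.0,
    planted_fraction: float = 0.05,
    seed: int = 0,
    mapping_coverage: float | None = None,
) -> tuple[pd.DataFrame, dict[str, str], FixtureTruth]:
    """Expression matrix with planted differential expression.

    Rows are probeset-style ids over unit-variance Gaussian noise;
    ``ceil(planted_fraction * n_genes)`` rows (none when ``effect_size`` is
    0) are shifted by ``effect_size`` standard deviations in the second
    group.  The mapping table assigns KEGG gene ids drawn from the graph's
    gene nodes to ``ceil(mapping_coverage * n_genes)`` rows, planted rows
    first — mapped rows are the pathway members, the rest of the chip lies
    outside the map.  ``mapping_coverage`` defaults to ``planted_fraction``.

    Returns the matrix (samples ``ctl*`` then ``mut*`` in columns), the
    row-id -> KEGG-id mapping, and the ground truth (planted rows, the
    gene -> node assignment, and the node keys holding planted genes).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must be in [0, 1]")
    gene_nodes = [
        n for n in graph.nodes
        if n.entry_type in ("gene", "ortholog") and n.names
    ]
    if not gene_nodes:
        raise ValueError("graph has no gene nodes to map onto")
    if mapping_coverage is None:
        mapping_coverage = planted_fraction

    rng = np.random.default_rng(seed)
    row_ids = [f"ps{i:05d}_at" for i in range(n_genes)]
    samples = (
        [f"ctl{j + 1}" for j in range(n_per_group)]
        + [f"mut{j + 1}" for j in range(n_per_group)]
    )
    values = rng.normal(0.0, 1.0, size=(n_genes, 2 * n_per_group))

    order = rng.permutation(n_genes)
    n_planted = 0 if effect_size == 0 else math.ceil(
        planted_fraction * n_genes
    )
    planted_rows = [int(i) for i in order[:n_planted]]
    values[planted_rows, n_per_group:] += effect_size

    n_mapped = math.ceil(mapping_coverage * n_genes)
    n_mapped = max(n_mapped, n_planted)
    mapped_rows = [int(i) for i in order[:n_mapped]]

    # one KEGG gene id per node, cycling through the pathway's gene nodes
    node_gene_ids = [n.names[0] for n in gene_nodes]
    mapping: dict[str, str] = {}
    truth = FixtureTruth()
    for j, row in enumerate(mapped_rows):
        gene_id = node_gene_ids[j % len(node_gene_ids)]
        node = gene_nodes[j % len(gene_nodes)]
        mapping[row_ids[row]] = gene_id
        truth.gene_to_node[gene_id] = node.node_key
        if row in set(planted_rows):
            truth.planted_node_keys.add(node.node_key)
    truth.planted_de_rows = {row_ids[r] for r in planted_rows}

    matrix = pd.DataFrame(values, index=row_ids, columns=samples)
    return matrix, mapping, truth


def matrix_to_table(matrix: pd.DataFrame) -> OmicsTable:
    """Wrap a samples-in-columns matrix as an OmicsTable with group labels.

    Sample columns named ``ctl*`` form one group, everything else the other.
    """
    labels = ["ctl" if c.startswith("ctl") else "mut" for c in matrix.columns]
    return OmicsTable(
        row_ids=[str(r) for r in matrix.index],
        matrix=matrix,
        group_labels=labels,
    )
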