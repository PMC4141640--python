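"""Property-graph construction: nodes, edges, groups, anchors, segments."""

import pytest

from kgmlviz import (
    GeneratorParams,
    KgmlValidationError,
    build_graph,
    build_segments,
    make_metabolic_kgml,
    make_signaling_kgml,
    parse_kgml,
    reaction_edges,
    relation_edges,
)
from kgmlviz.kgml import KgmlEntry, KgmlGraphics

from conftest import dialect_makers


def line_entry(coords):
    return KgmlEntry(
        entry_id=42,
        names=["ko:K00042"],
        entry_type="ortholog",
        graphics_list=[KgmlGraphics(
            shape_type="line", fg_color="#8080F7", coords=coords,
            width=0, height=0,
        )],
    )


class TestBuildGraph:
    def test_simple_counts(self, minimal_pathway):
        g = build_graph(minimal_pathway)
        assert len(g.nodes) == 2 and len(g.edges) == 0

    @pytest.mark.parametrize("name,maker,params", dialect_makers())
    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_against_truth(self, name, maker, params, seed):
        text, truth = maker(params(seed))
        g = build_graph(parse_kgml(text))
        assert len(g.nodes) == truth.expected_nodes
        assert len(g.edges) == truth.expected_edges

    def test_group_expansion(self, signaling_fixture):
        text, truth = signaling_fixture
        g = build_graph(parse_kgml(text))
        assert sorted(len(m) for m in g.group_membership.values()) == \
            sorted(truth.group_sizes)
        contains = [e for e in g.edges if e.interaction == "contains"]
        assert len(contains) == sum(truth.group_sizes)
        node_keys = {n.node_key for n in g.nodes}
        for members in g.group_membership.values():
            assert set(members) <= node_keys

    def test_attributes_from_graphics(self, minimal_pathway):
        g = build_graph(minimal_pathway)
        gene = g.node_by_key("entry:1")
        assert (gene.x, gene.y) == (100, 50)
        assert gene.bg_color == "#BFFFBF"
        assert gene.shape_type == "rectangle"
        assert gene.label == "geneA"

    def test_invalid_pathway_aborts(self, minimal_pathway):
        minimal_pathway.entries[1].entry_id = 1
        with pytest.raises(KgmlValidationError, match="duplicate"):
            build_graph(minimal_pathway)

    def test_deterministic_output(self, metabolic_fixture):
        text, _ = metabolic_fixture
        g1 = build_graph(parse_kgml(text))
        g2 = build_graph(parse_kgml(text))
        assert g1 == g2

    def test_ko_annotation_flag(self, signaling_fixture):
        text, _ = signaling_fixture
        g = build_graph(parse_kgml(text))
        for node in g.nodes:
            expected = node.entry_type == "ortholog" or any(
                n.startswith("ko:") for n in node.names
            )
            assert node.is_ko_annotated == expected

    def test_enzyme_degree_equals_reaction_arity(self):
        # brute-force degree oracle on a small instance
        text, truth = make_metabolic_kgml(
            GeneratorParams(n_enzymes=3, n_compounds=4, n_relations=0,
                            n_reactions=3, seed=13)
        )
        pathway = parse_kgml(text)
        g = build_graph(pathway)
        for rxn_index, rxn in enumerate(pathway.reactions):
            key = f"entry:{rxn.reaction_entry_id}"
            degree = sum(
                1 for e in g.edges
                if e.interaction in ("substrate", "product")
                and key in (e.source_key, e.target_key)
            )
            expected = sum(
                truth.substrate_counts[i] + truth.product_counts[i]
                for i, r in enumerate(pathway.reactions)
                if r.reaction_entry_id == rxn.reaction_entry_id
            )
            assert degree == expected


class TestRelationEdges:
    def test_interaction_label_and_direction(self, minimal_pathway):
        from kgmlviz import KgmlRelation
        from kgmlviz.kgml import KgmlSubtype

        minimal_pathway.relations.append(KgmlRelation(
            entry1=1, entry2=2, relation_type="PPrel",
            subtypes=[KgmlSubtype(name="activation")],
        ))
        edges = relation_edges(minimal_pathway)
        assert len(edges) == 1
        assert edges[0].interaction == "PPrel:activation"
        assert edges[0].source_key == "entry:1"
        assert edges[0].target_key == "entry:2"

    def test_compound_subtype_annotated_not_rerouted(self, minimal_pathway):
        from kgmlviz import KgmlRelation
        from kgmlviz.kgml import KgmlSubtype

        minimal_pathway.relations.append(KgmlRelation(
            entry1=1, entry2=1, relation_type="ECrel",
            subtypes=[KgmlSubtype(name="compound", value="2")],
        ))
        edges = relation_edges(minimal_pathway)
        assert edges[0].via_compound_id == 2
        assert edges[0].source_key == "entry:1"
        assert edges[0].target_key == "entry:1"

    def test_one_edge_per_relation(self, metabolic_fixture):
        text, truth = metabolic_fixture
        pathway = parse_kgml(text)
        assert len(relation_edges(pathway)) == truth.relation_count


class TestReactionEdges:
    def test_substrate_and_product_edges_through_enzyme(self, metabolic_fixture):
        text, truth = metabolic_fixture
        pathway = parse_kgml(text)
        edges = reaction_edges(pathway)
        assert len(edges) == sum(truth.substrate_counts) + \
            sum(truth.product_counts)
        for rxn in pathway.reactions:
            key = f"entry:{rxn.reaction_entry_id}"
            subs = [e for e in edges
                    if e.target_key == key and e.interaction == "substrate"
                    and e.names == rxn.reaction_names]
            prods = [e for e in edges
                     if e.source_key == key and e.interaction == "product"
                     and e.names == rxn.reaction_names]
            assert len(subs) >= len(rxn.substrate_ids) > 0
            assert len(prods) >= len(rxn.product_ids) > 0

    def test_reversible_flag_on_all_edges(self, metabolic_fixture):
        text, _ = metabolic_fixture
        pathway = parse_kgml(text)
        edges = reaction_edges(pathway)
        by_reaction = {}
        for rxn in pathway.reactions:
            expected = ("reversible" if rxn.direction == "reversible"
                        else "directed")
            by_reaction.setdefault(tuple(rxn.reaction_names), set()).add(
                expected)
        for e in edges:
            assert e.direction in by_reaction[tuple(e.names)]


class TestSegments:
    def test_two_coords_one_segment(self):
        anchors, segments = build_segments(line_entry([(0, 0), (10, 0)]))
        assert len(anchors) == 2 and len(segments) == 1
        assert segments[0].source_key == "anchor:42:0"
        assert segments[0].target_key == "anchor:42:1"

    def test_chain_connectivity_only(self):
        coords = [(0, 0), (10, 5), (20, 0), (30, 5), (40, 0)]
        anchors, segments = build_segments(line_entry(coords))
        assert len(segments) == len(coords) - 1
        for k, seg in enumerate(segments):
            assert seg.source_key == f"anchor:42:{k}"
            assert seg.target_key == f"anchor:42:{k + 1}"
        assert [(a.x, a.y) for a in anchors] == coords

    def test_segment_color_inherits_entry_fg(self, global_fixture):
        text, _ = global_fixture
        pathway = parse_kgml(text)
        g = build_graph(pathway)
        line_colors = {
            e.entry_id: e.graphics.fg_color
            for e in pathway.entries if e.is_line
        }
        segs = [e for e in g.edges if e.interaction == "segment"]
        assert segs
        for seg in segs:
            entry_id = int(seg.source_key.split(":")[1])
            assert seg.fg_color == line_colors[entry_id]

    def test_anchor_geometry(self):
        anchors, _ = build_segments(line_entry([(0, 0), (10, 0)]))
        for a in anchors:
            assert a.shape_type == "circle"
            assert a.width == a.height == 3.0

    def test_rejects_short_coord_list(self):
        with pytest.raises(KgmlValidationError):
            build_segments(line_entry([(0, 0)]))
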