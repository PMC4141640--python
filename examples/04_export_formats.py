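"""Export one pathway to GraphML, Cytoscape.js JSON, SIF and SVG.

The GraphML and Cytoscape.js documents reimport to the same topology,
attributes and positions; SIF is lossy by design and ships a sidecar
attribute table; the SVG reproduces the diagram's boxes and labels.
"""

from kgmlviz import (
    GeneratorParams,
    build_graph,
    from_cyjs,
    from_graphml,
    make_metabolic_kgml,
    parse_kgml,
    render_svg,
    sif_attribute_table,
    style_from_graph,
    to_cyjs,
    to_graphml,
    to_sif,
)

text, _ = make_metabolic_kgml(GeneratorParams(seed=7))
graph = build_graph(parse_kgml(text))
style = style_from_graph(graph)

graphml = to_graphml(graph, style)
back = from_graphml(graphml)
print(f"graphml : {len(graphml)} chars, reimport "
      f"{len(back.nodes)}/{len(back.edges)} nodes/edges "
      f"(original {len(graph.nodes)}/{len(graph.edges)})")

cyjs = to_cyjs(graph, style)
back = from_cyjs(cyjs)
print(f"cyjs    : reimported positions equal: "
      f"{[ (n.x, n.y) for n in back.nodes ] == [ (n.x, n.y) for n in graph.nodes ]}")

sif = to_sif(graph)
print(f"sif     : {len(sif.strip().splitlines())} lines "
      f"(= edges + isolated nodes), sidecar rows: "
      f"{len(sif_attribute_table(graph).strip().splitlines()) - 1}")

svg = render_svg(graph, style)
print(f"svg     : {svg.count('<rect')} boxes, {svg.count('<ellipse')} "
      f"circles, {svg.count('<text')} labels")
# One shape per visible node, one text element per nonempty label.
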