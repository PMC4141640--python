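import pytest

from kgmlviz import (
    GeneratorParams,
    build_graph,
    make_global_map_kgml,
    make_metabolic_kgml,
    make_signaling_kgml,
    parse_kgml,
)

MINIMAL_KGML = """<?xml version="1.0" encoding="UTF-8"?>
<pathway name="path:syn00001" org="syn" number="00001" title="Minimal">
  <entry id="1" name="syn:b0001" type="gene">
    <graphics name="geneA" fgcolor="#000000" bgcolor="#BFFFBF"
              type="rectangle" x="100" y="50" width="46" height="17"/>
  </entry>
  <entry id="2" name="cpd:C00001" type="compound">
    <graphics name="C00001" fgcolor="#000000" bgcolor="#FFFFFF"
              type="circle" x="200" y="50" width="8" height="8"/>
  </entry>
</pathway>
"""


def dialect_makers():
    """(name, maker, params-factory) for the three KGML dialects."""
    return [
        ("metabolic", make_metabolic_kgml,
         lambda seed: GeneratorParams(seed=seed)),
        ("signaling", make_signaling_kgml,
         lambda seed: GeneratorParams(n_enzymes=8, n_compounds=0,
                                      n_relations=6, n_reactions=0,
                                      n_groups=1, seed=seed)),
        ("global", make_global_map_kgml,
         lambda seed: GeneratorParams(n_lines=4, n_compounds=5, seed=seed)),
    ]


@pytest.fixture
def minimal_pathway():
    return parse_kgml(MINIMAL_KGML)


@pytest.fixture
def metabolic_fixture():
    text, truth = make_metabolic_kgml(GeneratorParams(seed=7))
    return text, truth


@pytest.fixture
def metabolic_graph(metabolic_fixture):
    text, truth = metabolic_fixture
    return build_graph(parse_kgml(text)), truth


@pytest.fixture
def global_fixture():
    text, truth = make_global_map_kgml(
        GeneratorParams(n_lines=4, n_compounds=5, seed=11)
    )
    return text, truth


@pytest.fixture
def signaling_fixture():
    text, truth = make_signaling_kgml(
        GeneratorParams(n_enzymes=8, n_compounds=0, n_relations=6,
                        n_reactions=0, n_groups=1, seed=5)
    )
    return text, truth
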