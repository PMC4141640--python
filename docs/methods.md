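# Methods

## Scope and data model

`kgmlviz` works with KGML (KEGG Markup Language) pathway documents, which
are unusual among pathway exchange formats in carrying both the machine
topology (entries, relations, reactions) and the hand-drawn diagram
(positions, sizes, shapes, colors) of every element. The toolkit models a
document as a `KgmlPathway` of typed records, converts it to an attributed
property graph (`PathwayGraph`), synthesizes a visual style from the
embedded graphics, overlays per-gene statistics, and exports to GraphML,
Cytoscape.js JSON, SIF and SVG.

Coordinates are kept in the KGML image convention end to end: origin at
the top-left, y increasing downward, `(x, y)` the element center. Nothing
re-lays-out the diagram — the manually drawn positions are the point of
the format, and SVG shares the same axis convention, so rendering needs no
flip.

### Parsing and validation

Parsing is lossless over the modeled fields; attributes outside the
modeled set are retained verbatim in a per-element `extras` map, because
KGML dialects drift across database releases. The entry `name` attribute
is split on whitespace runs into an ordered id list without deduplication
(order carries the display-name choice). When an entry has several
`<graphics>` children all are preserved in order and the first is primary
for layout and style; this first-wins rule is a deterministic choice the
format itself does not prescribe. `alt` children of reaction participants
are not consumed; their names are recorded in `extras` for round-trips.

Missing optional graphics attributes take the conventional enzyme-box
defaults: foreground `#000000`, background `#FFFFFF`, 46×17 px,
rectangle. Validation checks the modeled invariants (unique entry ids,
resolvable references, group/component consistency, line/coords
consistency, well-formed hex colors) rather than fetching the DTD, so
builds are hermetic. Violations are returned as records; the writer and
graph builder refuse invalid pathways before producing output.

### Graph construction

One node per non-line entry, keyed `entry:<id>`. Four edge constructions:

* **Relations** become one directed edge each, labeled
  `<type>:<subtypes>`. A `compound` subtype is annotated on the edge
  (`via_compound_id`) rather than rerouting through the compound node:
  this keeps the drawn relation count stable and leaves rerouting to
  exporters if ever needed.
* **Reactions** become substrate→enzyme and enzyme→product edges, so
  enzyme boxes mediate compound connectivity as they do on the map.
  Reversible reactions flag their edges `reversible` instead of
  duplicating reciprocal edges, preserving the diagram's edge count.
* **Groups** become an explicit node plus `contains` edges to members —
  simple and round-trippable; metanode collapse is viewer-specific.
* **Line graphics** (global/Atlas-style maps draw reactions as colored
  polylines) expand into chains of anchor nodes (3 px circles, invisible
  joints) with `segment` edges inheriting the line color and the entry's
  KEGG ids, so overlays can still address the reaction.

These rules give exact count identities used throughout the tests: nodes
= non-line entries + Σ coordinate pairs; edges = relations +
Σ(substrates + products) + Σ group sizes + Σ(pairs − 1).

### Visual style

A style is a set of default visual properties plus mapping functions
(passthrough, discrete, continuous) from data attributes to visual
properties — the same separation interactive network tools use, which is
what makes the omics overlay a style swap rather than a graph rewrite.
The synthesized base style binds `bg_color`→fill, `fg_color`→border and
label color, graphics size→node size, and a fixed shape table
(rectangle→rectangle, roundrectangle→round-rectangle, circle→ellipse).
Where an entry's type and its graphics shape disagree, the graphics shape
wins: the drawn form is the authority on appearance. Font size is fixed
at 11 px since KGML carries no font information.

Continuous color mappings interpolate linearly per 8-bit sRGB channel,
rounding half-up, and clamp outside the anchor range (a p-value beyond
the cutoff must saturate at white, not extrapolate). Resolution is total:
every property of every element resolves to the mapped value when the
source attribute is present, otherwise to the default; the resolved table
carries the union of node and edge properties so it contains no missing
cells, with inapplicable cells holding defaults and edge positions set to
segment midpoints.

## Omics overlay

The overlay stage reproduces a standard microarray workflow: a per-row
two-sample t-test between two groups of chips, a key column of KEGG gene
ids appended to the statistics table via an annotation mapping, fuzzy
matching of single-id rows against multi-id nodes, per-node aggregation,
and a recolored style.

* **t-test**: equal-variance two-sample test per row, p two-sided from
  the t distribution with n₁+n₂−2 degrees of freedom (Welch optional).
  Rows with zero pooled variance get a missing p with a warning rather
  than a fake value. No multiple-testing correction is applied by
  default; Benjamini–Hochberg is available as an option.
* **Fuzzy matching**: a row matches a node iff its key is a member of the
  node's id list (exact string equality per id). A row may match several
  nodes — diagrams intentionally repeat enzymes — and a node several
  rows.
* **Aggregation**: default `min` (a node is flagged when *any* member
  gene passes the cutoff, matching the convention that a colored box
  "includes" a differentially expressed gene); `mean` and Fisher's
  combined p (−2Σln p against χ² with 2k df) are alternatives. Nodes with
  no usable rows are absent from the result, not zero: missing statistics
  render as unmatched, never as white-significant.
* **Recoloring**: matched nodes move their original diagram fill to the
  border and take a red→white gradient fill in the aggregated statistic
  (`#FF0000` at p = 0, `#FFFFFF` at p ≥ threshold, default threshold
  0.05); unmatched KO (KEGG Orthology) annotated nodes get a `#00FF00`
  border; everything else keeps the base style. The overlay annotates
  nodes with an `overlay_p` attribute and swaps mappings; node and edge
  sets are never altered.

Parameters that matter: `threshold` (significance cutoff on the
aggregated statistic, default 0.05), `method` (`min`/`mean`/`fisher`,
default `min`), `welch` and `bh_correction` (both off by default).

## Synthetic data

Three generators emit valid KGML with a ground-truth record
(`FixtureTruth`) of exactly what was planted; organism code `syn` marks
everything as synthetic, and no real biochemistry is imitated —
the fixtures are structural stand-ins.

* *Metabolic*: enzyme boxes (1–3 gene ids each, 46×17 px) and compound
  circles on a 92×46 px grid, wired by reactions (1–2 substrates and
  products each, mixed reversible/irreversible) and ECrel relations with
  compound subtypes. Defaults: 5 enzymes, 6 compounds, 5 reactions, 3
  relations.
* *Signaling*: gene boxes, PPrel/GErel relations with
  activation/inhibition/expression-style subtypes, at least one group
  entry with components, a round-rectangle linked-map box and one maplink
  relation.
* *Global map*: line entries with 2–8 coordinate pairs and per-line
  random colors, endpoints anchored at compound circles.

Colors are random hex with mixed-case digits so round-trip tests exercise
byte-for-byte case preservation. One seed drives topology, layout and
colors; identical parameters and seed give identical bytes.

The expression generator emulates a four-vs-four chip design: unit-variance
Gaussian noise over 1000 probeset-style rows, with ⌈5%⌉ of rows shifted by
5σ in the treatment group. The id mapping covers `mapping_coverage` of the
rows with KEGG ids drawn from the pathway's gene nodes, planted rows
mapped first; coverage defaults to the planted fraction. The rationale:
a genome-scale chip measures far more genes than one map contains, so the
rows mapped onto a single pathway are its member genes — in the recovery
scenario those are exactly the perturbed rows, which makes
"flagged nodes = nodes holding planted genes" the correct expectation. If
unperturbed genes were also mapped onto the map, each would false-flag its
node at rate α and exact recovery would not be a meaningful target. What
passing therefore shows: the pipeline finds everything planted and adds
nothing, *given* a correct annotation mapping. What it does not show:
behavior under annotation errors, correlated noise, batch effects or
non-Gaussian intensity distributions, none of which the generator
emulates.

## Numerical choices

* Gradient and all continuous color blends: per-channel linear
  interpolation in 8-bit sRGB with half-up rounding
  (`floor(x + 0.5)`), so `gradient_color(0.025, 0.05) = #FF8080` exactly.
* The t-test delegates to a standard statistics library; the test suite
  checks it against a direct closed-form evaluation (pooled variance plus
  t survival function) to 1e-12 and calibrates the null rejection rate
  against a 99% binomial interval at α = 0.05.
* Fisher aggregation clips p at 1e-300 before the log to avoid −inf.
* Ordering is deterministic everywhere (entries by id, anchors by
  coordinate order, edges grouped by construction rule), so repeated runs
  are byte-identical.

## Known limitations

* Hand-drawn compartment and background artwork is not encoded in KGML at
  all, so it cannot be reproduced here (or by any KGML consumer); the
  rendered diagram shows only the encoded elements.
* SIF carries no attributes; the sidecar TSV is the honest workaround.
* The SVG renderer draws boxes, ellipses, polylines and centered labels;
  it does not attempt arrowheads or edge routing between boxes.
* Validation is against the modeled invariant set, not the full DTD; the
  unmodeled parts of a document survive in `extras` but are not checked.
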