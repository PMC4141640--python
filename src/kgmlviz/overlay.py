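"""Overlay per-gene statistics onto pathway nodes.

The workflow: compute per-row two-sample t-tests on an expression matrix
(mutant vs control groups), append a KEGG gene-id key column via an
annotation mapping, fuzzily match keys against each node's id *list* (set
membership, since one enzyme box carries several gene ids and one gene can
sit in several boxes), aggregate multi-gene nodes to a single statistic,
and re-style the diagram: the original node fill moves to the border, the
fill becomes a red-to-white gradient in the p-value, and orthology (KO)
annotated nodes that carry no data get a green border.

Nodes with no matched rows keep the base style: absence of evidence is
rendered as absence, never as a white "non-significant" fill.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph import PathwayGraph
from .style import MappingFunction, VisualStyle, interpolate_color

__all__ = [
    "OmicsTable",
    "OverlayResult",
    "row_ttest",
    "append_key_column",
    "match_keys",
    "aggregate",
    "gradient_color",
    "compute_overlay",
    "overlay_style",
    "read_omics_table",
    "read_mapping",
    "matrix_p_values",
]

DEFAULT_THRESHOLD = 0.05
KO_BORDER_COLOR = "#00FF00"
SIGNIFICANT_COLOR = "#FF0000"
NONSIGNIFICANT_COLOR = "#FFFFFF"


@dataclass
class OmicsTable:
    """Keyed per-gene statistics (or a raw expression matrix).

    ``row_ids`` are probeset/gene identifiers; ``key_column`` (when
    present) aligns a KEGG gene id to each row, empty string for unmapped
    rows; ``columns`` holds named numeric vectors such as ``p_value``;
    ``group_labels`` labels samples when the table is a raw matrix.
    """

    row_ids: list[str]
    columns: dict[str, np.ndarray] = field(default_factory=dict)
    key_column: list[str] | None = None
    matrix: pd.DataFrame | None = None
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.row_ids)
        for name, col in self.columns.items():
            if len(col) != n:
                raise ValueError(f"column {name!r} length != row count")
        if self.key_column is not None and len(self.key_column) != n:
            raise ValueError("key_column length != row count")


@dataclass
class OverlayResult:
    node_values: dict[str, float]
    node_hits: dict[str, list[str]]
    flagged: set[str]
    threshold: float = DEFAULT_THRESHOLD


def row_ttest(
    matrix: pd.DataFrame | np.ndarray,
    group_labels: Sequence[str],
    welch: bool = False,
) -> np.ndarray:
    """Per-row two-sample t-test p-values (two-sided).

    Equal-variance by default (p from the t distribution with n1+n2-2
    degrees of freedom); ``welch=True`` drops the equal-variance
    assumption.  Rows with zero pooled variance get NaN with a warning.
    """
    values = np.asarray(matrix, dtype=float)
    labels = np.asarray(group_labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {len(levels)}")
    a = values[:, labels == levels[0]]
    b = values[:, labels == levels[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # near-constant rows are handled below via the NaN path
        warnings.filterwarnings(
            "ignore", message="Precision loss occurred",
            category=RuntimeWarning,
        )
        result = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    p = np.asarray(result.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} row(s) with zero pooled variance; "
            "p recorded as missing",
            RuntimeWarning,
            stacklevel=2,
        )
    return p


def append_key_column(
    table: OmicsTable, mapping: Mapping[str, str]
) -> tuple[OmicsTable, dict[str, int]]:
    """Attach KEGG gene-id keys to rows covered by the mapping.

    Uncovered rows get an empty key; the returned report counts mapped and
    unmapped rows (coverage is reported, never fatal).
    """
    keys = [mapping.get(rid, "") for rid in table.row_ids]
    mapped = sum(1 for k in keys if k)
    out = OmicsTable(
        row_ids=list(table.row_ids),
        columns=dict(table.columns),
        key_column=keys,
        matrix=table.matrix,
        group_labels=table.group_labels,
    )
    report = {"mapped": mapped, "unmapped": len(keys) - mapped}
    return out, report


def match_keys(
    graph: PathwayGraph, table: OmicsTable
) -> dict[str, list[int]]:
    """Fuzzy key matching: row i matches node n iff key i is in n.names.

    Membership is exact string equality per id against the node's id list;
    a row may match several nodes (repeated enzyme boxes) and a node may
    match several rows (multi-gene boxes).  Only nodes with at least one
    match appear in the result.
    """
    if table.key_column is None:
        raise ValueError("table has no key column; run append_key_column")
    by_key: dict[str, list[int]] = {}
    for i, key in enumerate(table.key_column):
        if key:
            by_key.setdefault(key, []).append(i)
    matches: dict[str, list[int]] = {}
    for node in graph.nodes:
        hit_rows: list[int] = []
        for name in node.names:
            hit_rows.extend(by_key.get(name, ()))
        if hit_rows:
            matches[node.node_key] = sorted(set(hit_rows))
    return matches


def aggregate(
    node_matches: Mapping[str, Iterable[int]],
    values: Sequence[float] | np.ndarray,
    method: str = "min",
) -> dict[str, float]:
    """Summarize matched per-row statistics to one value per node.

    ``min`` (default) flags a node if any member gene passes; ``mean`` is
    the arithmetic mean; ``fisher`` combines p-values via -2*sum(ln p)
    against chi-square with 2k degrees of freedom.  Rows with missing
    values are dropped; a node with no usable rows is absent from the
    result (not zero).
    """
    if method not in ("min", "mean", "fisher"):
        raise ValueError(f"unknown aggregation method {method!r}")
    values = np.asarray(values, dtype=float)
    out: dict[str, float] = {}
    for key, rows in node_matches.items():
        p = values[list(rows)]
        p = p[~np.isnan(p)]
        if p.size == 0:
            continue
        if method == "min":
            out[key] = float(p.min())
        elif method == "mean":
            out[key] = float(p.mean())
        else:
            statistic = -2.0 * np.log(np.clip(p, 1e-300, None)).sum()
            out[key] = float(stats.chi2.sf(statistic, 2 * p.size))
    return out


def gradient_color(p: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Red-to-white fill for a statistic: 0 -> #FF0000, >= cutoff -> #FFFFFF.

    Channels interpolate linearly with half-up rounding, clamped at the
    endpoints.
    """
    if p < 0 or math.isnan(p):
        raise ValueError(f"statistic must be >= 0, got {p}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = min(p / threshold, 1.0)
    return interpolate_color(SIGNIFICANT_COLOR, NONSIGNIFICANT_COLOR, t)


def compute_overlay(
    graph: PathwayGraph,
    table: OmicsTable,
    statistic_column: str = "p_value",
    method: str = "min",
    threshold: float = DEFAULT_THRESHOLD,
    bh_correction: bool = False,
) -> OverlayResult:
    """Match, aggregate and flag: the complete node-statistics pass."""
    if statistic_column not in table.columns:
        raise KeyError(f"table has no column {statistic_column!r}")
    values = np.asarray(table.columns[statistic_column], dtype=float)
    if bh_correction:
        values = _benjamini_hochberg(values)
    matches = match_keys(graph, table)
    node_values = aggregate(matches, values, method=method)
    node_hits = {
        key: [table.row_ids[i] for i in rows]
        for key, rows in matches.items()
    }
    flagged = {k for k, v in node_values.items() if v < threshold}
    return OverlayResult(
        node_values=node_values,
        node_hits=node_hits,
        flagged=flagged,
        threshold=threshold,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaN entries stay NaN."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(ranked, 0, 1)
    q[ok] = adj
    return q


def overlay_style(
    style: VisualStyle,
    graph: PathwayGraph,
    result: OverlayResult,
) -> VisualStyle:
    """Re-style the diagram around an overlay result.

    Matched nodes take their original fill as border color and a
    red-to-white gradient fill in the aggregated statistic; unmatched nodes
    keep the base style except that KO-annotated ones get a green border.
    The aggregated statistic is attached to each matched node as the
    ``overlay_p`` attribute; node and edge sets are untouched.
    """
    new_style = style.copy()
    if not result.node_values:
        return new_style

    border_table: dict[str, str] = {}
    for node in graph.nodes:
        if node.node_key in result.node_values:
            border_table[node.node_key] = node.bg_color
        elif node.is_ko_annotated:
            border_table[node.node_key] = KO_BORDER_COLOR
        node.attrs.pop("overlay_p", None)
    for key, value in result.node_values.items():
        graph.node_by_key(key).attrs["overlay_p"] = value

    # The continuous fill mapping must outrank the diagram's bg_color
    # passthrough; remove fill/border passthroughs so overlay wins where it
    # applies (unmatched nodes still resolve via the discrete border table
    # or the passthroughs appended after).
    new_style.mappings = [
        m for m in new_style.mappings
        if not (m.element == "node" and m.target in ("fill", "border_color")
                and m.kind == "passthrough")
    ]
    new_style.mappings.append(
        MappingFunction("bg_color", "fill")
    )
    new_style.mappings.append(
        MappingFunction(
            "overlay_p", "fill", kind="continuous",
            anchors=[(0.0, SIGNIFICANT_COLOR),
                     (result.threshold, NONSIGNIFICANT_COLOR)],
        )
    )
    new_style.mappings.append(MappingFunction("fg_color", "border_color"))
    new_style.mappings.append(
        MappingFunction(
            "node_key", "border_color", kind="discrete", table=border_table
        )
    )
    return new_style


def read_omics_table(path: str, key_column: str | None = None) -> OmicsTable:
    """Load a delimited statistics table (TSV/CSV by extension).

    The first column holds row ids; remaining numeric columns become
    statistic vectors; ``key_column`` names a column of KEGG gene ids.
    """
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    row_ids = df.iloc[:, 0].astype(str).tolist()
    keys = None
    if key_column is not None:
        keys = df[key_column].fillna("").astype(str).tolist()
    columns = {
        name: df[name].to_numpy(dtype=float)
        for name in df.columns[1:]
        if name != key_column and pd.api.types.is_numeric_dtype(df[name])
    }
    return OmicsTable(row_ids=row_ids, columns=columns, key_column=keys)


def matrix_p_values(path: str, welch: bool = False) -> OmicsTable:
    """Read a raw expression matrix and compute per-row t-test p-values.

    The first column holds row ids; sample columns starting with ``ctl``
    form the control group, everything else the treatment group.
    """
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    labels = ["ctl" if c.startswith("ctl") else "mut" for c in df.columns]
    p = row_ttest(df.to_numpy(dtype=float), labels, welch=welch)
    return OmicsTable(
        row_ids=[str(r) for r in df.index],
        columns={"p_value": p},
        matrix=df,
        group_labels=labels,
    )


def read_mapping(path: str) -> dict[str, str]:
    """Load a two-column (row_id, kegg_id) delimited mapping table."""
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, header=0)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
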