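"""Omics overlay: t-tests, key matching, aggregation, gradient, restyle."""

import math

import numpy as np
import pytest
from scipy import stats

from kgmlviz import (
    GeneratorParams,
    OmicsTable,
    aggregate,
    append_key_column,
    apply_style,
    build_graph,
    compute_overlay,
    gradient_color,
    make_expression_fixture,
    make_metabolic_kgml,
    match_keys,
    overlay_style,
    parse_kgml,
    row_ttest,
    style_from_graph,
)
from kgmlviz.overlay import KO_BORDER_COLOR


def pooled_ttest_oracle(a, b):
    """Direct closed-form evaluation: pooled variance + t CDF."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    m1, m2 = a.mean(), b.mean()
    ss1 = ((a - m1) ** 2).sum()
    ss2 = ((b - m2) ** 2).sum()
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2 * stats.t.sf(abs(t), df)


class TestRowTtest:
    def test_identical_groups_give_p_one(self):
        matrix = np.array([[1.0, 2, 3, 1, 2, 3]])
        p = row_ttest(matrix, ["a", "a", "a", "b", "b", "b"])
        assert p[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("row", [
        [0, 0, 1, 1, 10, 10, 11, 11],
        [0.3, -1.2, 0.7, 0.1, 0.4, -0.5, 1.1, 0.0],
        [5, 5, 5, 6, 5, 5, 5, 5],
    ])
    def test_matches_closed_form(self, row):
        labels = ["a"] * 4 + ["b"] * 4
        p = row_ttest(np.array([row], float), labels)
        expected = pooled_ttest_oracle(row[:4], row[4:])
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(2024)
        matrix = rng.normal(size=(1000, 8))
        p = row_ttest(matrix, ["a"] * 4 + ["b"] * 4)
        rate = float((p < 0.05).mean())
        # 99% binomial interval around alpha = 0.05 at n = 1000
        lo = stats.binom.ppf(0.005, 1000, 0.05) / 1000
        hi = stats.binom.ppf(0.995, 1000, 0.05) / 1000
        assert lo <= rate <= hi

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            row_ttest(np.zeros((3, 3)), ["a", "b", "b"])

    def test_zero_variance_row_warns_and_is_missing(self):
        matrix = np.array([[1.0, 1, 1, 1, 1, 1, 1, 1],
                           [0.0, 1, 2, 3, 4, 5, 6, 7]])
        with pytest.warns(RuntimeWarning, match="zero pooled variance"):
            p = row_ttest(matrix, ["a"] * 4 + ["b"] * 4)
        assert np.isnan(p[0]) and not np.isnan(p[1])

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(5)
        row = np.concatenate([rng.normal(0, 0.1, 4), rng.normal(1, 5, 4)])
        labels = ["a"] * 4 + ["b"] * 4
        p_pooled = row_ttest(row[None, :], labels)[0]
        p_welch = row_ttest(row[None, :], labels, welch=True)[0]
        assert p_pooled != pytest.approx(p_welch)


class TestKeyColumn:
    def test_coverage_reported(self):
        table = OmicsTable(row_ids=["a", "b", "c"],
                           columns={"p_value": np.array([0.1, 0.2, 0.3])})
        out, report = append_key_column(table, {"a": "syn:b1", "c": "syn:b2"})
        assert out.key_column == ["syn:b1", "", "syn:b2"]
        assert report == {"mapped": 2, "unmapped": 1}

    def test_empty_mapping(self):
        table = OmicsTable(row_ids=["a", "b"],
                           columns={"p_value": np.array([0.1, 0.2])})
        out, report = append_key_column(table, {})
        assert out.key_column == ["", ""]
        assert report["mapped"] == 0


class TestMatchKeys:
    def test_membership_and_miss(self, metabolic_graph):
        g, _ = metabolic_graph
        gene_node = next(n for n in g.nodes if n.entry_type == "gene")
        table = OmicsTable(
            row_ids=["r1", "r2"],
            columns={"p_value": np.array([0.01, 0.5])},
            key_column=[gene_node.names[0], "syn:b9999"],
        )
        matches = match_keys(g, table)
        assert matches[gene_node.node_key] == [0]
        assert all(0 not in rows or key == gene_node.node_key
                   for key, rows in matches.items())
        assert not any(1 in rows for rows in matches.values())

    def test_requires_key_column(self, metabolic_graph):
        g, _ = metabolic_graph
        table = OmicsTable(row_ids=["a"], columns={"p": np.array([0.5])})
        with pytest.raises(ValueError, match="key column"):
            match_keys(g, table)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_nested_loop(self, seed):
        text, _ = make_metabolic_kgml(GeneratorParams(seed=seed))
        g = build_graph(parse_kgml(text))
        matrix, mapping, _ = make_expression_fixture(
            g, n_genes=60, seed=seed, mapping_coverage=0.5
        )
        keys = [mapping.get(r, "") for r in matrix.index]
        table = OmicsTable(
            row_ids=list(matrix.index),
            columns={"p_value": np.zeros(len(matrix))},
            key_column=keys,
        )
        expected = {}
        for node in g.nodes:  # brute-force double loop
            for i, key in enumerate(keys):
                if key and key in node.names:
                    expected.setdefault(node.node_key, []).append(i)
        assert match_keys(g, table) == expected


class TestAggregate:
    def test_min_mean(self):
        values = np.array([0.01, 0.2, 0.4])
        assert aggregate({"n": [0, 1]}, values)["n"] == pytest.approx(0.01)
        assert aggregate({"n": [1, 2]}, values, "mean")["n"] == \
            pytest.approx(0.3)

    def test_fisher_equals_chi2_survival(self):
        values = np.array([0.05, 0.05])
        out = aggregate({"n": [0, 1]}, values, "fisher")
        expected = stats.chi2.sf(-2 * (math.log(0.05) + math.log(0.05)), 4)
        assert out["n"] == pytest.approx(expected, rel=1e-12)

    def test_empty_and_all_missing_nodes_absent(self):
        values = np.array([np.nan, 0.5])
        out = aggregate({"a": [0], "b": [1]}, values)
        assert "a" not in out and out["b"] == 0.5

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            aggregate({}, np.array([]), "median")


class TestGradient:
    def test_endpoints(self):
        assert gradient_color(0.0, 0.05) == "#FF0000"
        assert gradient_color(0.05, 0.05) == "#FFFFFF"
        assert gradient_color(0.9, 0.05) == "#FFFFFF"

    def test_midpoint_half_up(self):
        assert gradient_color(0.025, 0.05) == "#FF8080"

    def test_monotone_redness(self):
        ps = np.linspace(0, 0.08, 200)
        redness = [255 - int(gradient_color(p, 0.05)[3:5], 16) for p in ps]
        assert all(a >= b for a, b in zip(redness, redness[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gradient_color(-0.1, 0.05)
        with pytest.raises(ValueError):
            gradient_color(0.1, 0.0)


class TestOverlay:
    def _fixture(self, seed=0, effect=5.0):
        text, _ = make_metabolic_kgml(GeneratorParams(seed=seed))
        g = build_graph(parse_kgml(text))
        matrix, mapping, truth = make_expression_fixture(
            g, n_genes=400, effect_size=effect, seed=seed
        )
        p = row_ttest(matrix.to_numpy(),
                      ["ctl" if c.startswith("ctl") else "mut"
                       for c in matrix.columns])
        table = OmicsTable(row_ids=list(matrix.index),
                           columns={"p_value": p})
        table, _ = append_key_column(table, mapping)
        return g, table, truth

    def test_flagged_equals_min_p_rule(self):
        g, table, _ = self._fixture(seed=1)
        result = compute_overlay(g, table)
        values = table.columns["p_value"]
        matches = match_keys(g, table)
        expected = {
            key for key, rows in matches.items()
            if np.nanmin(values[rows]) < result.threshold
        }
        assert result.flagged == expected
        assert result.flagged <= set(result.node_values)

    def test_planted_nodes_recovered(self):
        g, table, truth = self._fixture(seed=2)
        result = compute_overlay(g, table)
        assert result.flagged == truth.planted_node_keys

    def test_hits_belong_to_node_names(self):
        g, table, _ = self._fixture(seed=3)
        result = compute_overlay(g, table)
        key_of = dict(zip(table.row_ids, table.key_column))
        for node_key, hits in result.node_hits.items():
            names = set(g.node_by_key(node_key).names)
            assert all(key_of[h] in names for h in hits)

    def test_overlay_style_border_and_fill(self):
        g, table, _ = self._fixture(seed=4)
        base = style_from_graph(g)
        result = compute_overlay(g, table)
        styled = overlay_style(base, g, result)
        resolved = apply_style(g, styled)
        for node in g.nodes:
            row = resolved.loc[node.node_key]
            if node.node_key in result.node_values:
                assert row["border_color"] == node.bg_color
                assert row["fill"] == gradient_color(
                    result.node_values[node.node_key], result.threshold
                )
            elif node.is_ko_annotated:
                assert row["border_color"] == KO_BORDER_COLOR
                assert row["fill"] == node.bg_color
            else:
                assert row["border_color"] == node.fg_color
                assert row["fill"] == node.bg_color

    def test_empty_result_is_noop(self, metabolic_graph):
        g, _ = metabolic_graph
        base = style_from_graph(g)
        from kgmlviz import OverlayResult

        styled = overlay_style(base, g, OverlayResult({}, {}, set()))
        assert styled == base

    def test_topology_unchanged(self):
        g, table, _ = self._fixture(seed=5)
        nodes_before = [n.node_key for n in g.nodes]
        edges_before = [(e.source_key, e.target_key) for e in g.edges]
        result = compute_overlay(g, table)
        overlay_style(style_from_graph(g), g, result)
        assert [n.node_key for n in g.nodes] == nodes_before
        assert [(e.source_key, e.target_key) for e in g.edges] == edges_before
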