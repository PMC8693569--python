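import itertools
import json
from math import comb

import numpy as np
import pandas as pd
import pytest

import seqdash
from seqdash import (
    SelectionState,
    ValidationError,
    WidgetDoc,
    apply_event,
    build_mds_widget,
    build_summary_widget,
    validate_doc,
)
from seqdash.widget_spec import MAX_SHAPE_CATEGORIES

GENES = ("g1", "g2", "g3")


def _control(doc, name):
    for ctrl in doc.controls:
        if ctrl["name"] == name:
            return ctrl
    raise AssertionError(f"control {name} not found")


class TestSelectionMachine:
    def test_click_enters_graph_select_and_filters_table(self):
        state, directives = apply_event(SelectionState(), ("point_click", "g1"), GENES)
        assert state.mode == "GRAPH_SELECT"
        assert state.selected == ("g1",)
        assert directives["table"] == "selection"
        assert directives["expression_gene"] == "g1"

    def test_double_click_is_identity(self):
        s0 = SelectionState()
        s1, _ = apply_event(s0, ("point_click", "g1"), GENES)
        s2, directives = apply_event(s1, ("point_click", "g1"), GENES)
        assert s2 == s0
        assert directives["table"] == "full"

    def test_remove_middle_keeps_recency(self):
        state = SelectionState()
        for g in ("g1", "g2", "g3"):
            state, _ = apply_event(state, ("point_click", g), GENES)
        state, directives = apply_event(state, ("point_click", "g2"), GENES)
        assert state.selected == ("g1", "g3")
        assert state.last_selected == "g3"
        assert directives["expression_gene"] == "g3"

    def test_row_and_point_clicks_share_semantics(self):
        via_point, _ = apply_event(SelectionState(), ("point_click", "g2"), GENES)
        via_row, _ = apply_event(SelectionState(), ("row_click", "g2"), GENES)
        assert via_point == via_row

    def test_search_is_orthogonal(self):
        state, _ = apply_event(SelectionState(), ("point_click", "g1"), GENES)
        state, directives = apply_event(state, ("search", "kinase"), GENES)
        assert state.selected == ("g1",)
        assert directives["table_search"] == "kinase"

    def test_clear_returns_to_idle(self):
        state, _ = apply_event(SelectionState(), ("point_click", "g1"), GENES)
        state, directives = apply_event(state, ("clear",), GENES)
        assert state.mode == "IDLE" and state.selected == ()
        assert directives["table"] == "full"
        assert directives["expression_gene"] is None

    def test_unknown_gene_rejected_state_unchanged(self):
        state = SelectionState()
        with pytest.raises(ValidationError, match="unknown gene"):
            apply_event(state, ("point_click", "nope"), GENES)
        assert state == SelectionState()

    def test_exhaustive_sequences_match_parity_oracle(self):
        """Every click sequence of length <= 4 over 3 genes yields the
        selection predicted by click-parity, and IDLE <=> empty throughout."""
        events = [("point_click", g) for g in GENES] + [
            ("row_click", g) for g in GENES
        ] + [("clear",), ("search", "x")]
        checked = 0
        for length in range(5):
            for seq in itertools.product(events, repeat=length):
                state = SelectionState()
                clicks: dict[str, int] = {}
                for ev in seq:
                    state, _ = apply_event(state, ev, GENES)
                    if ev[0] in ("point_click", "row_click"):
                        clicks[ev[1]] = clicks.get(ev[1], 0) + 1
                    elif ev[0] == "clear":
                        clicks = {}
                    expected = {g for g, c in clicks.items() if c % 2 == 1}
                    assert set(state.selected) == expected
                    assert (state.mode == "IDLE") == (len(state.selected) == 0)
                checked += 1
        assert checked == sum(len(events) ** k for k in range(5))


@pytest.fixture(scope="module")
def mds_nine():
    expr, _ = seqdash.simulate_counts(
        n_genes=200, groups=("basal", "LP", "ML"), samples_per_group=3,
        n_de=40, seed=12,
    )
    res = seqdash.run_mds(expr)
    return expr, res


class TestBuildMdsWidget:
    def test_dimension_dropdowns_list_all_pairs(self, mds_nine):
        expr, res = mds_nine
        doc = build_mds_widget(res, expr.sample_table)
        x_opts = _control(doc, "x_dim")["options"]
        y_opts = _control(doc, "y_dim")["options"]
        assert len(x_opts) == res.n_dims == len(y_opts)
        pairs = {frozenset(p) for p in itertools.product(x_opts, y_opts)
                 if len(frozenset(p)) == 2}
        assert len(pairs) == comb(res.n_dims, 2)

    def test_default_encodings_mirror_group_and_libsize(self, mds_nine):
        expr, res = mds_nine
        doc = build_mds_widget(
            res, expr.sample_table, colour_by="group", shape_by="group",
            size_by="library_size",
        )
        enc = doc.encodings["mds"]
        assert enc["colour"] == "group" and enc["shape"] == "group"
        assert enc["size"] == "library_size"
        assert enc["x"] == "dim1" and enc["y"] == "dim2"
        assert "variance_explained" in doc.data
        panels = {c["panel"] for c in doc.controls if c.get("action") == "save_plot"}
        assert panels == {"mds", "variance"}

    def test_numeric_covariate_excluded_from_shape(self, mds_nine):
        expr, res = mds_nine
        doc = build_mds_widget(res, expr.sample_table)
        assert "library_size" in _control(doc, "colour_by")["options"]
        assert "library_size" in _control(doc, "size_by")["options"]
        assert "library_size" not in _control(doc, "shape_by")["options"]

    def test_continuous_shape_rejected(self, mds_nine):
        expr, res = mds_nine
        with pytest.raises(ValidationError, match="discretize"):
            build_mds_widget(res, expr.sample_table, shape_by="library_size")

    def test_too_many_shape_categories_rejected(self, mds_nine):
        expr, res = mds_nine
        st = expr.sample_table.copy()
        st["many"] = [f"cat{i}" for i in range(len(st))]
        if len(st) > MAX_SHAPE_CATEGORIES:
            with pytest.raises(ValidationError, match="glyph"):
                build_mds_widget(res, st, shape_by="many")

    def test_continuous_colour_gets_continuous_schemes(self, mds_nine):
        expr, res = mds_nine
        doc = build_mds_widget(res, expr.sample_table, colour_by="library_size")
        assert "viridis" in _control(doc, "scheme")["options"]
        doc2 = build_mds_widget(res, expr.sample_table, colour_by="group")
        assert "category10" in _control(doc2, "scheme")["options"]

    def test_document_validates_and_round_trips(self, mds_nine):
        expr, res = mds_nine
        doc = build_mds_widget(res, expr.sample_table)
        validate_doc(doc)
        again = WidgetDoc.from_json(doc.to_json())
        assert again.to_json() == doc.to_json()


class TestBuildSummaryWidget:
    def test_volcano_y_is_neglog10_p(self, sim_data, sim_de):
        expr, _ = sim_data
        de = sim_de
        doc = build_summary_widget("volcano", de, expr, "group")
        row = doc.data["summary"][0]
        assert row["neg_log10_p"] == pytest.approx(
            -np.log10(de.table["p_value"].iloc[0])
        )
        assert doc.encodings["summary"]["x"] == "logfc"
        assert doc.encodings["summary"]["y"] == "neg_log10_p"

    def test_ma_axes_and_cardinality(self, sim_data, sim_de):
        expr, _ = sim_data
        doc = build_summary_widget("ma", sim_de, expr, "group")
        assert doc.encodings["summary"]["x"] == "ave_expr"
        assert doc.encodings["summary"]["y"] == "logfc"
        assert len(doc.data["summary"]) == expr.n_genes
        lc = doc.data["expression"]["logcpm"]
        assert len(lc) == expr.n_genes and len(lc[0]) == expr.n_samples

    def test_ma_and_volcano_share_expression_payload(self, sim_data, sim_de):
        expr, _ = sim_data
        ma = build_summary_widget("ma", sim_de, expr, "group")
        volcano = build_summary_widget("volcano", sim_de, expr, "group")
        assert ma.data["expression"] == volcano.data["expression"]

    def test_max_y_axis_literal_in_document(self, toy_expr, toy_de):
        doc = build_summary_widget("ma", toy_de, toy_expr, "group", max_y_axis=10)
        domain = doc.encodings["expression"]["config"]["y_domain"]
        assert domain[1] == 10
        assert domain[0] <= 0
        auto = build_summary_widget("ma", toy_de, toy_expr, "group")
        assert auto.encodings["expression"]["config"]["y_domain"] is None

    def test_tick_rotation_45_anticlockwise(self, toy_expr, toy_de):
        doc = build_summary_widget("ma", toy_de, toy_expr, "group")
        assert doc.encodings["expression"]["config"]["x_tick_rotation"] == -45

    def test_status_legend_and_labels(self, toy_expr, toy_de):
        doc = build_summary_widget(
            "ma", toy_de, toy_expr, "group", status=[1, -1, 0, 0, 0]
        )
        colours = doc.encodings["summary"]["config"]["status_colours"]
        assert set(colours) == {"-1", "0", "1"}
        assert doc.encodings["summary"]["label"] == "symbol"
        assert [r["status"] for r in doc.data["summary"]] == [1, -1, 0, 0, 0]

    def test_xy_requires_matching_lengths(self, toy_expr, toy_de):
        with pytest.raises(ValidationError, match="len\\(x\\)=3"):
            build_summary_widget(
                "xy", toy_de, toy_expr, "group", x=[1, 2, 3], y=[1, 2, 3, 4, 5]
            )

    def test_xy_uses_supplied_vectors(self, toy_expr, toy_de):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [5.0, 4.0, 3.0, 2.0, 1.0]
        doc = build_summary_widget(
            "xy", toy_de, toy_expr, "group", x=x, y=y,
            x_label="score_a", y_label="score_b",
        )
        assert doc.encodings["summary"]["x"] == "score_a"
        assert [r["score_a"] for r in doc.data["summary"]] == x

    def test_unknown_group_column_lists_available(self, toy_expr, toy_de):
        with pytest.raises(ValidationError, match="group"):
            build_summary_widget("ma", toy_de, toy_expr, "condition")

    def test_sample_colours_length_checked(self, toy_expr, toy_de):
        with pytest.raises(ValidationError, match="sample_colours"):
            build_summary_widget(
                "ma", toy_de, toy_expr, "group", sample_colours=["red"]
            )
        doc = build_summary_widget(
            "ma", toy_de, toy_expr, "group",
            sample_colours=["red", "green", "blue"],
        )
        assert doc.data["expression"]["sample_colours"] == ["red", "green", "blue"]

    def test_search_save_and_strip_controls_present(self, toy_expr, toy_de):
        doc = build_summary_widget("ma", toy_de, toy_expr, "group")
        names = {c["name"] for c in doc.controls}
        assert {"search", "save_summary_plot", "save_expression_plot",
                "save_data"} <= names
        assert _control(doc, "save_data")["scopes"] == ["selected", "all"]
        assert "selection_strip" in doc.interaction["links"]


class TestValidateDoc:
    def test_missing_encoding_field_rejected(self, toy_expr, toy_de):
        doc = build_summary_widget("ma", toy_de, toy_expr, "group")
        doc.encodings["summary"]["x"] = "not_a_field"
        with pytest.raises(ValidationError, match="not_a_field"):
            validate_doc(doc)

    def test_empty_dropdown_rejected(self, toy_expr, toy_de):
        doc = build_summary_widget("ma", toy_de, toy_expr, "group")
        doc.controls.append({"name": "broken", "type": "dropdown", "options": []})
        with pytest.raises(ValidationError, match="broken"):
            validate_doc(doc)

    def test_json_round_trip_lossless(self, toy_expr, toy_de):
        doc = build_summary_widget("volcano", toy_de, toy_expr, "group")
        assert json.loads(doc.to_json()) == doc.to_dict()
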