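"""Declarative widget documents and the linked-view interaction machine.

A :class:`WidgetDoc` is a self-contained description of one dashboard: the
embedded data tables, the field-to-channel encodings, the UI controls with
their option lists and defaults, and a reference to the interaction contract.
The HTML renderer consumes the document unchanged; everything the front end
needs is inside it.

The interaction contract itself is modelled by :class:`SelectionState` and
:func:`apply_event`: a two-mode machine (IDLE / GRAPH_SELECT) in which point
clicks and table-row clicks share one toggle semantic, search is an
orthogonal filter, and the view directives after any event sequence are fully
determined by the resulting state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    GENE_KEY,
    SAMPLE_KEY,
    DEResult,
    ExpressionData,
    ValidationError,
)
from .mds import MDSResult
from .stats import library_sizes, log_cpm, neglog10_p

__all__ = [
    "SCHEMA_VERSION",
    "WidgetDoc",
    "SelectionState",
    "validate_doc",
    "build_mds_widget",
    "build_summary_widget",
    "apply_event",
]

SCHEMA_VERSION = "seqdash-widget/1"

#: distinct glyphs the runtime guarantees for the shape channel
MAX_SHAPE_CATEGORIES = 8

#: built-in palettes recorded in meta for reproducibility
DEFAULT_DISCRETE_SCHEMES = ("category10", "accent", "dark2", "paired", "set2")
DEFAULT_CONTINUOUS_SCHEMES = ("viridis", "plasma", "inferno", "magma", "cividis")

STATUS_COLOURS = {"-1": "#1f77b4", "0": "#c8c8c8", "1": "#d62728"}

WIDGET_KINDS = ("mds", "ma", "volcano", "xy")


# ---------------------------------------------------------------------------
# document
# ---------------------------------------------------------------------------

@dataclass
class WidgetDoc:
    """Self-describing declarative widget document (JSON-serializable)."""

    kind: str
    data: dict
    encodings: dict
    controls: list
    interaction: dict
    meta: dict

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "data": self.data,
            "encodings": self.encodings,
            "controls": self.controls,
            "interaction": self.interaction,
            "meta": self.meta,
        }

    def to_json(self) -> str:
        # canonical form: sorted keys, no float NaN, compact separators
        return json.dumps(
            self.to_dict(), sort_keys=True, separators=(",", ":"), allow_nan=False
        )

    @classmethod
    def from_dict(cls, d: dict) -> "WidgetDoc":
        return cls(
            kind=d["kind"],
            data=d["data"],
            encodings=d["encodings"],
            controls=d["controls"],
            interaction=d["interaction"],
            meta=d["meta"],
        )

    @classmethod
    def from_json(cls, text: str) -> "WidgetDoc":
        return cls.from_dict(json.loads(text))


def _table_fields(table) -> set:
    if isinstance(table, list):
        fields: set = set()
        for row in table:
            fields.update(row)
        return fields
    if isinstance(table, dict):
        return set(table)
    raise ValidationError("embedded tables must be lists of records or dicts")


def validate_doc(doc: WidgetDoc) -> None:
    """Check a document's structural invariants; raises on violation.

    Invariants: known kind and schema version; every encoding field exists in
    the table its panel embeds; every control's option list is non-empty; the
    document survives a JSON round trip losslessly.
    """
    if doc.kind not in WIDGET_KINDS:
        raise ValidationError(f"unknown widget kind {doc.kind!r}")
    if doc.meta.get("schema") != SCHEMA_VERSION:
        raise ValidationError(
            f"document schema {doc.meta.get('schema')!r} != {SCHEMA_VERSION!r}"
        )
    for name in ("data", "encodings", "interaction", "meta"):
        if not isinstance(getattr(doc, name), dict):
            raise ValidationError(f"{name} must be a mapping")
    if not isinstance(doc.controls, list):
        raise ValidationError("controls must be a list")
    for panel, enc in doc.encodings.items():
        table_name = enc.get("table")
        if table_name not in doc.data:
            raise ValidationError(
                f"encodings for panel {panel!r} reference missing table {table_name!r}"
            )
        fields = _table_fields(doc.data[table_name])
        for channel, fname in enc.items():
            if channel in ("table", "config"):
                continue
            names = fname if isinstance(fname, list) else [fname]
            for nm in names:
                if nm is not None and nm not in fields:
                    raise ValidationError(
                        f"encoding {panel}.{channel} references missing field {nm!r}"
                    )
    for ctrl in doc.controls:
        if "name" not in ctrl or "type" not in ctrl:
            raise ValidationError("every control needs a name and a type")
        if ctrl["type"] == "dropdown":
            if not ctrl.get("options"):
                raise ValidationError(
                    f"dropdown {ctrl['name']!r} has an empty option list"
                )
    rt = WidgetDoc.from_json(doc.to_json())
    if rt.to_json() != doc.to_json():
        raise ValidationError("document does not survive a serialize/parse round trip")


# ---------------------------------------------------------------------------
# selection state machine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionState:
    """Current gene selection of a summary-expression dashboard.

    ``mode`` is IDLE exactly when the selection is empty; ``selected``
    preserves insertion order; ``last_selected`` is the most recently added
    still-selected gene; ``search_text`` filters the table orthogonally.
    """

    mode: str = "IDLE"
    selected: tuple = ()
    last_selected: str | None = None
    search_text: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("IDLE", "GRAPH_SELECT"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if (self.mode == "IDLE") != (len(self.selected) == 0):
            raise ValidationError("mode must be IDLE exactly when selection is empty")
        if self.selected and self.last_selected not in self.selected:
            raise ValidationError("last_selected must be a member of the selection")
        if not self.selected and self.last_selected is not None:
            raise ValidationError("last_selected must be None when selection is empty")


def apply_event(
    state: SelectionState, event: tuple, gene_universe
) -> tuple[SelectionState, dict]:
    """Apply one user event; returns the new state and view directives.

    Events: ``("point_click", g)`` and ``("row_click", g)`` toggle gene g's
    membership (one shared semantic for graph- and table-initiated
    selection); ``("search", text)`` sets the orthogonal search filter;
    ``("clear",)`` empties the selection.  Directives say what each linked
    view shows: the table is filtered to the selection while any gene is
    selected, otherwise it shows all (search-filtered) genes; the expression
    panel tracks the most recently selected gene.
    """
    universe = set(map(str, gene_universe))
    name = event[0]
    if name in ("point_click", "row_click"):
        g = str(event[1])
        if g not in universe:
            raise ValidationError(f"unknown gene id {g!r}")
        selected = list(state.selected)
        if g in selected:
            selected.remove(g)
        else:
            selected.append(g)
        last = selected[-1] if selected else None
        new = SelectionState(
            mode="GRAPH_SELECT" if selected else "IDLE",
            selected=tuple(selected),
            last_selected=last,
            search_text=state.search_text,
        )
    elif name == "search":
        new = replace(state, search_text=str(event[1]))
    elif name == "clear":
        new = SelectionState(search_text=state.search_text)
    else:
        raise ValidationError(f"unknown event {name!r}")
    directives = {
        "table": "selection" if new.mode == "GRAPH_SELECT" else "full",
        "table_search": new.search_text,
        "expression_gene": new.last_selected,
        "highlight": list(new.selected),
        "selection_strip": list(new.selected),
    }
    return new, directives


# ---------------------------------------------------------------------------
# covariate typing helpers
# ---------------------------------------------------------------------------

def _is_numeric(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(
        series
    )


def _records(df: pd.DataFrame) -> list:
    out = []
    for _, row in df.iterrows():
        rec = {}
        for k, v in row.items():
            if isinstance(v, (np.floating, float)):
                rec[k] = float(v)
            elif isinstance(v, (np.integer, int)):
                rec[k] = int(v)
            elif isinstance(v, np.bool_):
                rec[k] = bool(v)
            elif pd.isna(v):
                rec[k] = None  # missing annotation fields display as empty cells
            else:
                rec[k] = str(v)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# MDS widget
# ---------------------------------------------------------------------------

def build_mds_widget(
    mds: MDSResult,
    sample_table: pd.DataFrame,
    x_dim: int = 1,
    y_dim: int = 2,
    colour_by: str | None = None,
    shape_by: str | None = None,
    size_by: str = "library_size",
    scheme: str | None = None,
) -> WidgetDoc:
    """Build the MDS dashboard document.

    The samples table embeds every retained dimension plus all covariates
    (library size auto-added as ``library_size`` when absent), so the x/y
    dimension dropdowns can offer any pair of dimensions.  Colour and size
    accept any covariate; shape is restricted to discrete covariates.  A
    variance-explained bar series rides alongside, and each of the two panels
    gets its own save-plot control.
    """
    if SAMPLE_KEY not in sample_table.columns:
        raise ValidationError(f"sample table lacks key column {SAMPLE_KEY!r}")
    st = sample_table.copy()
    st[SAMPLE_KEY] = st[SAMPLE_KEY].astype(str)
    if list(st[SAMPLE_KEY]) != [str(s) for s in mds.sample_ids]:
        raise ValidationError("sample table order does not match MDS sample order")
    if "library_size" not in st.columns:
        lib = mds.params.get("library_sizes")
        if lib is not None:
            st["library_size"] = list(lib)
    covariates = [c for c in st.columns if c != SAMPLE_KEY]
    if not covariates:
        raise ValidationError("sample table needs at least one covariate column")
    discrete = [c for c in covariates if not _is_numeric(st[c])]
    numeric = [c for c in covariates if _is_numeric(st[c])]

    if colour_by is None:
        colour_by = covariates[0]
    for name, val in (("colour_by", colour_by), ("size_by", size_by)):
        if val is not None and val not in covariates:
            raise ValidationError(
                f"{name}={val!r} is not a covariate (have: {', '.join(covariates)})"
            )
    if shape_by is not None:
        if shape_by not in covariates:
            raise ValidationError(
                f"shape_by={shape_by!r} is not a covariate (have: {', '.join(covariates)})"
            )
        if shape_by in numeric:
            raise ValidationError(
                f"shape_by={shape_by!r} is continuous; discretize it first "
                "(shape requires a discrete covariate)"
            )
        n_cat = st[shape_by].nunique()
        if n_cat > MAX_SHAPE_CATEGORIES:
            raise ValidationError(
                f"shape_by={shape_by!r} has {n_cat} categories; the runtime "
                f"guarantees {MAX_SHAPE_CATEGORIES} distinct glyphs"
            )
    dims = list(range(1, mds.n_dims + 1))
    if x_dim not in dims or y_dim not in dims:
        raise ValidationError(
            f"requested dimensions ({x_dim}, {y_dim}) outside retained 1..{mds.n_dims}"
        )
    colour_is_numeric = colour_by in numeric
    if scheme is None:
        scheme = (
            DEFAULT_CONTINUOUS_SCHEMES[0] if colour_is_numeric
            else DEFAULT_DISCRETE_SCHEMES[0]
        )
    schemes = list(
        DEFAULT_CONTINUOUS_SCHEMES if colour_is_numeric else DEFAULT_DISCRETE_SCHEMES
    )
    if scheme not in schemes:
        raise ValidationError(f"unknown colour scheme {scheme!r} (have: {schemes})")

    samples = st.copy()
    for i, dim in enumerate(dims):
        samples[f"dim{dim}"] = mds.coordinates.iloc[:, i].to_numpy()
    data = {
        "samples": _records(samples),
        "variance_explained": [
            {"dimension": i + 1, "proportion": float(p)}
            for i, p in enumerate(mds.var_explained)
        ],
    }
    encodings = {
        "mds": {
            "table": "samples",
            "x": f"dim{x_dim}",
            "y": f"dim{y_dim}",
            "colour": colour_by,
            "shape": shape_by,
            "size": size_by,
            "tooltip": [SAMPLE_KEY] + covariates,
        },
        "variance": {
            "table": "variance_explained",
            "x": "dimension",
            "y": "proportion",
        },
    }
    dim_options = [f"dim{d}" for d in dims]
    controls = [
        {"name": "x_dim", "type": "dropdown", "options": dim_options,
         "default": f"dim{x_dim}", "target": "mds.x"},
        {"name": "y_dim", "type": "dropdown", "options": dim_options,
         "default": f"dim{y_dim}", "target": "mds.y"},
        {"name": "colour_by", "type": "dropdown", "options": covariates,
         "default": colour_by, "target": "mds.colour"},
        {"name": "shape_by", "type": "dropdown", "options": ["none"] + discrete,
         "default": shape_by if shape_by is not None else "none",
         "target": "mds.shape"},
        {"name": "size_by", "type": "dropdown", "options": ["none"] + covariates,
         "default": size_by if size_by is not None else "none",
         "target": "mds.size"},
        {"name": "scheme", "type": "dropdown", "options": schemes,
         "default": scheme, "target": "mds.colour_scheme"},
        {"name": "save_mds_plot", "type": "button", "action": "save_plot",
         "panel": "mds", "formats": ["png", "svg"]},
        {"name": "save_variance_plot", "type": "button", "action": "save_plot",
         "panel": "variance", "formats": ["png", "svg"]},
    ]
    doc = WidgetDoc(
        kind="mds",
        data=data,
        encodings=encodings,
        controls=controls,
        interaction={"machine": "none"},
        meta={
            "schema": SCHEMA_VERSION,
            "params": {
                "x_dim": x_dim,
                "y_dim": y_dim,
                "colour_by": colour_by,
                "shape_by": shape_by,
                "size_by": size_by,
                "scheme": scheme,
                "discrete_schemes": list(DEFAULT_DISCRETE_SCHEMES),
                "continuous_schemes": list(DEFAULT_CONTINUOUS_SCHEMES),
                **{k: v for k, v in mds.params.items() if k != "library_sizes"},
            },
        },
    )
    validate_doc(doc)
    return doc


# ---------------------------------------------------------------------------
# summary-expression widget
# ---------------------------------------------------------------------------

def build_summary_widget(
    kind: str,
    de: DEResult,
    expr: ExpressionData,
    group_col: str,
    status=None,
    sample_colours=None,
    max_y_axis: float | None = None,
    x=None,
    y=None,
    x_label: str | None = None,
    y_label: str | None = None,
    prior: float = 0.5,
) -> WidgetDoc:
    """Build an MA / volcano / XY summary-expression dashboard document.

    Layout: a gene-level summary scatter (MA: average log-CPM vs logFC;
    volcano: logFC vs -log10 p; XY: two caller-supplied vectors), a linked
    per-sample expression panel showing log-CPM of the selected gene
    stratified by ``group_col``, and a searchable statistics table.  The
    status vector drives the up/non-DE/down colour legend.  ``max_y_axis``
    fixes the expression panel's y maximum, overriding per-gene auto-scaling;
    ``sample_colours`` optionally colours expression points by a second
    factor.
    """
    if kind not in ("ma", "volcano", "xy"):
        raise ValidationError(f"unknown summary widget kind {kind!r}")
    de_ids = [str(g) for g in de.gene_ids]
    if de_ids != [str(g) for g in expr.gene_ids]:
        raise ValidationError("DE table and expression data are not aligned; use align()")
    if group_col not in expr.sample_table.columns:
        avail = [c for c in expr.sample_table.columns if c != SAMPLE_KEY]
        raise ValidationError(
            f"unknown group column {group_col!r} (available: {', '.join(avail)})"
        )
    n_genes, n_samples = expr.n_genes, expr.n_samples
    if status is None:
        status = np.zeros(n_genes, dtype=int)
    status = np.asarray(status, dtype=int)
    if status.shape != (n_genes,):
        raise ValidationError(f"status has length {status.size}, expected {n_genes}")
    if sample_colours is not None and len(sample_colours) != n_samples:
        raise ValidationError(
            f"sample_colours has length {len(sample_colours)}, expected {n_samples}"
        )

    if kind == "xy":
        if x is None or y is None:
            raise ValidationError("kind='xy' requires explicit x and y vectors")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != (n_genes,) or y.shape != (n_genes,):
            raise ValidationError(
                f"x/y vectors must match the number of genes: "
                f"got len(x)={x.size}, len(y)={y.size}, expected {n_genes}"
            )
        x_field = x_label or "x"
        y_field = y_label or "y"
    elif kind == "ma":
        x = de.table["ave_expr"].to_numpy(dtype=float)
        y = de.table["logfc"].to_numpy(dtype=float)
        x_field, y_field = "ave_expr", "logfc"
    else:  # volcano
        x = de.table["logfc"].to_numpy(dtype=float)
        y = neglog10_p(de.table["p_value"].to_numpy(dtype=float))
        x_field, y_field = "logfc", "neg_log10_p"

    lc = log_cpm(expr, prior=prior)
    summary = pd.concat(
        [
            expr.gene_table.reset_index(drop=True),
            de.table.drop(columns=[GENE_KEY]).reset_index(drop=True),
        ],
        axis=1,
    )
    summary["status"] = status
    if x_field not in summary.columns:
        summary[x_field] = x
    if y_field not in summary.columns:
        summary[y_field] = y
    summary_records = _records(summary)

    groups = [str(g) for g in expr.sample_table[group_col]]
    expression = {
        "samples": [str(s) for s in expr.sample_ids],
        "group": groups,
        "library_size": [float(v) for v in library_sizes(expr)],
        "logcpm": [[float(v) for v in row] for row in lc.to_numpy()],
    }
    if sample_colours is not None:
        expression["sample_colours"] = [str(c) for c in sample_colours]

    y_domain = (
        None
        if max_y_axis is None
        else [min(0.0, float(lc.to_numpy().min())), float(max_y_axis)]
    )
    encodings = {
        "summary": {
            "table": "summary",
            "x": x_field,
            "y": y_field,
            "colour": "status",
            "tooltip": [c for c in summary.columns],
            "label": _symbol_field(summary),
            "config": {"status_colours": dict(STATUS_COLOURS)},
        },
        "expression": {
            "table": "expression",
            "x": "group",
            "y": "logcpm",
            "tooltip": ["samples", "logcpm"],
            "config": {
                "x_tick_rotation": -45,  # 45 degrees anticlockwise
                "y_domain": y_domain,  # None -> auto-scale per gene
                "point_colours": "sample_colours" if sample_colours is not None else None,
            },
        },
    }
    controls = [
        {"name": "search", "type": "search", "target": "table",
         "placeholder": "search genes"},
        {"name": "save_summary_plot", "type": "button", "action": "save_plot",
         "panel": "summary", "formats": ["png", "svg"]},
        {"name": "save_expression_plot", "type": "button", "action": "save_plot",
         "panel": "expression", "formats": ["png", "svg"]},
        {"name": "save_data", "type": "button", "action": "save_data",
         "scopes": ["selected", "all"], "format": "csv"},
        {"name": "max_y_axis", "type": "numeric", "target": "expression.y_max",
         "default": max_y_axis},
        {"name": "clear", "type": "button", "action": "clear_selection"},
    ]
    interaction = {
        "machine": "selection/v1",
        "modes": ["IDLE", "GRAPH_SELECT"],
        "events": ["point_click", "row_click", "search", "clear"],
        "links": {
            "table": "filtered to selection in GRAPH_SELECT, full otherwise",
            "expression": "shows most recently selected gene",
            "selection_strip": "lists selected gene ids",
        },
    }
    doc = WidgetDoc(
        kind=kind,
        data={
            "summary": summary_records,
            "expression": expression,
            "table_schema": {"columns": [str(c) for c in summary.columns]},
        },
        encodings=encodings,
        controls=controls,
        interaction=interaction,
        meta={
            "schema": SCHEMA_VERSION,
            "params": {
                "group_col": group_col,
                "max_y_axis": max_y_axis,
                "prior": prior,
                "x_label": x_field,
                "y_label": y_field,
                "status_colours": dict(STATUS_COLOURS),
            },
        },
    )
    validate_doc(doc)
    return doc


def _symbol_field(summary: pd.DataFrame) -> str:
    # gene symbol labels above selected points, falling back to the id
    return "symbol" if "symbol" in summary.columns else GENE_KEY
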