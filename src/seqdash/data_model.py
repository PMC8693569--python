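"""Core data containers and tabular I/O.

The package's universal input is a gene x sample count matrix together with
a per-sample covariate table and a per-gene annotation table
(:class:`ExpressionData`), plus a per-gene table of differential-expression
summary statistics (:class:`DEResult`).  Counts are oriented genes-in-rows,
samples-in-columns; readers never guess the orientation.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ValidationError",
    "ExpressionData",
    "DEResult",
    "read_counts",
    "write_counts",
    "read_table",
    "attach_tables",
    "align",
    "export_csv",
]

SAMPLE_KEY = "sample_id"
GENE_KEY = "gene_id"

#: DE statistic columns in export order; the two optional ones are included
#: only when present.
STAT_COLUMNS = ("logfc", "ave_expr", "p_value", "adj_p", "status")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(names, what: str) -> None:
    seen: dict[str, int] = {}
    for n in names:
        seen[n] = seen.get(n, 0) + 1
    dups = sorted(n for n, c in seen.items() if c > 1)
    if dups:
        raise ValidationError(f"duplicate {what} name(s): {', '.join(map(str, dups))}")


@dataclass
class ExpressionData:
    """Counts plus aligned sample covariates and gene annotations.

    Parameters
    ----------
    counts
        Gene x sample matrix of non-negative finite values.  Index holds the
        gene ids, columns hold the sample ids.  Counts may be fractional
        (upstream quantifiers emit expected counts); non-negativity is the
        only value constraint.
    sample_table
        One row per sample, keyed by ``sample_id``, aligned to the columns of
        ``counts``.  Arbitrary extra covariate columns are carried through.
    gene_table
        One row per gene, keyed by ``gene_id``, aligned to the rows of
        ``counts``.
    """

    counts: pd.DataFrame
    sample_table: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    gene_table: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = self.counts
        if not isinstance(c, pd.DataFrame):
            c = pd.DataFrame(c)
            self.counts = c
        _check_unique(c.index, "gene")
        _check_unique(c.columns, "sample")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(c)
            raise ValidationError(
                f"non-numeric count {bad[2]!r} at gene {bad[0]!r}, sample {bad[1]!r}"
            )
        finite = np.isfinite(values)
        nonneg = values >= 0
        if not (finite & nonneg).all():
            gi, si = np.argwhere(~(finite & nonneg))[0]
            raise ValidationError(
                f"invalid count {values[gi, si]!r} at gene {c.index[gi]!r}, "
                f"sample {c.columns[si]!r} (counts must be finite and >= 0)"
            )
        if self.sample_table is None:
            self.sample_table = pd.DataFrame({SAMPLE_KEY: list(c.columns)})
        if self.gene_table is None:
            self.gene_table = pd.DataFrame({GENE_KEY: list(c.index)})
        _validate_aligned_table(self.sample_table, SAMPLE_KEY, list(c.columns), "sample")
        _validate_aligned_table(self.gene_table, GENE_KEY, list(c.index), "gene")

    @property
    def gene_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def _first_non_numeric(c: pd.DataFrame):
    for gid, row in c.iterrows():
        for sid, v in row.items():
            try:
                float(v)
            except (TypeError, ValueError):
                return gid, sid, v
    raise AssertionError("no non-numeric cell found")  # pragma: no cover


def _validate_aligned_table(table: pd.DataFrame, key: str, names: list, what: str) -> None:
    if key not in table.columns:
        raise ValidationError(f"{what} table lacks required key column {key!r}")
    got = list(table[key])
    _check_unique(got, what)
    if got != names:
        raise ValidationError(
            f"{what} table order does not match counts {what} order; "
            "use attach_tables() to align"
        )


@dataclass
class DEResult:
    """Per-gene differential-expression summary statistics.

    ``logfc`` is the log2 fold change, ``ave_expr`` the mean log-CPM,
    ``p_value`` the raw p-value; ``adj_p`` (adjusted p) and ``status``
    (-1 down / 0 not significant / 1 up) are optional.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in (GENE_KEY, "logfc", "ave_expr", "p_value"):
            if col not in t.columns:
                raise ValidationError(f"DE table lacks required column {col!r}")
        _check_unique(t[GENE_KEY], "gene")
        for col in ("logfc", "ave_expr", "p_value", "adj_p"):
            if col in t.columns and t[col].isna().any():
                gid = t.loc[t[col].isna(), GENE_KEY].iloc[0]
                raise ValidationError(f"missing {col} for gene {gid!r}")
        for col in ("p_value", "adj_p"):
            if col in t.columns:
                v = t[col].to_numpy(dtype=float)
                if ((v < 0) | (v > 1)).any():
                    gid = t.loc[(t[col] < 0) | (t[col] > 1), GENE_KEY].iloc[0]
                    raise ValidationError(f"{col} outside [0, 1] for gene {gid!r}")
        if "status" in t.columns:
            bad = ~t["status"].isin([-1, 0, 1])
            if bad.any():
                gid = t.loc[bad, GENE_KEY].iloc[0]
                raise ValidationError(
                    f"status for gene {gid!r} not in {{-1, 0, 1}}"
                )

    @property
    def gene_ids(self) -> list:
        return list(self.table[GENE_KEY])

    @property
    def stat_columns(self) -> list[str]:
        return [c for c in STAT_COLUMNS if c in self.table.columns]

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(
    path: str | os.PathLike,
    format: str = "tsv",
    *,
    row_names: str | os.PathLike | None = None,
    col_names: str | os.PathLike | None = None,
) -> ExpressionData:
    """Read a counts matrix into an :class:`ExpressionData` (counts only).

    ``format`` is one of ``tsv``/``csv`` (header row of sample names, first
    column of gene names) or ``mtx-triplet`` (MatrixMarket coordinate file
    with sidecar ``row_names``/``col_names`` text files, one name per line).
    Sample and gene tables attach separately via :func:`attach_tables`.
    """
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionData(counts=df)
    if format == "mtx-triplet":
        if row_names is None or col_names is None:
            raise ValidationError(
                "mtx-triplet format requires row_names and col_names sidecar files"
            )
        mat = scipy.io.mmread(os.fspath(path))
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        genes = _read_names(row_names)
        samples = _read_names(col_names)
        if dense.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"matrix shape {dense.shape} does not match "
                f"{len(genes)} row names x {len(samples)} column names"
            )
        return ExpressionData(counts=pd.DataFrame(dense, index=genes, columns=samples))
    raise ValidationError(f"unknown counts format {format!r}")


def _read_names(path: str | os.PathLike) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def write_counts(
    expr: ExpressionData,
    path: str | os.PathLike,
    format: str = "tsv",
    *,
    row_names: str | os.PathLike | None = None,
    col_names: str | os.PathLike | None = None,
) -> None:
    """Write counts in any dialect :func:`read_counts` accepts (round-trip safe)."""
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        expr.counts.to_csv(path, sep=sep)
        return
    if format == "mtx-triplet":
        if row_names is None or col_names is None:
            raise ValidationError(
                "mtx-triplet format requires row_names and col_names sidecar paths"
            )
        sparse = scipy.sparse.coo_matrix(expr.counts.to_numpy())
        scipy.io.mmwrite(os.fspath(path), sparse)
        for names, p in ((expr.gene_ids, row_names), (expr.sample_ids, col_names)):
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("\n".join(map(str, names)) + "\n")
        return
    raise ValidationError(f"unknown counts format {format!r}")


def read_table(path: str | os.PathLike, format: str | None = None) -> pd.DataFrame:
    """Read a sample/gene/DE table (TSV or CSV, inferred from extension)."""
    if format is None:
        format = "csv" if os.fspath(path).endswith(".csv") else "tsv"
    sep = "\t" if format == "tsv" else ","
    return pd.read_csv(path, sep=sep)


def read_de_table(path: str | os.PathLike, format: str | None = None) -> DEResult:
    return DEResult(read_table(path, format))


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def attach_tables(
    expr: ExpressionData,
    sample_table: pd.DataFrame | None = None,
    gene_table: pd.DataFrame | None = None,
) -> ExpressionData:
    """Attach covariate/annotation tables, reordered to the counts' order.

    Unmatched keys on either side are errors, never silent drops.  Passing
    ``None`` for a table leaves the existing one in place.
    """
    new_sample = expr.sample_table
    new_gene = expr.gene_table
    if sample_table is not None:
        new_sample = _reorder(sample_table, SAMPLE_KEY, expr.sample_ids, "sample")
    if gene_table is not None:
        new_gene = _reorder(gene_table, GENE_KEY, expr.gene_ids, "gene")
    return replace(expr, sample_table=new_sample, gene_table=new_gene)


def _reorder(table: pd.DataFrame, key: str, names: list, what: str) -> pd.DataFrame:
    if key not in table.columns:
        raise ValidationError(f"{what} table lacks required key column {key!r}")
    table = table.copy()
    table[key] = table[key].astype(str)
    names = [str(n) for n in names]
    _check_unique(table[key], what)
    have = set(table[key])
    want = set(names)
    missing = sorted(want - have)
    extra = sorted(have - want)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing from {what} table: {', '.join(missing)}")
        if extra:
            parts.append(f"not in counts: {', '.join(extra)}")
        raise ValidationError(f"{what} table key mismatch ({'; '.join(parts)})")
    return table.set_index(key).loc[names].reset_index()


@dataclass
class PairedData:
    """A :class:`DEResult` aligned gene-for-gene with an :class:`ExpressionData`."""

    de: DEResult
    expr: ExpressionData


def align(de: DEResult, expr: ExpressionData) -> PairedData:
    """Match DE statistics to expression data by gene id (expression order wins)."""
    de_ids = [str(g) for g in de.gene_ids]
    expr_ids = [str(g) for g in expr.gene_ids]
    de_set, expr_set = set(de_ids), set(expr_ids)
    missing_de = len(expr_set - de_set)
    missing_expr = len(de_set - expr_set)
    if missing_de or missing_expr:
        parts = []
        if missing_de:
            parts.append(
                f"{missing_de} gene{'s' if missing_de != 1 else ''} missing from DE table"
            )
        if missing_expr:
            parts.append(
                f"{missing_expr} gene{'s' if missing_expr != 1 else ''} missing from expression data"
            )
        raise ValidationError("; ".join(parts))
    t = de.table.copy()
    t[GENE_KEY] = t[GENE_KEY].astype(str)
    reordered = t.set_index(GENE_KEY).loc[expr_ids].reset_index()
    return PairedData(de=DEResult(reordered), expr=expr)


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def _format_value(v) -> str:
    # shortest round-trip representation for floats; verbatim otherwise
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return str(v)


def export_csv(
    de: DEResult,
    expr_values: pd.DataFrame,
    selection: set | list | tuple = (),
    scope: str = "all",
) -> str:
    """Export annotations + DE statistics + per-sample expression as CSV text.

    ``expr_values`` is the gene x sample log-CPM matrix (index = gene ids,
    aligned with ``de``).  ``scope='selected'`` restricts rows to the
    ``selection`` gene ids (expression order preserved); ``scope='all'``
    exports every gene.  Fields containing delimiters, quotes or newlines are
    RFC-4180 quoted, so the document re-parses verbatim.
    """
    if scope not in ("all", "selected"):
        raise ValidationError(f"scope must be 'all' or 'selected', got {scope!r}")
    gene_ids = [str(g) for g in de.gene_ids]
    if list(map(str, expr_values.index)) != gene_ids:
        raise ValidationError("expression matrix gene order does not match DE table")
    sel = {str(g) for g in selection}
    unknown = sel - set(gene_ids)
    if unknown:
        raise ValidationError(f"selection contains unknown gene id(s): {sorted(unknown)}")
    if scope == "selected" and not sel:
        raise ValidationError(
            "scope='selected' requires a non-empty selection; use scope='all'"
        )

    annot_cols = [c for c in de.table.columns if c not in STAT_COLUMNS]
    stat_cols = de.stat_columns
    sample_cols = [str(s) for s in expr_values.columns]

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(annot_cols + stat_cols + sample_cols)
    for i, gid in enumerate(gene_ids):
        if scope == "selected" and gid not in sel:
            continue
        row = [_format_value(de.table[c].iloc[i]) for c in annot_cols]
        row += [_format_value(de.table[c].iloc[i]) for c in stat_cols]
        row += [_format_value(v) for v in expr_values.iloc[i]]
        writer.writerow(row)
    return buf.getvalue()
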