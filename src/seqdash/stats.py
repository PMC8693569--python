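"""Numeric substrate: library sizes, log-CPM, BH adjustment, DE status calls.

All routines are vectorised numpy implementations; none of them delegate the
core arithmetic to an external statistics package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DEResult, ExpressionData, ValidationError

__all__ = [
    "StatusCall",
    "library_sizes",
    "log_cpm",
    "bh_adjust",
    "decide_status",
    "neglog10_p",
]


def library_sizes(expr: ExpressionData) -> pd.Series:
    """Per-sample total counts (column sums), in sample order."""
    return expr.counts.sum(axis=0)


def log_cpm(expr: ExpressionData, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    value = log2( (count + prior) / (libsize + 2 * prior) * 1e6 )

    The prior keeps zero counts finite; the matching ``2 * prior`` offset in
    the denominator keeps the transform consistent across library sizes.
    Defined for all valid inputs, including all-zero samples.
    """
    if not prior > 0:
        raise ValidationError(f"prior must be > 0, got {prior!r}")
    counts = expr.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    vals = np.log2((counts + prior) / (lib + 2.0 * prior) * 1e6)
    return pd.DataFrame(vals, index=expr.counts.index, columns=expr.counts.columns)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, compute ``p_(i) * m / i``, enforce monotonicity from the
    largest rank downward (running minimum), cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class StatusCall:
    """Parameters of the automatic significant-gene call.

    ``alpha`` is the significance cutoff on the adjusted p-value,
    ``lfc_min`` a minimum absolute log2 fold change (default 0: no floor),
    ``adjusted`` records whether supplied p-values are already adjusted.
    """

    alpha: float = 0.05
    lfc_min: float = 0.0
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha!r}")
        if self.lfc_min < 0:
            raise ValidationError(f"lfc_min must be >= 0, got {self.lfc_min!r}")


def decide_status(
    de: DEResult,
    call: StatusCall = StatusCall(),
    explicit_status=None,
) -> np.ndarray:
    """Call each gene up (1), down (-1) or not significant (0).

    Uses the DE table's ``adj_p`` when present, otherwise BH-adjusts
    ``p_value`` (or takes it as already adjusted when ``call.adjusted``).
    A gene is significant when adjusted p < alpha and |logfc| >= lfc_min;
    its status is then the sign of the log fold change.  An
    ``explicit_status`` vector overrides the automatic call entirely.
    """
    n = len(de)
    if explicit_status is not None:
        s = np.asarray(explicit_status, dtype=int)
        if s.shape != (n,):
            raise ValidationError(
                f"explicit status has length {s.size}, expected {n}"
            )
        if not np.isin(s, (-1, 0, 1)).all():
            raise ValidationError("explicit status values must be in {-1, 0, 1}")
        return s
    logfc = de.table["logfc"].to_numpy(dtype=float)
    if "adj_p" in de.table.columns:
        q = de.table["adj_p"].to_numpy(dtype=float)
    elif call.adjusted:
        q = de.table["p_value"].to_numpy(dtype=float)
    else:
        q = bh_adjust(de.table["p_value"].to_numpy(dtype=float))
    sig = (q < call.alpha) & (np.abs(logfc) >= call.lfc_min)
    return np.where(sig, np.sign(logfc).astype(int), 0)


def neglog10_p(p) -> np.ndarray:
    """-log10 p-values for the volcano y-axis, with zeros kept finite.

    p = 0 is clamped to half the smallest nonzero p in the vector; if every
    p is zero the clamp falls back to 1e-300.
    """
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    nonzero = p[p > 0]
    eps = nonzero.min() / 2.0 if nonzero.size else 1e-300
    return -np.log10(np.where(p == 0, eps, p))
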