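"""Leading-logFC distances and classical (Torgerson) multidimensional scaling.

Sample similarity is summarised by the leading log-fold-change distance: the
root-mean-square of the largest absolute log-CPM differences over a top-gene
subset, chosen either per sample pair (``pairwise``) or once for all samples
from the genes with largest log-CPM variance (``common``).  The distance
matrix is embedded by classical MDS via double-centering and
eigendecomposition, and each retained dimension is annotated with the
proportion of positive-eigenvalue mass it explains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .data_model import ExpressionData, ValidationError
from .stats import log_cpm

__all__ = [
    "MDSResult",
    "leading_logfc_distance",
    "classical_mds",
    "variance_explained",
    "run_mds",
]

logger = logging.getLogger(__name__)


@dataclass
class MDSResult:
    """Sample embedding from classical MDS of leading-logFC distances.

    ``coordinates`` is a sample x dimension frame with columns ``dim1..dimK``
    (K <= n_samples - 1, truncated to positive eigenvalues);
    ``eigenvalues`` holds all eigenvalues sorted descending;
    ``var_explained`` the per-retained-dimension proportions of the positive
    eigenvalue mass; ``params`` records how the embedding was computed.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    var_explained: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]

    @property
    def sample_ids(self) -> list:
        return list(self.coordinates.index)


def leading_logfc_distance(
    logcpm, top: int = 500, gene_selection: str = "pairwise"
) -> np.ndarray:
    """Symmetric sample x sample leading-logFC distance matrix.

    For ``pairwise`` selection, d(i, j) is the RMS of the t largest absolute
    log-CPM differences between samples i and j, t = min(top, n_genes).  For
    ``common`` selection the same RMS is taken over a single gene set: the t
    genes with largest log-CPM variance across all samples.
    """
    if top < 1:
        raise ValidationError(f"top must be >= 1, got {top!r}")
    if gene_selection not in ("pairwise", "common"):
        raise ValidationError(
            f"gene_selection must be 'pairwise' or 'common', got {gene_selection!r}"
        )
    x = np.asarray(logcpm, dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValidationError("at least 2 samples are required for a distance matrix")
    t = min(top, n_genes)
    d = np.zeros((n_samples, n_samples), dtype=float)
    if gene_selection == "common":
        rv = x.var(axis=1, ddof=1) if n_samples > 1 else np.zeros(n_genes)
        keep = np.argsort(rv, kind="stable")[::-1][:t]
        sub = x[np.sort(keep)]
        for i in range(n_samples):
            diff = sub[:, i + 1 :].T - sub[:, i]
            if diff.size:
                d[i, i + 1 :] = np.sqrt(np.mean(diff**2, axis=1))
    else:
        for i in range(n_samples):
            for j in range(i + 1, n_samples):
                sq = (x[:, i] - x[:, j]) ** 2
                largest = np.partition(sq, n_genes - t)[n_genes - t :]
                d[i, j] = np.sqrt(largest.mean())
    d = d + d.T
    return d


def classical_mds(D, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson classical scaling of a distance matrix.

    Double-centers B = -1/2 * J D^2 J, eigendecomposes it, and returns
    coordinates (eigenvectors scaled by sqrt of positive eigenvalues,
    truncated to min(k, #positive)) along with all eigenvalues sorted
    descending.  Each coordinate column's sign is fixed so its
    largest-magnitude entry is positive, making outputs reproducible despite
    the inherent sign ambiguity.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValidationError("distance matrix must be square")
    if np.abs(D - D.T).max(initial=0.0) > 1e-8:
        raise ValidationError("distance matrix is not symmetric (tolerance 1e-8)")
    if np.abs(np.diag(D)).max(initial=0.0) > 1e-8 or (D < 0).any():
        raise ValidationError("distances must be nonnegative with a zero diagonal")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k!r}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0  # symmetrize against rounding
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # eigenvalues within rounding error of zero are not signal
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValidationError("degenerate configuration: no positive eigenvalue")
    keep = min(k, n_pos)
    coords = eigvecs[:, :keep] * np.sqrt(eigvals[:keep])
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    neg_mass = float(-eigvals[eigvals < -tol].sum())
    if neg_mass > 0:
        logger.info(
            "dropped negative eigenvalue mass %.4g (non-Euclidean distances)", neg_mass
        )
    return coords, eigvals


def variance_explained(eigenvalues) -> np.ndarray:
    """Proportion of total positive-eigenvalue mass per positive eigenvalue."""
    ev = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    # eigenvalues within rounding error of zero carry no variance
    tol = len(ev) * np.finfo(float).eps * max(np.abs(ev).max(initial=0.0), 1.0)
    pos = ev[ev > tol]
    if pos.size == 0:
        raise ValidationError("no positive eigenvalue: degenerate configuration")
    return pos / pos.sum()


def run_mds(
    expr: ExpressionData,
    top: int = 500,
    gene_selection: str = "pairwise",
    prior: float = 0.5,
) -> MDSResult:
    """Full pipeline: log-CPM -> leading-logFC distance -> classical MDS.

    Requests k = n_samples - 1 dimensions; fewer may be retained if the
    eigenvalue spectrum has fewer positive entries.  Two-sample inputs are
    allowed but yield a single trivial dimension (warned).
    """
    n = expr.n_samples
    if n < 2:
        raise ValidationError("MDS requires at least 2 samples")
    if n < 3:
        warnings.warn(
            "MDS of 2 samples has a single trivial dimension", UserWarning, stacklevel=2
        )
    lc = log_cpm(expr, prior=prior)
    D = leading_logfc_distance(lc.to_numpy(), top=top, gene_selection=gene_selection)
    coords, eigvals = classical_mds(D, k=n - 1)
    ve = variance_explained(eigvals)[: coords.shape[1]]
    frame = pd.DataFrame(
        coords,
        index=expr.sample_ids,
        columns=[f"dim{i + 1}" for i in range(coords.shape[1])],
    )
    return MDSResult(
        coordinates=frame,
        eigenvalues=eigvals,
        var_explained=ve,
        params={
            "top": top,
            "gene_selection": gene_selection,
            "prior": prior,
            "library_sizes": [float(v) for v in expr.counts.sum(axis=0)],
        },
    )
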