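"""Negative-binomial count simulation with planted group effects.

The generator emulates a small bulk RNA-seq design: per-gene baseline means
drawn log-uniform, a designated subset of genes given a +/- log2 fold change
in one group, per-sample library sizes drawn uniformly, and counts sampled
from a negative binomial with a common dispersion.  It exists to provide
fully reproducible fixtures (and a simple per-gene two-sample test to turn
them into DE tables) for the dashboards; it makes no claim to model
single-cell zero inflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import DEResult, ExpressionData, ValidationError
from .stats import log_cpm

__all__ = ["SimTruth", "simulate_counts", "fixture_de_test", "subsample_columns"]

#: defaults chosen to resemble genetically identical model-organism samples:
#: squared biological coefficient of variation ~0.05, ~1M reads per sample
DEFAULT_DISPERSION = 0.05
DEFAULT_LIBSIZE_RANGE = (8e5, 1.2e6)
DEFAULT_MEAN_RANGE_CPM = (1.0, 1024.0)


@dataclass
class SimTruth:
    """Ground truth of a simulation: which genes are DE and by how much."""

    de_flags: np.ndarray
    true_lfc: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if (self.true_lfc[~self.de_flags.astype(bool)] != 0).any():
            raise ValidationError("true_lfc must be 0 wherever de_flags is 0")


def simulate_counts(
    n_genes: int = 1000,
    groups=("A", "B"),
    samples_per_group: int = 3,
    n_de: int = 100,
    lfc_magnitude: float = 2.0,
    dispersion: float = DEFAULT_DISPERSION,
    libsize_range=DEFAULT_LIBSIZE_RANGE,
    seed: int = 0,
) -> tuple[ExpressionData, SimTruth]:
    """Simulate a gene x sample count matrix with planted DE genes.

    DE genes receive ``+/- lfc_magnitude`` (random sign) in the last group.
    Counts are NB(mean = relative abundance x library size, dispersion);
    all draws flow from one seeded generator, so outputs are bit-reproducible.
    """
    groups = list(groups)
    if n_de > n_genes:
        raise ValidationError(f"n_de={n_de} exceeds n_genes={n_genes}")
    if n_de < 0 or n_genes < 1:
        raise ValidationError("n_genes must be >= 1 and n_de >= 0")
    if dispersion <= 0:
        raise ValidationError(f"dispersion must be > 0, got {dispersion!r}")
    if samples_per_group < 1 or len(groups) < 1:
        raise ValidationError("need at least one group with at least one sample")
    lo, hi = libsize_range
    if not (0 < lo <= hi):
        raise ValidationError(f"invalid libsize_range {libsize_range!r}")

    rng = np.random.default_rng(seed)
    base = np.exp(
        rng.uniform(
            np.log(DEFAULT_MEAN_RANGE_CPM[0]), np.log(DEFAULT_MEAN_RANGE_CPM[1]), n_genes
        )
    )
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_flags = np.zeros(n_genes, dtype=int)
    de_flags[de_idx] = 1
    signs = rng.choice([-1.0, 1.0], size=n_de)
    true_lfc = np.zeros(n_genes)
    true_lfc[de_idx] = signs * lfc_magnitude

    n_samples = len(groups) * samples_per_group
    sample_group = np.repeat(groups, samples_per_group)
    libsizes = rng.uniform(lo, hi, n_samples)

    # relative abundance per gene per group; the fold change lands on the
    # last group so earlier groups share the baseline
    counts = np.empty((n_genes, n_samples))
    r = 1.0 / dispersion
    for j in range(n_samples):
        mu_g = base * (2.0 ** (true_lfc if sample_group[j] == groups[-1] else 0.0))
        frac = mu_g / mu_g.sum()
        mu = frac * libsizes[j]
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)

    gene_ids = [f"gene{i + 1}" for i in range(n_genes)]
    sample_ids = [
        f"{g}_{k + 1}" for g in groups for k in range(samples_per_group)
    ]
    expr = ExpressionData(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        sample_table=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": list(sample_group),
                "library_size": counts.sum(axis=0),
            }
        ),
        gene_table=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "symbol": [f"Sym{i + 1}" for i in range(n_genes)],
            }
        ),
    )
    truth = SimTruth(
        de_flags=de_flags,
        true_lfc=true_lfc,
        params={
            "n_genes": n_genes,
            "groups": groups,
            "samples_per_group": samples_per_group,
            "n_de": n_de,
            "lfc_magnitude": lfc_magnitude,
            "dispersion": dispersion,
            "libsize_range": tuple(libsize_range),
            "seed": seed,
        },
    )
    return expr, truth


def fixture_de_test(
    expr: ExpressionData, group_col: str, contrast: tuple
) -> DEResult:
    """Per-gene two-sample comparison on log-CPM (fixture-quality DE table).

    logfc is the difference of group mean log-CPM (second minus first
    contrast label), the p-value comes from a pooled-variance two-sample
    t-test, and ave_expr is the overall mean log-CPM.  Genes with zero
    pooled variance get p = 1 (no evidence) so the output is total.
    """
    if group_col not in expr.sample_table.columns:
        raise ValidationError(f"unknown group column {group_col!r}")
    a, b = contrast
    groups = expr.sample_table[group_col].astype(str)
    ia = np.flatnonzero((groups == str(a)).to_numpy())
    ib = np.flatnonzero((groups == str(b)).to_numpy())
    for label, idx in ((a, ia), (b, ib)):
        if idx.size < 2:
            raise ValidationError(
                f"group {label!r} has {idx.size} sample(s); need >= 2"
            )
    lc = log_cpm(expr).to_numpy()
    xa, xb = lc[:, ia], lc[:, ib]
    na, nb = ia.size, ib.size
    ma_, mb_ = xa.mean(axis=1), xb.mean(axis=1)
    logfc = mb_ - ma_
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    p = np.where(se == 0, 1.0, p)  # degenerate variance: no evidence
    return DEResult(
        pd.DataFrame(
            {
                "gene_id": expr.gene_ids,
                "logfc": logfc,
                "ave_expr": lc.mean(axis=1),
                "p_value": p,
            }
        )
    )


def subsample_columns(expr: ExpressionData, n: int, seed: int) -> ExpressionData:
    """Uniform without-replacement column subset (original order preserved).

    Used to keep single-cell-scale payloads tractable; a random sub-sample
    remains informative about the distribution of the full set of columns.
    """
    if n > expr.n_samples:
        raise ValidationError(
            f"cannot sub-sample {n} of {expr.n_samples} samples"
        )
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(expr.n_samples, size=n, replace=False))
    return ExpressionData(
        counts=expr.counts.iloc[:, keep],
        sample_table=expr.sample_table.iloc[keep].reset_index(drop=True),
        gene_table=expr.gene_table,
    )
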