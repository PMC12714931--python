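"""Two-group differential expression via a self-contained NB Wald test.

The engine follows the classical count-based recipe:

1. **Normalization** — median-of-ratios size factors: each sample's factor
   is the median, over genes expressed in every sample, of the ratio of its
   count to the gene's geometric mean across samples; factors are rescaled
   to geometric mean 1.
2. **Dispersion** — per-gene method-of-moments under a negative-binomial
   variance Var = mu + alpha * mu^2, using the pooled within-group variance
   of normalized counts: ``alpha = max((s2 - mu_bar) / mu_bar^2, ALPHA_MIN)``.
3. **Wald test** — log2 fold change of group means (pseudocount 0.5), a
   delta-method standard error under the NB variance, the Wald statistic
   against the standard normal, and Benjamini–Hochberg adjustment.

Deliberately omitted (non-goals): fold-change shrinkage, dispersion
shrinkage toward a trend, outlier filtering, independent filtering and
multi-factor designs. Consequently results are close to, but not
numerically identical with, full-featured DE packages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptome_sim import CONTROL, ExpressionMatrix

__all__ = [
    "ALPHA_MIN",
    "PSEUDOCOUNT",
    "SE_FLOOR",
    "estimate_size_factors",
    "normalize_counts",
    "estimate_dispersion",
    "bh_adjust",
    "wald_test",
    "significant_up",
    "significant_down",
]

ALPHA_MIN = 1e-8  # dispersion floor (Poisson limit)
PSEUDOCOUNT = 0.5  # stabilizes log fold changes at zero means
SE_FLOOR = 1e-6  # avoids infinite Wald statistics


def _as_counts(counts: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(counts, ExpressionMatrix):
        return counts.counts
    return counts


def estimate_size_factors(counts: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with strictly positive counts in every sample enter the
    median. If no such gene exists the estimator falls back to total-count
    ratios and emits a warning.
    """
    mat = _as_counts(counts)
    x = mat.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if all_positive.any():
        xp = x[all_positive]
        geomean = np.exp(np.log(xp).mean(axis=1, keepdims=True))
        log_factors = np.log(np.median(xp / geomean, axis=0))
    else:
        warnings.warn(
            "no gene with all-positive counts; falling back to total-count "
            "ratio normalization",
            UserWarning,
            stacklevel=2,
        )
        totals = x.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total counts; cannot normalize")
        log_factors = np.log(totals)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=mat.columns, name="size_factor")


def normalize_counts(
    counts: ExpressionMatrix | pd.DataFrame, size_factors: pd.Series | None = None
) -> pd.DataFrame:
    """Counts divided per sample by its size factor."""
    mat = _as_counts(counts)
    if size_factors is None:
        size_factors = estimate_size_factors(mat)
    return mat / size_factors


def _group_masks(groups: pd.Series, reference: str) -> tuple[np.ndarray, np.ndarray, str]:
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among groups {levels}")
    other = next(g for g in levels if g != reference)
    ref_mask = (groups == reference).to_numpy()
    other_mask = ~ref_mask
    return ref_mask, other_mask, other


def estimate_dispersion(
    normalized_counts: pd.DataFrame,
    groups: pd.Series,
    reference: str = CONTROL,
    alpha_min: float = ALPHA_MIN,
) -> pd.DataFrame:
    """Per-gene NB dispersion by method of moments.

    The within-group variance is pooled across the two groups
    (``((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)``) and compared with the grand
    mean of normalized counts: ``alpha = max((s2 - mu) / mu^2, alpha_min)``.
    Genes with zero mean get the floor and are flagged.
    """
    ref_mask, other_mask, _ = _group_masks(groups.loc[normalized_counts.columns], reference)
    n1, n2 = int(ref_mask.sum()), int(other_mask.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("dispersion estimation needs at least 2 samples per group")
    x = normalized_counts.to_numpy(dtype=float)
    mu = x.mean(axis=1)
    s2_pooled = (
        x[:, ref_mask].var(axis=1, ddof=1) * (n1 - 1) + x[:, other_mask].var(axis=1, ddof=1) * (n2 - 1)
    ) / (n1 + n2 - 2)
    zero_mean = mu == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2_pooled - mu) / np.square(mu)
    alpha = np.where(zero_mean, alpha_min, np.maximum(alpha, alpha_min))
    return pd.DataFrame(
        {"dispersion": alpha, "zero_mean": zero_mean}, index=normalized_counts.index
    )


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``padj_(i) = min_{j >= i} ( m * p_(j) / j )`` over the sorted p-values,
    capped at 1. Raises on values outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def wald_test(
    counts: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series | None = None,
    reference: str = CONTROL,
    treatment: str | None = None,
) -> pd.DataFrame:
    """NB Wald differential expression, treatment vs reference.

    Returns a table indexed by gene id with columns ``baseMean``,
    ``log2FoldChange``, ``lfcSE``, ``stat``, ``pvalue``, ``padj`` and
    ``dispersion``. ``log2FoldChange > 0`` means higher expression in the
    treatment (post-vaccination) group.
    """
    if isinstance(counts, ExpressionMatrix):
        if groups is None:
            groups = counts.groups
        counts = counts.counts
    if groups is None:
        raise ValueError("a sample-to-group mapping is required")
    groups = groups.loc[counts.columns]
    ref_mask, other_mask, other = _group_masks(groups, reference)
    if treatment is not None and treatment != other:
        raise ValueError(f"treatment level {treatment!r} not found (have {other!r})")
    x_raw = counts.to_numpy(dtype=float)
    if x_raw[:, ref_mask].sum() == 0 or x_raw[:, other_mask].sum() == 0:
        raise ValueError("one group has all-zero counts for every gene")

    size_factors = estimate_size_factors(counts)
    norm = normalize_counts(counts, size_factors)
    disp = estimate_dispersion(norm, groups, reference=reference)
    alpha = disp["dispersion"].to_numpy()

    x = norm.to_numpy(dtype=float)
    n_ref, n_trt = int(ref_mask.sum()), int(other_mask.sum())
    mu_ref = x[:, ref_mask].mean(axis=1)
    mu_trt = x[:, other_mask].mean(axis=1)

    log2fc = np.log2(mu_trt + PSEUDOCOUNT) - np.log2(mu_ref + PSEUDOCOUNT)
    # Delta method: Var(log2(mu_hat + pc)) ~= Var(mu_hat) / ((mu_hat+pc) ln2)^2
    # with Var(mu_hat) = (mu + alpha mu^2) / n under the NB variance model.
    var_ref = (mu_ref + alpha * mu_ref**2) / n_ref
    var_trt = (mu_trt + alpha * mu_trt**2) / n_trt
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_trt / np.square(mu_trt + PSEUDOCOUNT) + var_ref / np.square(mu_ref + PSEUDOCOUNT)
    ) / ln2
    se = np.maximum(se, SE_FLOOR)
    stat = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    padj = bh_adjust(pvalue)

    return pd.DataFrame(
        {
            "baseMean": x.mean(axis=1),
            "log2FoldChange": log2fc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "dispersion": alpha,
        },
        index=counts.index,
    )


def significant_up(de_table: pd.DataFrame, fdr: float = 0.05) -> pd.Index:
    """Gene ids with padj < fdr and positive log2 fold change."""
    mask = (de_table["padj"] < fdr) & (de_table["log2FoldChange"] > 0)
    return de_table.index[mask]


def significant_down(de_table: pd.DataFrame, fdr: float = 0.05) -> pd.Index:
    """Gene ids with padj < fdr and negative log2 fold change."""
    mask = (de_table["padj"] < fdr) & (de_table["log2FoldChange"] < 0)
    return de_table.index[mask]
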