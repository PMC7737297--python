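"""Shared statistical helpers: one-sided rank-sum tests and row-wise correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: largest per-group size at which the exact rank-sum null is enumerated
EXACT_MAX_N = 12


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    n1: int
    n2: int
    method: str


def rank_sum_test(x, y, alternative: str = "greater", method: str = "auto") -> TestResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney U) test of ``x`` versus ``y``.

    ``method='auto'`` uses the exact null distribution when both groups have
    at most 12 observations and there are no ties, and the tie-corrected
    normal approximation (with continuity correction) otherwise.  ``'exact'``
    and ``'asymptotic'`` force the respective path.  Degenerate input where
    every pooled value is identical returns P = 1 (no evidence in either
    direction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=x.size * y.size / 2.0, pvalue=1.0,
                          n1=x.size, n2=y.size, method="degenerate")
    if method == "auto":
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (no_ties and max(x.size, y.size) <= EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                      n1=x.size, n2=y.size, method=method)


def rank_sum_matrix(X: np.ndarray, Y: np.ndarray, alternative: str = "greater") -> np.ndarray:
    """Row-wise one-sided rank-sum P values (tie-corrected normal approximation).

    ``X`` (rows x n1) is compared against ``Y`` (rows x n2) row by row; used
    for the per-node tests where group sizes exceed the exact-path limit.
    Rows where every pooled value is identical get P = 1.
    """
    res = stats.mannwhitneyu(X, Y, alternative=alternative, method="asymptotic", axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (np.ptp(X, axis=1) == 0) & (np.ptp(Y, axis=1) == 0) \
        & (X[:, 0] == Y[:, 0])
    p[degenerate] = 1.0
    return p


def welch_t_test(x, y, alternative: str = "less") -> TestResult:
    """One-sided Welch (unequal-variance) two-sample t-test."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 finite values")
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                      n1=x.size, n2=y.size, method="welch")


def spearman_rows(A: np.ndarray, B: np.ndarray, min_samples: int = 3) -> np.ndarray:
    """Per-row Spearman correlation between matching rows of ``A`` and ``B``.

    NaNs are excluded pairwise per row.  Rows with fewer than ``min_samples``
    complete pairs, or with a constant value vector (undefined ranks), yield
    NaN.
    """
    n_rows = A.shape[0]
    out = np.full(n_rows, np.nan)
    for i in range(n_rows):
        a, b = A[i], B[i]
        mask = np.isfinite(a) & np.isfinite(b)
        if mask.sum() < min_samples:
            continue
        a, b = a[mask], b[mask]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        out[i] = stats.spearmanr(a, b).statistic
    return out


def pearson_pairwise_complete(a: np.ndarray, b: np.ndarray,
                              min_values: int = 3) -> float:
    """Pearson r over positions where both vectors are finite; NaN if degenerate."""
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < min_values:
        return float("nan")
    a, b = a[mask], b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)
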