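"""Intra-rater reliability: absolute-agreement ICC, Bland–Altman, within-subject CV.

The reliability battery quantifies agreement between repeated measurements
of the same vessels by one grader: the two-way random-effects
absolute-agreement intraclass correlation (single- and average-measure
forms, McGraw–Wong ICC(A,1)/ICC(A,k)) with F-based 95% confidence
intervals, Bland–Altman bias and limits of agreement with a
difference-vs-mean trend line, and the root-mean-square within-subject
coefficient of variation with chi-square confidence bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Two-way ANOVA mean squares of an n subjects x k sessions matrix."""

    rows: float
    columns: float
    error: float
    n_subjects: int
    n_sessions: int


@dataclass(frozen=True)
class ICCResult:
    form: str  # 'single' | 'average'
    icc: float
    ci_low: float
    ci_high: float
    anova_mean_squares: AnovaMeanSquares
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    trend_slope: float
    trend_intercept: float


@dataclass(frozen=True)
class CVResult:
    cv_percent: float
    ci_low: float
    ci_high: float


def _as_matrix(data: np.ndarray) -> np.ndarray:
    m = np.asarray(data, dtype=float)
    if m.ndim != 2:
        raise ValueError("repeated measures must be a 2-D (subjects x sessions) array")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 sessions")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing or non-finite cells are not allowed")
    return m


def anova_mean_squares(data: np.ndarray) -> AnovaMeanSquares:
    """Mean squares for subjects (rows), sessions (columns) and error."""
    m = _as_matrix(data)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    return AnovaMeanSquares(
        rows=ss_rows / (n - 1),
        columns=ss_cols / (k - 1),
        error=max(ss_err, 0.0) / ((n - 1) * (k - 1)),
        n_subjects=n,
        n_sessions=k,
    )


def icc_absolute_agreement(
    data: np.ndarray, form: str = "single", alpha: float = 0.05
) -> ICCResult:
    """Two-way random absolute-agreement ICC with a 95% confidence interval.

    single:  (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    average: (MSR - MSE) / (MSR + (MSC - MSE)/n)

    Confidence bounds use the standard F-based construction for the
    absolute-agreement two-way model; the average-measure interval is the
    Spearman–Brown transform of the single-measure one.  A matrix with zero
    total variance has no defined ICC and is reported degenerate.
    """
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    m = _as_matrix(data)
    n, k = m.shape
    ms = anova_mean_squares(m)
    msr, msc, mse = ms.rows, ms.columns, ms.error

    if np.ptp(m) == 0:
        return ICCResult(form, float("nan"), float("nan"), float("nan"), ms, True)

    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom_single == 0:
        return ICCResult(form, float("nan"), float("nan"), float("nan"), ms, True)
    icc_single = (msr - mse) / denom_single

    # F-based interval for ICC(A,1) (Satterthwaite df for the session term).
    a = (k * icc_single) / (n * (1 - icc_single)) if icc_single < 1 else np.inf
    b = 1 + (k * icc_single * (n - 1)) / (n * (1 - icc_single)) if icc_single < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:  # perfect agreement
        lo = hi = 1.0
    lo, hi = min(lo, icc_single), max(hi, icc_single)

    if form == "single":
        return ICCResult("single", float(icc_single), float(lo), float(hi), ms)

    denom_avg = msr + (msc - mse) / n
    icc_avg = (msr - mse) / denom_avg if denom_avg != 0 else float("nan")

    def spearman_brown(r: float) -> float:
        if not np.isfinite(r) or r >= 1:
            return 1.0
        return (k * r) / (1 + (k - 1) * r)

    lo_a, hi_a = spearman_brown(lo), spearman_brown(hi)
    lo_a, hi_a = min(lo_a, icc_avg), max(hi_a, icc_avg)
    return ICCResult("average", float(icc_avg), float(lo_a), float(hi_a), ms)


def bland_altman(first: np.ndarray, second: np.ndarray) -> BlandAltmanResult:
    """Bias, 95% limits of agreement and difference-vs-mean trend line.

    Differences are first minus second; limits of agreement are
    bias ± 1.96·SD(differences); the trend is the ordinary least-squares
    line of difference on pairwise mean.
    """
    x = np.asarray(first, dtype=float)
    y = np.asarray(second, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("first and second must be equally long 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    mean = 0.5 * (x + y)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) == 0 or np.ptp(diff) == 0:
        slope, intercept = 0.0, bias
    else:
        slope, intercept = np.polyfit(mean, diff, 1)
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        trend_slope=float(slope),
        trend_intercept=float(intercept),
    )


def coefficient_of_variation(
    first: np.ndarray,
    second: np.ndarray,
    alpha: float = 0.05,
    method: str = "rms",
) -> CVResult:
    """Within-subject coefficient of variation (%) of duplicate measurements.

    The default root-mean-square form estimates, per subject, the
    within-subject variance from the pair difference (d²/2) relative to the
    squared pair mean, then averages across subjects:

        cv = 100 · sqrt( mean_i[ (d_i²/2) / m_i² ] )

    The 95% interval scales cv by chi-square bounds on the pooled
    within-subject variance with n degrees of freedom.  ``method='sd_mean'``
    instead averages the per-subject SD/mean ratios.
    """
    x = np.asarray(first, dtype=float)
    y = np.asarray(second, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("first and second must be equally long 1-D arrays, n >= 3")
    m = 0.5 * (x + y)
    if np.any(m <= 0):
        raise ValueError("all subject means must be positive")
    d = x - y
    n = x.size
    if method == "rms":
        cv = float(np.sqrt(np.mean((d**2 / 2.0) / m**2)))
    elif method == "sd_mean":
        cv = float(np.mean(np.abs(d) / np.sqrt(2.0) / m))
    else:
        raise ValueError("method must be 'rms' or 'sd_mean'")
    lo = cv * np.sqrt(n / stats.chi2.ppf(1 - alpha / 2, n))
    hi = cv * np.sqrt(n / stats.chi2.ppf(alpha / 2, n))
    return CVResult(cv_percent=100 * cv, ci_low=100 * lo, ci_high=100 * hi)
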