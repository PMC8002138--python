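"""Group comparisons, correlation grids and regressions on cohort tables.

Continuous variables are compared across groups with one-way ANOVA plus
Tukey post-hoc tests when a Kolmogorov–Smirnov check (against a normal with
the sample mean/SD, pooled across groups) does not reject normality, and
with Kruskal–Wallis otherwise; two-group variables fall back to Student's
t-test.  Categorical covariates use Pearson chi-square without continuity
correction.  Associations between arterial morphometry and retinal layer
thickness are assessed with per-group Pearson correlations and with
univariate or covariate-adjusted ordinary least squares, reporting
standardized coefficients (slope scaled by SD(predictor)/SD(dependent)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_COVARIATES = ("age", "gender_male", "diabetes_duration", "hba1c")


class NormalityResult(NamedTuple):
    statistic: float
    p_value: float
    is_normal: bool
    testable: bool = True


@dataclass(frozen=True)
class GroupComparisonResult:
    variable: str
    test_used: str  # 'anova' | 'kruskal-wallis' | 'chi-square' | 't-test'
    statistic: float
    p_value: float
    group_means: Dict[str, float] = field(default_factory=dict)
    posthoc: Optional[Dict[Tuple[str, str], float]] = None


@dataclass(frozen=True)
class CorrelationResult:
    group: str
    sector: str
    r: float
    p_value: float
    n: int
    flagged: bool = False


@dataclass(frozen=True)
class RegressionResult:
    dependent: str
    predictor: str
    model: str  # 'univariate' | 'adjusted'
    standardized_coefficient: float
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates: Tuple[str, ...] = ()
    n: int = 0


def test_normality(values: np.ndarray, alpha: float = 0.05) -> NormalityResult:
    """One-sample KS test against a normal with the sample mean and SD."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return NormalityResult(float("nan"), float("nan"), False, testable=False)
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return NormalityResult(float(stat), float(p), bool(p >= alpha))


def _group_values(table: pd.DataFrame, variable: str, group_col: str):
    if variable not in table.columns:
        raise ValueError(f"variable {variable!r} not in table")
    groups = []
    for label, sub in table.groupby(group_col, sort=True):
        vals = sub[variable].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        if vals.size < 3:
            raise ValueError(f"group {label!r} has n < 3 for {variable!r}")
        groups.append((str(label), vals))
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups with data for {variable!r}")
    return groups


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Normality-gated comparison of a continuous variable across groups.

    Tukey-adjusted pairwise p-values are attached for three-group parametric
    comparisons; two-group parametric comparisons use Student's t-test.
    """
    groups = _group_values(table, variable, group_col)
    labels = [g for g, _ in groups]
    arrays = [v for _, v in groups]
    pooled = np.concatenate(arrays)
    norm = test_normality(pooled, alpha=alpha)
    parametric = norm.testable and norm.is_normal
    means = {g: float(v.mean()) for g, v in groups}

    if parametric and len(groups) == 2:
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return GroupComparisonResult(variable, "t-test", float(stat), float(p), means)
    if parametric:
        stat, p = stats.f_oneway(*arrays)
        tk = pairwise_tukeyhsd(
            endog=pooled,
            groups=np.concatenate([[g] * v.size for g, v in groups]),
            alpha=alpha,
        )
        uniq = list(tk.groupsunique)
        pairs = [
            (str(uniq[i]), str(uniq[j]))
            for i in range(len(uniq))
            for j in range(i + 1, len(uniq))
        ]
        posthoc = {pair: float(pv) for pair, pv in zip(pairs, tk.pvalues)}
        return GroupComparisonResult(
            variable, "anova", float(stat), float(p), means, posthoc
        )
    stat, p = stats.kruskal(*arrays)
    return GroupComparisonResult(variable, "kruskal-wallis", float(stat), float(p), means)


def chi_square_counts(contingency: np.ndarray) -> Tuple[float, float]:
    """Pearson chi-square on a group x category count table, no correction."""
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal row or column")
    res = stats.chi2_contingency(obs, correction=False)
    if np.any(res.expected_freq < 1):
        raise ValueError("expected counts below 1; chi-square not applicable")
    return float(res.statistic), float(res.pvalue)


def pearson_grid(
    table: pd.DataFrame,
    layer_a: str,
    layer_b: str,
    sectors: Sequence[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group, per-sector Pearson correlation between two layers.

    Sector columns are named ``{layer}_{sector}``.  Constant columns yield a
    flagged row with undefined r.
    """
    rows = []
    for label, sub in table.groupby(group_col, sort=True):
        for sector in sectors:
            col_a, col_b = f"{layer_a}_{sector}", f"{layer_b}_{sector}"
            pair = sub[[col_a, col_b]].dropna()
            if len(pair) < 3:
                raise ValueError(f"group {label!r} has n < 3 for sector {sector!r}")
            a = pair[col_a].to_numpy(dtype=float)
            b = pair[col_b].to_numpy(dtype=float)
            if a.std() == 0 or b.std() == 0:
                rows.append(CorrelationResult(str(label), sector, float("nan"),
                                              float("nan"), len(pair), True))
                continue
            r, p = stats.pearsonr(a, b)
            rows.append(CorrelationResult(str(label), sector, float(r), float(p), len(pair)))
    return pd.DataFrame(rows)


def _collinear_columns(x: np.ndarray, names: Sequence[str]) -> list:
    bad = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        others = np.column_stack([np.ones(len(x)), others])
        beta, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ beta
        denom = np.sum((x[:, j] - x[:, j].mean()) ** 2)
        if denom == 0 or np.sum(resid**2) / denom < 1e-10:
            bad.append(names[j])
    return bad


def _ols_result(
    table: pd.DataFrame,
    dependent: str,
    predictor: str,
    covariates: Tuple[str, ...],
    model: str,
) -> RegressionResult:
    cols = [dependent, predictor, *covariates]
    data = table[cols].dropna()
    n = len(data)
    min_n = len(covariates) + 10
    if n < min_n:
        raise ValueError(f"need n >= {min_n} complete cases, got {n}")
    y = data[dependent].to_numpy(dtype=float)
    x_cols = [predictor, *covariates]
    x = data[x_cols].to_numpy(dtype=float)
    if data[predictor].std(ddof=1) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < x.shape[1] + 1:
        bad = _collinear_columns(x, x_cols)
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    ci = fit.conf_int()
    std_coef = slope * data[predictor].std(ddof=1) / data[dependent].std(ddof=1)
    return RegressionResult(
        dependent=dependent,
        predictor=predictor,
        model=model,
        standardized_coefficient=float(std_coef),
        coefficient=slope,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p_value=float(fit.pvalues[1]),
        covariates=covariates,
        n=n,
    )


def univariate_regression(
    table: pd.DataFrame, dependent: str, predictor: str
) -> RegressionResult:
    """OLS of a morphometry variable on one factor, standardized coefficient.

    The standardized coefficient equals the Pearson correlation between
    dependent and predictor; the reported CI is for the unstandardized slope.
    """
    return _ols_result(table, dependent, predictor, (), "univariate")


def adjusted_regression(
    table: pd.DataFrame,
    dependent: str,
    predictor: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> RegressionResult:
    """OLS of dependent on predictor plus covariates.

    Reports the predictor's standardized partial coefficient; default
    covariates are age, gender, diabetes duration and HbA1c.
    """
    return _ols_result(table, dependent, predictor, tuple(covariates), "adjusted")
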