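"""Statistical procedures for the whole-bone architecture analyses.

Major-axis (MA) regression with a permutation test of the slope,
Breusch-Pagan heteroscedasticity diagnostics, two-way random-effects
average-measures intraclass correlation ICC(2,k) for scorer reliability,
and the categorical-score aggregation rule (mean of numeric scores unless
'n/a' scores are in the majority).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "ICCResult",
    "major_axis",
    "perm_test_slope",
    "breusch_pagan",
    "icc2k",
    "aggregate_scores",
    "propagate_na",
    "normal_probability_points",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    p_perm: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


@dataclass
class ICCResult:
    icc: float
    ms_bones: float
    ms_scorers: float
    ms_error: float
    k: int
    n: int


def _validate_xy(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return x, y


def major_axis(x, y) -> RegressionResult:
    """Major-axis regression: the first principal axis of the bivariate
    covariance (the line minimising perpendicular distances).

    r^2 is the squared Pearson correlation.  If the covariance is zero the
    axis follows the larger-variance coordinate; a vertical axis yields an
    infinite slope.
    """
    x, y = _validate_xy(x, y)
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    if sxx + syy == 0:
        raise ValueError("x and y have zero total variance")
    sxy = np.cov(x, y, ddof=1)[0, 1]
    cov = np.array([[sxx, sxy], [sxy, syy]])
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if abs(v[0]) < 1e-300:
        slope = np.inf
        intercept = np.nan
    else:
        slope = v[1] / v[0]
        intercept = float(np.mean(y) - slope * np.mean(x))
    if sxx == 0 or syy == 0:
        r2 = 0.0
    else:
        r2 = float(sxy**2 / (sxx * syy))
    return RegressionResult(slope=float(slope), intercept=intercept,
                            r_squared=min(r2, 1.0), n=len(x))


def _ma_slope_closed_form(sxx, syy, sxy):
    """MA slope from moments; handles sxy = 0 by axis-of-larger-variance."""
    if sxy == 0:
        return 0.0 if sxx >= syy else np.inf
    return (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)


def perm_test_slope(x, y, n_perm: int = 100_000, seed: int | None = None) -> RegressionResult:
    """Two-sided permutation test that the MA slope is zero.

    y is permuted against x and the MA slope recomputed for every replicate;
    the p-value uses the add-one estimator ``(1 + #extreme) / (n_perm + 1)``.
    Because permuting y leaves both marginal variances fixed, exceedance is
    assessed on |covariance| (equivalently |r|), the statistic that is
    monotone in the evidence against a zero slope for every variance
    configuration -- |slope| itself is not monotone in the association when
    var(y) > var(x), where near-zero covariance drives the major axis
    towards the vertical.
    """
    x, y = _validate_xy(x, y, min_n=5)
    if np.var(y) == 0:
        raise ValueError("y is constant: permutation test undefined")
    res = major_axis(x, y)
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    obs = abs(xc @ yc)
    # vectorised permutations of y
    order = np.argsort(rng.random((n_perm, len(y))), axis=1)
    perm_stat = np.abs(yc[order] @ xc)
    n_extreme = int(np.count_nonzero(perm_stat >= obs - 1e-12))
    res.p_perm = (1.0 + n_extreme) / (n_perm + 1.0)
    res.n_permutations = n_perm
    res.seed = seed
    return res


def breusch_pagan(x, y, studentized: bool = False) -> tuple:
    """Breusch-Pagan test of heteroscedasticity against the predictor.

    Auxiliary regression of the squared OLS residuals on x.  The classical
    (default) statistic is ESS/2 of the regression of u^2 / mean(u^2) on x;
    the studentized (Koenker) form is ``n * R^2`` of the auxiliary
    regression.  Either is referred to chi-square with 1 df.  Returns
    ``(LM, p)``; zero residual variance gives (0, 1).
    """
    x, y = _validate_xy(x, y, min_n=5)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    u2 = (y - X @ beta) ** 2
    s2 = u2.mean()
    if s2 <= 1e-24 * max(float(np.mean(y**2)), 1e-300):
        return 0.0, 1.0
    g = u2 / s2
    gamma, *_ = np.linalg.lstsq(X, g, rcond=None)
    ghat = X @ gamma
    ess = float(np.sum((ghat - g.mean()) ** 2))
    if studentized:
        tss = float(np.sum((g - g.mean()) ** 2))
        r2_aux = 0.0 if tss == 0 else 1.0 - float(np.sum((g - ghat) ** 2)) / tss
        lm = len(x) * r2_aux
    else:
        lm = ess / 2.0
    p = float(sps.chi2.sf(lm, df=1))
    return float(lm), p


def icc2k(table: pd.DataFrame | np.ndarray) -> ICCResult:
    """ICC(2,k): two-way random-effects, average-measures intraclass
    correlation of a bones x scorers table.

    Rows containing any missing score are dropped first (the reliability of
    the scorer mean is defined only for fully scored bones).  From the
    two-way mean squares, ``ICC = (MSR - MSE) / (MSR + (MSC - MSE) / n)``.
    """
    arr = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be 2D (bones x scorers)")
    complete = ~np.isnan(arr).any(axis=1)
    arr = arr[complete]
    n, k = arr.shape
    if n < 2:
        raise ValueError(
            f"ICC requires >= 2 fully scored bones; only {n} available"
        )
    grand = arr.mean()
    row_m = arr.mean(axis=1)
    col_m = arr.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((arr - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    icc = 1.0 if denom == 0 and msr == mse else (msr - mse) / denom
    return ICCResult(icc=float(icc), ms_bones=float(msr), ms_scorers=float(msc),
                     ms_error=float(mse), k=k, n=n)


def aggregate_scores(table: pd.DataFrame) -> pd.Series:
    """Per-bone mean score under the n/a-majority rule.

    A bone's aggregate is the mean of its numeric scores unless 'n/a'
    (missing) scores outnumber numeric ones, in which case the aggregate is
    'n/a' (NaN)."""
    arr = table.to_numpy(dtype=float)
    n_na = np.isnan(arr).sum(axis=1)
    n_num = arr.shape[1] - n_na
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(np.isnan(arr), np.nan, arr), axis=1)
    out = np.where(n_na > n_num, np.nan, means)
    out = np.where(n_num == 0, np.nan, out)
    return pd.Series(out, index=table.index, name="mean_score")


def propagate_na(feature1: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Apply the scoring dependency between features: where a scorer rated
    the cancellous extent (feature 1) as 0, that scorer's entries for the
    dependent feature become 'n/a'."""
    out = other.copy()
    zero = feature1.to_numpy(dtype=float) == 0
    vals = out.to_numpy(dtype=float)
    vals[zero] = np.nan
    return pd.DataFrame(vals, index=out.index, columns=out.columns)


def normal_probability_points(x, y):
    """Ordered OLS residuals against normal quantiles (diagnostic output for
    a visual normality check; no automated decision)."""
    x, y = _validate_xy(x, y)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = np.sort(y - X @ beta)
    n = len(resid)
    q = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    return pd.DataFrame({"normal_quantile": q, "ordered_residual": resid})
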