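"""Cohort-level statistics: hyperglycemia designation, stall rates,
Bland–Altman agreement with exact tolerance-factor confidence intervals,
moment coefficients, group comparisons and regressions.

Conventions follow the study design: a mouse is designated hyperglycemic on
two consecutive weekly glucose readings strictly above 250 mg/dL; group
comparisons use the two-tailed unpaired Student's t test with pooled
variance (a Welch option exists but is off by default); correlation is
reported as the squared Pearson coefficient of an ordinary least-squares
fit; skew is the adjusted Fisher–Pearson standardized moment coefficient;
percentages and flux are rounded to two decimals for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats as sps

__all__ = [
    "BlandAltmanResult",
    "GroupComparison",
    "RegressionSummary",
    "designate_hyperglycemic",
    "stall_rate",
    "tolerance_factor",
    "bland_altman",
    "adjusted_skew",
    "excess_kurtosis",
    "group_compare",
    "regression_r2_slope",
    "age_group",
    "weekly_summary",
]

HYPERGLYCEMIA_CUTOFF_MGDL = 250.0
GLUCOSE_METER_CAP_MGDL = 600.0


@dataclass
class BlandAltmanResult:
    """Agreement of one grader (or the pooled set) against the grader mean."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    n: int
    degenerate: bool = False


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    n: int


def designate_hyperglycemic(glucose_mgdl, cutoff: float = HYPERGLYCEMIA_CUTOFF_MGDL) -> bool:
    """True iff two consecutive weekly readings strictly exceed the cutoff."""
    g = np.atleast_1d(np.asarray(glucose_mgdl, dtype=float))
    if g.size < 2:
        raise ValueError("designation requires >= 2 weekly readings")
    above = g > cutoff
    return bool(np.any(above[:-1] & above[1:]))


def stall_rate(stall_flags) -> float:
    """Percentage of stalled capillary segments, truncated to 2 decimals.

    Truncation (not rounding) matches the study's printed rates, e.g.
    9/589 = 1.528% reported as 1.52%.
    """
    flags = np.atleast_1d(np.asarray(stall_flags))
    if flags.size == 0:
        raise ValueError("stall rate requires >= 1 segment")
    rate = 100.0 * float(np.count_nonzero(flags)) / flags.size
    return np.floor(rate * 100.0 + 1e-9) / 100.0


def tolerance_factor(
    n: int,
    coverage: float = 0.95,
    confidence: float = 0.95,
    method: str = "exact",
) -> float:
    """Two-sided normal tolerance factor k(n, coverage, confidence).

    ``xbar +/- k s`` covers at least the ``coverage`` fraction of a normal
    population with probability ``confidence``.  The exact factor solves

        integral_0^inf 2 phi(z) * P[chi2_{n-1} >= (n-1) r(z)^2 / k^2] dz
            = confidence,

    where ``r(z)^2`` is the ``coverage`` quantile of the noncentral
    chi-square with 1 df and noncentrality ``z^2 / n`` (the squared
    standardized offset of the sample mean).  ``method='howe'`` gives the
    common closed-form approximation.
    """
    if n < 2:
        raise ValueError("tolerance factor requires n >= 2")
    if not (0 < coverage < 1 and 0 < confidence < 1):
        raise ValueError("coverage and confidence must lie in (0, 1)")
    if method == "howe":
        z = sps.norm.ppf((1 + coverage) / 2)
        chi = sps.chi2.ppf(1 - confidence, n - 1)
        return float(z * np.sqrt((n - 1) * (1 + 1.0 / n) / chi))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'howe'")

    df = n - 1

    def conf_of_k(k: float) -> float:
        def integrand(z: float) -> float:
            r2 = sps.ncx2.ppf(coverage, 1, z * z / n)
            return 2 * sps.norm.pdf(z) * sps.chi2.sf(df * r2 / (k * k), df)

        val, _ = integrate.quad(integrand, 0, 8.0, limit=200)
        return val

    lo, hi = 1e-3, 1.0
    while conf_of_k(hi) < confidence:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("tolerance factor bracketing failed")
    return float(optimize.brentq(lambda k: conf_of_k(k) - confidence, lo, hi, xtol=1e-8))


def _ba_one(d: np.ndarray, coverage: float, confidence: float, method: str) -> BlandAltmanResult:
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if n > 1 else 0.0
    z = sps.norm.ppf((1 + coverage) / 2)  # 1.96 for 95% limits
    loa_low, loa_high = bias - z * sd, bias + z * sd
    if sd == 0:
        zero = (bias, bias)
        return BlandAltmanResult(
            bias=bias, sd_diff=0.0, loa_low=bias, loa_high=bias,
            ci_bias=zero, ci_loa_low=zero, ci_loa_high=zero,
            n=n, degenerate=True,
        )
    tcrit = sps.t.ppf(1 - (1 - confidence) / 2, n - 1)
    ci_bias = (bias - tcrit * sd / np.sqrt(n), bias + tcrit * sd / np.sqrt(n))
    # two-sided tolerance factors at the lower/upper confidence quantiles
    alpha = 1 - confidence
    k_lo = tolerance_factor(n, coverage, alpha / 2, method=method)
    k_hi = tolerance_factor(n, coverage, 1 - alpha / 2, method=method)
    ci_loa_high = (bias + k_lo * sd, bias + k_hi * sd)
    ci_loa_low = (bias - k_hi * sd, bias - k_lo * sd)
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, loa_low=loa_low, loa_high=loa_high,
        ci_bias=ci_bias, ci_loa_low=ci_loa_low, ci_loa_high=ci_loa_high,
        n=n,
    )


def bland_altman(
    grader_counts,
    coverage: float = 0.95,
    confidence: float = 0.95,
    method: str = "exact",
) -> dict:
    """Bland–Altman agreement of each grader against the grader-mean truth.

    ``grader_counts`` is an ``(n_capillaries, n_graders)`` table (DataFrame
    columns = graders, or a 2-D array).  With no established ground truth,
    the per-capillary mean across graders serves as truth; differences are
    plain ``grader - truth`` in cells/s.  Returns a dict keyed by grader
    label plus ``"pooled"`` (all graders' differences combined).  Limits of
    agreement are ``bias +/- 1.96 sd``; their confidence intervals come from
    exact two-sided normal tolerance factors evaluated at the lower and
    upper confidence quantiles.
    """
    if isinstance(grader_counts, pd.DataFrame):
        labels = [str(c) for c in grader_counts.columns]
        table = grader_counts.to_numpy(dtype=float)
    else:
        table = np.asarray(grader_counts, dtype=float)
        labels = [f"grader{j + 1}" for j in range(table.shape[1])]
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 graders")
    if table.shape[0] < 3:
        raise ValueError("need >= 3 capillaries")
    if not np.all(np.isfinite(table)):
        raise ValueError("missing cells are not allowed")
    truth = table.mean(axis=1, keepdims=True)
    diffs = table - truth
    out = {
        labels[j]: _ba_one(diffs[:, j], coverage, confidence, method)
        for j in range(table.shape[1])
    }
    out["pooled"] = _ba_one(diffs.ravel(), coverage, confidence, method)
    return out


def adjusted_skew(sample) -> float:
    """Adjusted Fisher–Pearson standardized moment coefficient.

    ``G1 = n^2 / ((n-1)(n-2)) * m3 / s^3`` with ``m3`` the third central
    moment and ``s`` the sample SD.
    """
    x = np.atleast_1d(np.asarray(sample, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("skew requires n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("skew undefined for zero variance")
    m3 = np.mean((x - x.mean()) ** 3)
    return float(n * n / ((n - 1) * (n - 2)) * m3 / s**3)


def excess_kurtosis(sample) -> float:
    """Bias-adjusted excess kurtosis (G2), 0 for a normal population."""
    x = np.atleast_1d(np.asarray(sample, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("kurtosis requires n >= 4")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("kurtosis undefined for zero variance")
    m4 = np.sum((x - x.mean()) ** 4)
    g2 = (n + 1) * n / ((n - 1) * (n - 2) * (n - 3)) * m4 / s**4
    return float(g2 - 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


def group_compare(a, b, equal_var: bool = True) -> GroupComparison:
    """Two-tailed unpaired Student's t test (pooled variance by default)."""
    xa = np.atleast_1d(np.asarray(a, dtype=float))
    xb = np.atleast_1d(np.asarray(b, dtype=float))
    if xa.size < 2 or xb.size < 2:
        raise ValueError("both samples need n >= 2")
    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
        if xa.mean() == xb.mean():
            return GroupComparison(
                float(xa.mean()), 0.0, xa.size,
                float(xb.mean()), 0.0, xb.size, 0.0, 1.0,
            )
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
    return GroupComparison(
        mean_a=float(xa.mean()), sd_a=float(xa.std(ddof=1)), n_a=int(xa.size),
        mean_b=float(xb.mean()), sd_b=float(xb.std(ddof=1)), n_b=int(xb.size),
        t=float(t), p=float(p),
    )


def regression_r2_slope(x, y) -> RegressionSummary:
    """OLS slope/intercept with R^2 = squared Pearson correlation."""
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    yv = np.atleast_1d(np.asarray(y, dtype=float))
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("regression requires paired samples with n >= 3")
    if np.var(xv) == 0:
        raise ValueError("regression undefined: var(x) = 0")
    res = sps.linregress(xv, yv)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=int(xv.size),
    )


def age_group(week: int) -> str:
    """'young' for postnatal weeks 5-12, 'mature' for 13 onward."""
    if week < 5:
        raise ValueError("weeks before 5 fall outside the study epoch")
    return "young" if week <= 12 else "mature"


def weekly_summary(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    week_col: str = "week",
) -> pd.DataFrame:
    """Per-week, per-group mean +/- SD of one cohort variable.

    Weeks without data are simply absent from the output.  Row order of the
    input does not affect the result.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    if variable not in cohort.columns:
        raise ValueError(f"unknown variable {variable!r}")
    grouped = (
        cohort.groupby([group_col, week_col], sort=True)[variable]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
        .reset_index()
    )
    return grouped
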