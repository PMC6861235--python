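"""Trend estimation, cross-parameter correlation, and period-ratio comparisons.

All significance statements are per-series two-sided tests at the 95% level
(Student-t, n-2 degrees of freedom for regressions); no multiple-testing
correction is applied, and that choice is recorded in the output metadata of
the pipeline tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calendars import AnnualSeries, align_years
from .exceptions import InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class TrendResult:
    """OLS slope with 95% confidence half-width, R^2 and significance flag."""

    slope: float
    ci95_half_width: float
    r2: float
    n_years: int
    significant: bool
    intercept: float
    units: str = ""
    degenerate: bool = False  # zero-variance series: R^2 defined as 0

    def summary(self) -> str:
        star = "*" if self.significant else ""
        return (f"slope = {self.slope:+.4g} +/- {self.ci95_half_width:.4g} "
                f"{self.units}/yr{star}  (R^2 = {self.r2:.2f}, n = {self.n_years})")


def _ols(values: np.ndarray, years: np.ndarray) -> tuple[float, float, float, float]:
    """slope, intercept, slope standard error, R^2 (R^2 := 0 for flat y)."""
    t = years - years.mean()
    stt = float(t @ t)
    yc = values - values.mean()
    slope = float(t @ yc) / stt
    intercept = float(values.mean() - slope * years.mean())
    resid = yc - slope * t
    sse = float(resid @ resid)
    sst = float(yc @ yc)
    n = values.size
    se = np.sqrt(max(sse, 0.0) / (n - 2) / stt) if n > 2 else np.nan
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return slope, intercept, se, r2


def linear_trend(series: AnnualSeries, units: str | None = None) -> TrendResult:
    """Linear trend of an annual series with a Student-t 95% confidence interval."""
    years = series.years.astype(float)
    values = series.values
    finite = np.isfinite(values)
    years, values = years[finite], values[finite]
    if values.size < 3:
        raise InsufficientDataError(f"linear_trend needs >=3 years, got {values.size}")
    slope, intercept, se, r2 = _ols(values, years)
    tcrit = stats.t.ppf(0.975, values.size - 2)
    half = float(tcrit * se)
    degenerate = float(np.ptp(values)) == 0.0
    return TrendResult(slope=slope, ci95_half_width=half, r2=max(0.0, min(1.0, r2)),
                       n_years=values.size, significant=abs(slope) > half,
                       intercept=intercept,
                       units=units if units is not None else series.units,
                       degenerate=degenerate)


@dataclass
class RelativeTrend:
    """Trend as percent of the series mean per year, CI scaled identically."""

    percent_per_year: float
    ci95_half_width: float
    base_value: float
    base: str
    significant: bool


def relative_trend(trend: TrendResult, series: AnnualSeries,
                   base: str = "mean") -> RelativeTrend:
    """Normalise an absolute trend to %/yr of the series level.

    ``base`` selects the normaliser: the series mean (default), the first
    year's value, or the fitted line's value in the first year.
    """
    values = series.values[np.isfinite(series.values)]
    if base == "mean":
        denom = float(values.mean())
    elif base == "first":
        denom = float(values[0])
    elif base == "fitted_start":
        denom = float(trend.intercept + trend.slope * series.years.min())
    else:
        raise ValueError(f"unknown base {base!r}")
    if denom <= 0:
        raise InsufficientDataError(
            f"relative trend undefined: {base} of the series is {denom:.4g} <= 0")
    scale = 100.0 / denom
    return RelativeTrend(percent_per_year=trend.slope * scale,
                         ci95_half_width=trend.ci95_half_width * scale,
                         base_value=denom, base=base,
                         significant=trend.significant)


@dataclass
class CorrelationResult:
    r: float
    r2: float
    p_value: float
    significant: bool
    n_years: int


def correlate(a: AnnualSeries, b: AnnualSeries) -> CorrelationResult:
    """Pearson R^2 between two annual series on their common fire years.

    Significance is the two-sided t-test on r with n-2 degrees of freedom at
    the 95% level.
    """
    _, av, bv = align_years(a, b)
    finite = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[finite], bv[finite]
    if av.size < 3:
        raise InsufficientDataError(f"correlate needs >=3 common years, got {av.size}")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return CorrelationResult(r=0.0, r2=0.0, p_value=1.0, significant=False,
                                 n_years=av.size)
    r, p = stats.pearsonr(av, bv)
    return CorrelationResult(r=float(r), r2=float(r) ** 2, p_value=float(p),
                             significant=bool(p < 0.05), n_years=av.size)


def ratio_series(fp: AnnualSeries, deforestation: AnnualSeries) -> AnnualSeries:
    """Elementwise fire-parameter-to-deforestation ratio on common fire years.

    Years with zero or negative deforestation are set missing and logged.
    """
    common, fv, dv = align_years(fp, deforestation)
    bad = ~(dv > 0)
    if bad.any():
        logger.warning("ratio_series: %d years with non-positive deforestation set missing",
                       int(bad.sum()))
    out = np.where(bad, np.nan, fv / np.where(bad, np.nan, dv))
    units = f"{fp.units} / {deforestation.units}".strip(" /")
    return AnnualSeries(region=fp.region, variable=f"{fp.variable}:{deforestation.variable}",
                        units=units, years=common, values=out, calendar=fp.calendar)


@dataclass
class PeriodComparison:
    """Mean ratio per period with 95% CIs and the between-period factor."""

    period1_mean: float
    period2_mean: float
    period1_ci95: float
    period2_ci95: float
    factor: float
    factor_ci95: float
    significant: bool
    n1: int
    n2: int
    method: str = "factor CI excludes 1 (delta method, t df=n1+n2-2)"


def _period_stats(values: np.ndarray) -> tuple[float, float, float, int]:
    """mean, SEM, t-based 95% half-width, n."""
    n = values.size
    mean = float(values.mean())
    if n > 1:
        sem = float(values.std(ddof=1) / np.sqrt(n))
        half = float(stats.t.ppf(0.975, n - 1) * sem)
    else:
        sem, half = 0.0, 0.0
    return mean, sem, half, n


def period_comparison(ratio: AnnualSeries, period1: tuple[int, int],
                      period2: tuple[int, int]) -> PeriodComparison:
    """Compare mean ratios between two year ranges (inclusive).

    Each period gets a 95% CI from the standard error of its mean; the
    Period II / Period I factor gets a first-order (delta-method) CI, and the
    comparison is significant when that CI excludes 1.
    """
    s = ratio.to_series()
    def pick(lo_hi):
        lo, hi = lo_hi
        v = s.loc[(s.index >= lo) & (s.index <= hi)].to_numpy()
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise InsufficientDataError(f"period {lo}-{hi} has fewer than 2 usable years")
        return v
    v1, v2 = pick(period1), pick(period2)
    m1, sem1, h1, n1 = _period_stats(v1)
    m2, sem2, h2, n2 = _period_stats(v2)
    if m1 == 0:
        raise InsufficientDataError("period 1 mean is zero; factor undefined")
    factor = m2 / m1
    rel_var = (sem1 / m1) ** 2 + (sem2 / m2) ** 2 if m2 != 0 else (sem1 / m1) ** 2
    se_factor = abs(factor) * np.sqrt(rel_var)
    tcrit = stats.t.ppf(0.975, n1 + n2 - 2)
    half = float(tcrit * se_factor)
    significant = bool(factor - half > 1.0 or factor + half < 1.0)
    return PeriodComparison(period1_mean=m1, period2_mean=m2, period1_ci95=h1,
                            period2_ci95=h2, factor=float(factor), factor_ci95=half,
                            significant=significant, n1=n1, n2=n2)
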