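"""Per-grid-cell precipitation adjustment of annual fire parameters.

The method removes precipitation-driven interannual variability (IAV) from an
annual fire parameter (fire count, burned area, AOD or fire-related CO2
emissions) so that the residual trend reflects non-meteorological drivers:

1. Antecedent precipitation ``AP_T(y)`` = mean monthly precipitation over the
   ``T`` months immediately preceding the burning-season peak month of fire
   year ``y``, for window lengths ``T`` = 1..24.
2. Both ``AP_T`` and the fire parameter ``FP`` are split into a fitted
   linear-in-year trend and residual IAV by ordinary least squares.
3. For each ``T`` a no-intercept regression ``FP_IAV = b0 * AP_IAV + eps`` is
   fitted; the window maximising the absolute Pearson correlation between the
   two IAV series is selected per cell (ties break to the shortest window).
4. The precipitation-induced series is ``b0 * AP`` with the FULL (un-detrended)
   antecedent precipitation, and the adjusted series is ``FP - b0 * AP``.

The scalar functions operate on single series; :class:`PrecipAdjustmentModel`
applies the fit over a whole grid (vectorised, with a per-cell fallback when
the precipitation record has gaps) and aggregates adjusted regional series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calendars import AnalysisCalendar, AnnualSeries, annualize, fire_year_of
from .exceptions import (AlignmentError, GridError, InsufficientDataError,
                         UndefinedFitError)
from .grids import DEFAULT_AGGREGATION, GridSpec, MonthlyField, RegionMask

logger = logging.getLogger(__name__)

MAX_WINDOW_MONTHS = 24


# ---------------------------------------------------------------------------
# Scalar building blocks
# ---------------------------------------------------------------------------

@dataclass
class DetrendResult:
    """Linear-in-year trend plus interannual-variability residuals."""

    years: np.ndarray
    trend_component: np.ndarray
    iav_component: np.ndarray
    slope: float
    intercept: float


def detrend(values, years) -> DetrendResult:
    """OLS of value on year; trend = fitted line, IAV = residuals.

    The decomposition is exact: trend + IAV reproduces the input, and the IAV
    sums to zero (OLS with intercept).
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    if values.size < 3:
        raise InsufficientDataError(f"detrend needs >=3 years, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise InsufficientDataError("detrend requires a gap-free series")
    if np.ptp(years) == 0:
        raise UndefinedFitError("years axis is constant")
    t = years - years.mean()
    slope = float(t @ (values - values.mean()) / (t @ t))
    intercept = float(values.mean() - slope * years.mean())
    trend = intercept + slope * years
    return DetrendResult(years=years.astype(int), trend_component=trend,
                         iav_component=values - trend, slope=slope, intercept=intercept)


def antecedent_precip(
    P: pd.Series,
    calendar: AnalysisCalendar,
    T: int,
    years,
) -> pd.Series:
    """Mean monthly precipitation over the T months before each year's peak month.

    Years whose antecedent window is not fully covered (or contains missing
    months) are dropped with a warning.
    """
    if not 1 <= T <= MAX_WINDOW_MONTHS:
        raise ValueError(f"T must be in 1..{MAX_WINDOW_MONTHS}")
    if not isinstance(P.index, pd.PeriodIndex):
        raise ValueError("P must be indexed by a monthly PeriodIndex")
    pos = {p: i for i, p in enumerate(P.index)}
    values = P.to_numpy(dtype=float)
    out_years, out_vals, dropped = [], [], []
    for y in years:
        peak = pd.Period(f"{int(y)}-{calendar.peak_month:02d}", freq="M")
        window = [peak - k for k in range(1, T + 1)]
        if any(p not in pos for p in window):
            dropped.append(int(y))
            continue
        w = values[[pos[p] for p in window]]
        if not np.all(np.isfinite(w)):
            dropped.append(int(y))
            continue
        out_years.append(int(y))
        out_vals.append(w.mean())
    if dropped:
        warnings.warn(f"antecedent_precip(T={T}): dropped years {dropped} "
                      "with incomplete antecedent windows", stacklevel=2)
    return pd.Series(out_vals, index=out_years, name=f"AP(T={T})")


@dataclass
class NoInterceptFit:
    b0: float
    r: float
    residuals: np.ndarray


def fit_no_intercept(fp_iav, ap_iav) -> NoInterceptFit:
    """No-intercept OLS of FP_IAV on AP_IAV: b0 = sum(xy)/sum(x^2).

    ``r`` is the Pearson correlation of the two IAV series (defined as 0 when
    the fire-parameter IAV has zero variance — a perfectly linear series has
    nothing left to couple).
    """
    x = np.asarray(ap_iav, dtype=float)
    y = np.asarray(fp_iav, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need equal-length IAV series with >=3 years")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise UndefinedFitError("AP_IAV is identically zero; no-intercept fit undefined")
    b0 = float(x @ y) / sxx
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    r = float((xc @ yc) / denom) if denom > 0 else 0.0
    return NoInterceptFit(b0=b0, r=r, residuals=y - b0 * x)


@dataclass
class CellFit:
    """Selected antecedent window and coupling for one grid cell."""

    T_opt: int
    b0: float
    r: float
    residuals: np.ndarray
    years: np.ndarray
    candidate_r: np.ndarray   # |.| maximised; NaN where a window was undefined
    candidate_b0: np.ndarray
    fp_detrend: DetrendResult
    ap_detrend: DetrendResult


def select_window(
    P: pd.Series,
    fp: pd.Series,
    calendar: AnalysisCalendar | None = None,
    max_window: int = MAX_WINDOW_MONTHS,
) -> CellFit:
    """Search the 1..24-month antecedent windows for the strongest coupling.

    ``fp`` is an annual series indexed by fire-year labels.  For each window
    length the AP series is built, both series are detrended, and a
    no-intercept regression is fitted on the IAV components; the window with
    maximum |Pearson r| wins, ties going to the shortest window.
    """
    calendar = calendar or AnalysisCalendar()
    fp_years = np.asarray(fp.index, dtype=int)
    candidate_r = np.full(max_window, np.nan)
    candidate_b0 = np.full(max_window, np.nan)
    fits: dict[int, tuple[NoInterceptFit, np.ndarray, DetrendResult, DetrendResult]] = {}
    for T in range(1, max_window + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ap = antecedent_precip(P, calendar, T, fp_years)
        common = np.intersect1d(fp_years, np.asarray(ap.index, dtype=int))
        if common.size < 3:
            continue
        fp_vals = fp.loc[common].to_numpy(dtype=float)
        ap_vals = ap.loc[common].to_numpy(dtype=float)
        if not np.all(np.isfinite(fp_vals)):
            continue
        fp_dt = detrend(fp_vals, common)
        ap_dt = detrend(ap_vals, common)
        try:
            f = fit_no_intercept(fp_dt.iav_component, ap_dt.iav_component)
        except UndefinedFitError:
            continue
        candidate_r[T - 1] = f.r
        candidate_b0[T - 1] = f.b0
        fits[T] = (f, common, fp_dt, ap_dt)
    if not fits:
        raise UndefinedFitError("all antecedent windows undefined for this cell")
    abs_r = np.where(np.isnan(candidate_r), -np.inf, np.abs(candidate_r))
    T_opt = int(np.argmax(abs_r)) + 1  # argmax returns the first (smallest T) on ties
    f, common, fp_dt, ap_dt = fits[T_opt]
    return CellFit(T_opt=T_opt, b0=f.b0, r=f.r, residuals=f.residuals, years=common,
                   candidate_r=candidate_r, candidate_b0=candidate_b0,
                   fp_detrend=fp_dt, ap_detrend=ap_dt)


@dataclass
class AdjustedSeries:
    """Observed, precipitation-induced, and adjusted annual values."""

    years: np.ndarray
    observed: np.ndarray
    precipitation_induced: np.ndarray
    adjusted: np.ndarray


def precip_induced(fit: CellFit, ap_full: pd.Series) -> pd.Series:
    """Precipitation-induced series b0 * AP using the full (un-detrended) AP."""
    return fit.b0 * ap_full


def adjust(fp: pd.Series, fp_precipitation: pd.Series,
           recenter: bool = False, clip_nonnegative: bool = False) -> AdjustedSeries:
    """Adjusted series = observed - precipitation-induced, elementwise.

    By default nothing more is done: adjusted values are statistical
    constructs and may go negative even for count-like variables, and the
    full (un-detrended) induced component shifts the mean level.  The
    ``recenter`` extension adds back the observed-minus-adjusted mean;
    ``clip_nonnegative`` floors the result at zero.  Both default off.
    """
    ya = np.asarray(fp.index, dtype=int)
    yb = np.asarray(fp_precipitation.index, dtype=int)
    if not np.array_equal(ya, yb):
        raise AlignmentError("observed and precipitation-induced series have different year labels")
    obs = fp.to_numpy(dtype=float)
    ind = fp_precipitation.to_numpy(dtype=float)
    adj = obs - ind
    if recenter:
        adj = adj + (obs.mean() - adj.mean())
    if clip_nonnegative:
        adj = np.maximum(adj, 0.0)
    return AdjustedSeries(years=ya, observed=obs, precipitation_induced=ind,
                          adjusted=adj)


def adjust_cell(
    P: pd.Series,
    fp: pd.Series,
    calendar: AnalysisCalendar | None = None,
    max_window: int = MAX_WINDOW_MONTHS,
) -> tuple[CellFit, AdjustedSeries]:
    """Full single-cell pathway: window search, induced series, adjustment."""
    calendar = calendar or AnalysisCalendar()
    fit = select_window(P, fp, calendar, max_window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap_full = antecedent_precip(P, calendar, fit.T_opt, fit.years)
    induced = precip_induced(fit, ap_full)
    return fit, adjust(fp.loc[fit.years], induced)


# ---------------------------------------------------------------------------
# Grid-level model (statsmodels-style Model / Results pair)
# ---------------------------------------------------------------------------

def _annualize_lattice(field_: MonthlyField, calendar: AnalysisCalendar,
                       statistic: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell annual values over complete fire years: (years, lattice[year,row,col])."""
    periods = field_.periods
    labels = np.array([fire_year_of(calendar, p.year, p.month) for p in periods])
    years = [int(y) for y in np.unique(labels) if (labels == y).sum() == 12]
    if not years:
        raise InsufficientDataError("no complete fire year in the field")
    out = np.empty((len(years),) + field_.grid.shape)
    for i, y in enumerate(years):
        block = field_.values[labels == y]
        out[i] = block.sum(axis=0) if statistic == "sum" else block.mean(axis=0)
    return np.array(years), out


class PrecipAdjustmentModel:
    """Grid-wide precipitation adjustment of one fire parameter.

    Parameters
    ----------
    precip : MonthlyField
        Monthly precipitation (mm/month), co-registered with ``fire`` and
        extending at least ``max_window`` months before the first fire year's
        peak month (a two-year head start covers every window).
    fire : MonthlyField
        The fire parameter to adjust (counts, burned %, AOD, or Tg CO2).
    mask : RegionMask
        Region layers for aggregated output series.
    calendar : AnalysisCalendar
    statistic : {'sum', 'mean'}
        Per-cell annualisation of the fire parameter over each fire year.
    """

    def __init__(self, precip: MonthlyField, fire: MonthlyField, mask: RegionMask,
                 calendar: AnalysisCalendar | None = None, statistic: str = "sum",
                 max_window: int = MAX_WINDOW_MONTHS,
                 years: tuple[int, int] | None = None,
                 recenter_adjusted: bool = False, clip_nonnegative: bool = False):
        if not (precip.grid == fire.grid):
            raise GridError("precipitation and fire parameter are on different grids "
                            "(regrid the 0.25 deg precipitation up to 0.50 deg first)")
        if not (mask.grid == fire.grid):
            raise GridError("mask grid does not match the data grid")
        self.precip = precip
        self.fire = fire
        self.mask = mask
        self.calendar = calendar or AnalysisCalendar()
        self.statistic = statistic
        self.max_window = max_window
        self.years_limit = years
        self.recenter_adjusted = recenter_adjusted
        self.clip_nonnegative = clip_nonnegative

    def _postprocess(self, observed: np.ndarray, adjusted: np.ndarray) -> np.ndarray:
        if self.recenter_adjusted:
            adjusted = adjusted + (observed.mean(axis=0) - adjusted.mean(axis=0))[None]
        if self.clip_nonnegative:
            adjusted = np.maximum(adjusted, 0.0)
        return adjusted

    def fit(self) -> "PrecipAdjustmentResults":
        cal = self.calendar
        years, fp_lat = _annualize_lattice(self.fire, cal, self.statistic)
        if self.years_limit is not None:
            lo, hi = self.years_limit
            keep = (years >= lo) & (years <= hi)
            years, fp_lat = years[keep], fp_lat[keep]
        n_years = years.size
        if n_years < 3:
            raise InsufficientDataError("need >=3 complete fire years")
        nr, nc = self.fire.grid.shape

        p_ok = np.all(np.isfinite(self.precip.values))
        ap_all = None
        if p_ok:
            ap_all = self._ap_stack(years)  # (24, n_years, nr, nc) or None if short record
        if ap_all is None:
            return self._fit_percell(years, fp_lat)

        # Vectorised path: detrend everything with one projection matrix.
        t = years - years.mean()
        stt = float(t @ t)

        def iav(v, axis_time):
            # residuals of OLS on year along axis_time (axis has length n_years)
            v = np.moveaxis(v, axis_time, 0)
            mean = v.mean(axis=0)
            slope = np.tensordot(t, v - mean, axes=(0, 0)) / stt
            resid = v - mean - t[(...,) + (None,) * (v.ndim - 1)] * slope
            return np.moveaxis(resid, 0, axis_time)

        fp_iav = iav(fp_lat, 0)                       # (n_years, nr, nc)
        ap_iav = iav(ap_all, 1)                       # (24, n_years, nr, nc)

        sxx = np.einsum("wtij,wtij->wij", ap_iav, ap_iav)
        sxy = np.einsum("wtij,tij->wij", ap_iav, fp_iav)
        syy = np.einsum("tij,tij->ij", fp_iav, fp_iav)
        with np.errstate(invalid="ignore", divide="ignore"):
            b0_all = sxy / sxx
            r_all = sxy / np.sqrt(sxx * syy[None])
        r_all = np.where(syy[None] == 0, 0.0, r_all)          # flat FP: nothing to couple
        undefined = sxx == 0
        r_all = np.where(undefined, np.nan, r_all)
        score = np.where(np.isnan(r_all), -np.inf, np.abs(r_all))
        T_opt = score.argmax(axis=0) + 1                      # ties -> smallest T
        # zero-variance FP cells (never any fire) pass through unadjusted
        unadjustable = ~np.isfinite(score.max(axis=0)) | (syy == 0)

        ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        w = T_opt - 1
        b0 = b0_all[w, ii, jj]
        r = r_all[w, ii, jj]
        ap_sel = ap_all[w, :, ii, jj]                         # (nr, nc, n_years)
        induced = np.moveaxis(b0[..., None] * ap_sel, -1, 0)  # (n_years, nr, nc)
        b0 = np.where(unadjustable, 0.0, b0)
        r = np.where(unadjustable, np.nan, r)
        T_map = np.where(unadjustable, 0, T_opt)
        induced[:, unadjustable] = 0.0
        adjusted = self._postprocess(fp_lat, fp_lat - induced)
        return PrecipAdjustmentResults(
            model=self, years=years, observed=fp_lat, induced=induced,
            adjusted=adjusted, T_opt=T_map, b0=b0, r=r, unadjustable=unadjustable,
            candidate_r=r_all,
        )

    def _ap_stack(self, years: np.ndarray) -> np.ndarray | None:
        """AP for every window length: array (max_window, n_years, nrow, ncol)."""
        P = self.precip
        csum = np.concatenate([np.zeros((1,) + P.grid.shape),
                               np.cumsum(P.values, axis=0)], axis=0)
        try:
            peak_idx = np.array([P.time_index_of(int(y), self.calendar.peak_month)
                                 for y in years])
        except IndexError:
            return None
        if peak_idx.min() < self.max_window:
            return None
        out = np.empty((self.max_window, years.size) + P.grid.shape)
        for T in range(1, self.max_window + 1):
            out[T - 1] = (csum[peak_idx] - csum[peak_idx - T]) / T
        return out

    def _fit_percell(self, years: np.ndarray, fp_lat: np.ndarray) -> "PrecipAdjustmentResults":
        """Per-cell fallback used when the precipitation record has gaps."""
        nr, nc = self.fire.grid.shape
        n_years = years.size
        T_map = np.zeros((nr, nc), dtype=int)
        b0 = np.zeros((nr, nc))
        r = np.full((nr, nc), np.nan)
        unadjustable = np.zeros((nr, nc), dtype=bool)
        induced = np.zeros((n_years, nr, nc))
        cand = np.full((self.max_window, nr, nc), np.nan)
        for i in range(nr):
            for j in range(nc):
                fp = pd.Series(fp_lat[:, i, j], index=years)
                vals = fp.to_numpy()
                if not np.all(np.isfinite(vals)) or np.ptp(vals) == 0:
                    unadjustable[i, j] = True
                    continue
                try:
                    fit, adj = adjust_cell(self.precip.cell_series(i, j), fp,
                                           self.calendar, self.max_window)
                except (UndefinedFitError, InsufficientDataError):
                    unadjustable[i, j] = True
                    continue
                if not np.array_equal(fit.years, years):
                    unadjustable[i, j] = True  # incomplete AP coverage: pass through
                    continue
                T_map[i, j] = fit.T_opt
                b0[i, j] = fit.b0
                r[i, j] = fit.r
                cand[:, i, j] = fit.candidate_r
                induced[:, i, j] = adj.precipitation_induced
        adjusted = self._postprocess(fp_lat, fp_lat - induced)
        n_flagged = int(unadjustable.sum())
        if n_flagged:
            logger.info("precip adjustment: %d/%d cells passed through unadjusted",
                        n_flagged, nr * nc)
        return PrecipAdjustmentResults(model=self, years=years, observed=fp_lat,
                                       induced=induced, adjusted=adjusted, T_opt=T_map,
                                       b0=b0, r=r, unadjustable=unadjustable,
                                       candidate_r=cand)


@dataclass
class PrecipAdjustmentResults:
    """Fitted per-cell adjustment parameters and the adjusted annual lattice."""

    model: PrecipAdjustmentModel
    years: np.ndarray
    observed: np.ndarray     # (n_years, nrow, ncol)
    induced: np.ndarray
    adjusted: np.ndarray
    T_opt: np.ndarray        # (nrow, ncol), 0 where unadjustable
    b0: np.ndarray
    r: np.ndarray
    unadjustable: np.ndarray
    candidate_r: np.ndarray  # (max_window, nrow, ncol)

    def regional_series(self, region: str, method: str | None = None) -> pd.DataFrame:
        """Aggregate observed/induced/adjusted per-cell annual values over a region."""
        mask = self.model.mask
        layer = mask.layer(region)
        if method is None:
            method = DEFAULT_AGGREGATION.get(self.model.fire.variable, "sum")
        def agg(lat: np.ndarray) -> np.ndarray:
            v = lat[:, layer]
            if method == "sum":
                return v.sum(axis=1)
            if method == "mean":
                return v.mean(axis=1)
            if method == "area_percent":
                w = mask.cell_area[layer]
                return (v * w).sum(axis=1) / w.sum()
            raise ValueError(f"unknown aggregation method {method!r}")
        return pd.DataFrame({
            "fire_year": self.years,
            "observed": agg(self.observed),
            "precip_induced": agg(self.induced),
            "adjusted": agg(self.adjusted),
        }).set_index("fire_year")

    def regional_annual_series(self, region: str, which: str = "adjusted",
                               method: str | None = None) -> AnnualSeries:
        df = self.regional_series(region, method)
        suffix = "" if which == "observed" else f" ({which})"
        return AnnualSeries(region=region, variable=self.model.fire.variable + suffix,
                            units=self.model.fire.units, years=self.years,
                            values=df[which].to_numpy(), calendar=self.model.calendar)

    def summary(self) -> str:
        n = self.T_opt.size
        n_bad = int(self.unadjustable.sum())
        good = ~self.unadjustable
        lines = [
            "Precipitation adjustment results",
            "================================",
            f"variable:            {self.model.fire.variable} [{self.model.fire.units}]",
            f"grid:                {self.model.fire.grid.shape} at "
            f"{self.model.fire.grid.resolution} deg",
            f"fire years:          {self.years.min()}-{self.years.max()} (n={self.years.size})",
            f"cells fitted:        {n - n_bad}/{n} ({n_bad} passed through unadjusted)",
        ]
        if good.any():
            lines += [
                f"window T_opt:        median {np.median(self.T_opt[good]):.0f} months, "
                f"range {self.T_opt[good].min()}-{self.T_opt[good].max()}",
                f"coupling b0:         median {np.median(self.b0[good]):+.4g}",
                f"|r| at T_opt:        median {np.nanmedian(np.abs(self.r[good])):.3f}",
            ]
        return "\n".join(lines)
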