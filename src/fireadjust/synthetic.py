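"""Seeded synthetic gridded data with known ground truth.

The generator emulates the study conditions of the regional analysis:

* a seasonal precipitation cycle with a broad December-April wet season
  peaking in March above 300 mm/month and a June-September dry season,
  interannual anomalies shared across the months of a fire year (and across
  the grid, mimicking region-wide wet/dry years), month-level jitter, and an
  optional linear trend — with a 24-month head start before the first fire
  year so every antecedent window is defined;
* fire parameters built by inverting the adjustment model itself:
  ``FP(y) = baseline + trend*(y - y0) + b0_true * AP_IAV(T_true, y) + noise``
  per cell, so parameter recovery is a sharp test of the estimator;
* a deforestation series that rises to a 2004 peak, declines steeply to 2009,
  then stabilises (reporting-year labelled);
* point fire detections with uniform in-cell positions and uniform
  confidence in [60, 100], so a confidence >= 80 filter keeps ~50%.

Month-level jitter is not cosmetic: the interannual anomaly is constant
within a fire year, so without jitter every antecedent window contained in a
single fire year would be perfectly collinear and the window length
unidentifiable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .calendars import AnalysisCalendar, AnnualSeries, fire_year_of
from .grids import AnnualRegionalTable, GridSpec, MonthlyField, RegionMask


def default_grid(resolution: float = 0.25, n: int = 10) -> GridSpec:
    """A small n x n grid in the south-western Amazon."""
    return GridSpec(resolution=resolution, lat_min=-12.0, lat_max=-12.0 + n * resolution,
                    lon_min=-64.0, lon_max=-64.0 + n * resolution)


@dataclass
class PrecipConfig:
    annual_mean: float = 175.0        # mm/month, annual-mean level
    seasonal_amplitude: float = 140.0  # mm/month; March peak ~315, September ~35
    wet_peak_month: int = 3
    iav_sd: float = 15.0              # mm/month, fire-year anomaly (region-wide)
    jitter_sd: float = 30.0           # mm/month, per cell-month
    trend: float = 0.0                # mm/month per fire year


@dataclass
class FireConfig:
    variable: str = "fire_count"
    units: str = "count/month"
    baseline: float = 50.0            # annual level per cell at the first fire year
    trend: float = -1.0               # per fire year per cell
    b0_range: tuple[float, float] = (-2.0, -0.5)   # coupling, FP units per (mm/month)
    T_range: tuple[int, int] = (1, 12)             # true antecedent windows (months)
    noise_sd: float | None = None     # absolute annual noise sd; overrides noise_frac
    noise_frac: float | None = 0.1    # noise sd as a fraction of the coupled-signal sd
    step_factor: float = 1.0          # multiply annual FP from step_year on (decoupling runs)
    step_year: int | None = None
    clip_nonnegative: bool = False
    #: monthly disaggregation of the annual value across the fire year
    #: (Aug 30%, Sep 45%, Oct 15%, remaining 10% spread over the other months)
    monthly_profile: tuple[float, ...] = (
        0.10 / 9, 0.10 / 9, 0.10 / 9, 0.10 / 9,      # Apr-Jul
        0.30, 0.45, 0.15,                            # Aug, Sep, Oct
        0.10 / 9, 0.10 / 9, 0.10 / 9, 0.10 / 9, 0.10 / 9,  # Nov-Mar
    )


@dataclass
class DeforestationConfig:
    initial: float = 18000.0          # km^2/yr at the first reporting year
    peak: float = 27000.0
    peak_year: int = 2004
    plateau: float = 6500.0
    decline_end: int = 2009
    plateau_noise_cv: float = 0.08
    region: str = "BLA"


@dataclass
class SyntheticConfig:
    grid: GridSpec = field(default_factory=default_grid)
    n_years: int = 18
    start_year: int = 2000
    head_start_months: int = 24
    seed: int = 0
    calendar: AnalysisCalendar = field(default_factory=AnalysisCalendar)
    precip: PrecipConfig = field(default_factory=PrecipConfig)
    fire: FireConfig = field(default_factory=FireConfig)
    deforestation: DeforestationConfig = field(default_factory=DeforestationConfig)

    @property
    def fire_years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def rngs(self) -> dict[str, np.random.Generator]:
        names = ["precip_anomaly", "precip_jitter", "fire_b0", "fire_T",
                 "fire_noise", "deforestation", "points"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SyntheticTruth:
    """Hidden generator parameters for recovery tests."""

    years: np.ndarray
    b0_field: np.ndarray          # (nrow, ncol)
    T_field: np.ndarray           # (nrow, ncol) int
    baseline_field: np.ndarray
    fire_trend_field: np.ndarray
    ap_iav: np.ndarray            # (n_years, nrow, ncol) at the true window
    induced: np.ndarray           # b0_field * ap_iav, per year
    annual_fp: np.ndarray         # the annual values before monthly disaggregation

    def save(self, path) -> None:
        payload = {
            "years": self.years.tolist(),
            "b0_field": self.b0_field.tolist(),
            "T_field": self.T_field.tolist(),
            "baseline_field": self.baseline_field.tolist(),
            "fire_trend_field": self.fire_trend_field.tolist(),
            "annual_fp": self.annual_fp.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------

def _seasonal_cycle(cfg: PrecipConfig, months: np.ndarray) -> np.ndarray:
    phase = 2.0 * np.pi * (months - cfg.wet_peak_month) / 12.0
    return cfg.annual_mean + cfg.seasonal_amplitude * np.cos(phase)


def generate_precipitation(config: SyntheticConfig,
                           rngs: dict[str, np.random.Generator] | None = None) -> MonthlyField:
    """Monthly precipitation field with head start, fully determined by the seed."""
    rngs = rngs or config.rngs()
    cal = config.calendar
    n_months = config.head_start_months + 12 * config.n_years
    first_fy_start = config.start_year * 12 + cal.start_offset  # absolute month index
    start_idx = first_fy_start - config.head_start_months
    start = (start_idx // 12, start_idx % 12 + 1)
    abs_idx = start_idx + np.arange(n_months)
    months = abs_idx % 12 + 1
    years_cal = abs_idx // 12
    clim = _seasonal_cycle(config.precip, months)

    fy = np.array([fire_year_of(cal, y, m) for y, m in zip(years_cal, months)])
    fy_labels = np.unique(fy)
    anomalies = dict(zip(fy_labels,
                         rngs["precip_anomaly"].normal(0.0, config.precip.iav_sd,
                                                       fy_labels.size)))
    anom = np.array([anomalies[l] for l in fy])
    trend = config.precip.trend * (fy - config.start_year)

    base = clim + anom + trend  # (n_months,)
    jitter = rngs["precip_jitter"].normal(0.0, config.precip.jitter_sd,
                                          (n_months,) + config.grid.shape)
    values = np.maximum(base[:, None, None] + jitter, 0.0)
    return MonthlyField(grid=config.grid, variable="precipitation", units="mm/month",
                        start=start, values=values)


def _ap_at_window(P: MonthlyField, calendar: AnalysisCalendar, years: np.ndarray,
                  T_field: np.ndarray) -> np.ndarray:
    """Per-cell antecedent precipitation at that cell's window: (n_years, nrow, ncol)."""
    csum = np.concatenate([np.zeros((1,) + P.grid.shape),
                           np.cumsum(P.values, axis=0)], axis=0)
    peak_idx = np.array([P.time_index_of(int(y), calendar.peak_month) for y in years])
    if peak_idx.min() < int(T_field.max()):
        raise ValueError("true antecedent windows exceed the precipitation head start")
    nr, nc = P.grid.shape
    out = np.empty((years.size, nr, nc))
    for T in np.unique(T_field):
        sel = T_field == T
        ap = (csum[peak_idx] - csum[peak_idx - int(T)]) / float(T)
        out[:, sel] = ap[:, sel]
    return out


def _detrend_lattice(values: np.ndarray, years: np.ndarray) -> np.ndarray:
    """IAV (OLS residuals vs year) along axis 0."""
    t = years - years.mean()
    stt = float(t @ t)
    mean = values.mean(axis=0)
    slope = np.tensordot(t, values - mean, axes=(0, 0)) / stt
    return values - mean - t[:, None, None] * slope


def generate_fire_parameter(config: SyntheticConfig, P: MonthlyField,
                            rngs: dict[str, np.random.Generator] | None = None,
                            ) -> tuple[MonthlyField, SyntheticTruth]:
    """Fire parameter coupled to antecedent precipitation, plus the hidden truth.

    Annual values follow the generative model inverted by the estimator; they
    are spread across the fire-year months with a fixed August-October-peaked
    profile so both monthly and annual paths exist.
    """
    rngs = rngs or config.rngs()
    fc = config.fire
    cal = config.calendar
    years = config.fire_years
    nr, nc = config.grid.shape

    lo, hi = fc.b0_range
    b0 = (np.full((nr, nc), lo) if lo == hi
          else rngs["fire_b0"].uniform(lo, hi, (nr, nc)))
    tlo, thi = fc.T_range
    T = rngs["fire_T"].integers(tlo, thi + 1, (nr, nc))

    ap = _ap_at_window(P, cal, years, T)
    ap_iav = _detrend_lattice(ap, years.astype(float))
    induced = b0[None] * ap_iav

    tt = (years - years[0]).astype(float)
    baseline = np.full((nr, nc), fc.baseline)
    trend_field = np.full((nr, nc), fc.trend)
    annual = baseline[None] + trend_field[None] * tt[:, None, None] + induced

    if fc.noise_sd is not None:
        noise_scale = np.full((nr, nc), fc.noise_sd)
    elif fc.noise_frac:
        noise_scale = fc.noise_frac * induced.std(axis=0)
    else:
        noise_scale = np.zeros((nr, nc))
    annual = annual + rngs["fire_noise"].normal(0.0, 1.0, annual.shape) * noise_scale[None]

    if fc.step_factor != 1.0:
        step_year = fc.step_year or config.deforestation.decline_end
        annual = np.where((years >= step_year)[:, None, None],
                          annual * fc.step_factor, annual)
    if fc.clip_nonnegative:
        annual = np.maximum(annual, 0.0)

    profile = np.asarray(fc.monthly_profile)
    profile = profile / profile.sum()  # exact partition of the annual value
    monthly = np.empty((12 * config.n_years, nr, nc))
    for i, _y in enumerate(years):
        monthly[12 * i:12 * (i + 1)] = annual[i][None] * profile[:, None, None]
    start_idx = config.start_year * 12 + cal.start_offset
    start = (start_idx // 12, start_idx % 12 + 1)
    field_ = MonthlyField(grid=config.grid, variable=fc.variable, units=fc.units,
                          start=start, values=monthly)
    truth = SyntheticTruth(years=years, b0_field=b0, T_field=T,
                           baseline_field=baseline, fire_trend_field=trend_field,
                           ap_iav=ap_iav, induced=induced, annual_fp=annual)
    return field_, truth


def generate_deforestation(config: SyntheticConfig,
                           rngs: dict[str, np.random.Generator] | None = None,
                           ) -> AnnualRegionalTable:
    """Reporting-year deforestation: rise to the peak year, steep decline, plateau."""
    rngs = rngs or config.rngs()
    dc = config.deforestation
    years = config.fire_years  # reporting-year labels share the numeric range
    values = np.empty(years.size)
    rng = rngs["deforestation"]
    for i, y in enumerate(years):
        if y <= dc.peak_year:
            span = max(dc.peak_year - years[0], 1)
            values[i] = dc.initial + (dc.peak - dc.initial) * (y - years[0]) / span
        elif y < dc.decline_end:
            # geometric interpolation from the peak down to the plateau
            frac = (y - dc.peak_year) / (dc.decline_end - dc.peak_year)
            values[i] = dc.peak * (dc.plateau / dc.peak) ** frac
        else:
            values[i] = dc.plateau * (1.0 + rng.normal(0.0, dc.plateau_noise_cv))
    values = np.maximum(values, 1.0)
    return AnnualRegionalTable(region=dc.region, variable="deforestation",
                               units="km^2/yr", years=years, values=values)


def generate_fire_points(config: SyntheticConfig, FP: MonthlyField,
                         rngs: dict[str, np.random.Generator] | None = None) -> pd.DataFrame:
    """Point detections realising a counts field (rounded to integers, clipped at 0).

    Positions are uniform inside each cell; confidence is uniform in [60, 100],
    so a >= 80 filter keeps half the points in expectation.
    """
    rngs = rngs or config.rngs()
    rng = rngs["points"]
    grid = FP.grid
    counts = np.rint(np.maximum(FP.values, 0.0)).astype(int)
    periods = FP.periods
    res = grid.resolution
    rows = []
    for t in range(counts.shape[0]):
        p = periods[t]
        days = p.days_in_month
        nz = np.argwhere(counts[t] > 0)
        for i, j in nz:
            n = counts[t, i, j]
            lat = grid.lat_min + (i + rng.random(n)) * res
            lon = grid.lon_min + (j + rng.random(n)) * res
            day = rng.integers(1, days + 1, n)
            conf = rng.uniform(60.0, 100.0, n)
            for k in range(n):
                rows.append((lat[k], lon[k], f"{p.year:04d}-{p.month:02d}-{day[k]:02d}",
                             conf[k]))
    return pd.DataFrame(rows, columns=["latitude", "longitude", "acq_date", "confidence"])


def synthetic_region_mask(grid: GridSpec,
                          state_names: tuple[str, ...] = ("RO", "MT", "PA", "TO"),
                          domain: str = "BLA") -> RegionMask:
    """Quadrant 'states' tiling the whole grid, plus the full-domain layer."""
    nr, nc = grid.shape
    half_r, half_c = nr // 2, nc // 2
    quads = [
        (slice(0, half_r), slice(0, half_c)),
        (slice(0, half_r), slice(half_c, nc)),
        (slice(half_r, nr), slice(0, half_c)),
        (slice(half_r, nr), slice(half_c, nc)),
    ]
    regions: dict[str, np.ndarray] = {domain: np.ones((nr, nc), dtype=bool)}
    for name, q in zip(state_names, quads):
        layer = np.zeros((nr, nc), dtype=bool)
        layer[q] = True
        regions[name] = layer
    return RegionMask(grid=grid, regions=regions, domain=domain)


def generate_step_ratio_series(rng: np.random.Generator, step: float = 2.5,
                               noise_cv: float = 0.1, n1: int = 8, n2: int = 8,
                               base: float = 1.0, start_year: int = 2001) -> AnnualSeries:
    """Ratio series with a configured step change between two periods.

    Period values are ``base`` (resp. ``base*step``) with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``.
    """
    levels = np.concatenate([np.full(n1, base), np.full(n2, base * step)])
    values = levels * (1.0 + rng.normal(0.0, noise_cv, n1 + n2))
    years = np.arange(start_year, start_year + n1 + n2)
    return AnnualSeries(region="BLA", variable="ratio", units="",
                        years=years, values=values)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def make_config(preset: str, seed: int = 0, grid: GridSpec | None = None,
                n_years: int = 18, start_year: int = 2000) -> SyntheticConfig:
    """Named study conditions: ``null``, ``coupled`` or ``decoupling``.

    * ``null``: no coupling (b0 = 0), no trends, moderate additive noise —
      the no-signal control.
    * ``coupled``: the default generative model (negative coupling, declining
      fire trend, noise at 10% of the coupled signal).
    * ``decoupling``: coupled fields whose annual fire level steps up by 2.5x
      from 2009 on, against a flat deforestation series, so the
      fire-to-deforestation ratio steps by the configured factor.
    """
    grid = grid or default_grid()
    cfg = SyntheticConfig(grid=grid, seed=seed, n_years=n_years, start_year=start_year)
    if preset == "null":
        cfg.fire = FireConfig(b0_range=(0.0, 0.0), trend=0.0,
                              noise_sd=5.0, noise_frac=None)
    elif preset == "coupled":
        pass  # the defaults are the coupled conditions
    elif preset == "decoupling":
        cfg.fire = FireConfig(trend=0.0, step_factor=2.5, step_year=2009)
        cfg.deforestation = DeforestationConfig(
            initial=6500.0, peak=6500.0, peak_year=start_year,
            plateau=6500.0, decline_end=start_year + 1, plateau_noise_cv=0.05)
    else:
        raise ValueError(f"unknown preset {preset!r}; use null|coupled|decoupling")
    return cfg
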