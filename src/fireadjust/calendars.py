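"""Fire-year calendar: burning-season windows, annualisation, and wet-season onset.

The analysis year is centred on the burning-season peak month (September over
the Brazilian Legal Amazon): five months before the peak through six months
after it, i.e. April of year Y through March of year Y+1, labelled Y.
Deforestation reporting years (1 August - 31 July, labelled by the later
year) are re-labelled onto this fire-year axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, FormatError, InsufficientDataError
from .grids import AnnualRegionalTable, MonthlyField


@dataclass(frozen=True)
class AnalysisCalendar:
    """Window geometry of the fire year and associated season definitions."""

    peak_month: int = 9
    window_before: int = 5
    window_after: int = 6
    burning_months: tuple[int, ...] = (8, 9, 10)
    deforestation_year_start: int = 8

    def __post_init__(self) -> None:
        if not 1 <= self.peak_month <= 12:
            raise ValueError("peak_month must be in 1..12")
        if self.window_before + self.window_after + 1 != 12:
            raise ValueError("window_before + window_after + 1 must equal 12")

    @property
    def start_offset(self) -> int:
        """0-based month offset of the fire-year start from January of the label year."""
        return self.peak_month - 1 - self.window_before


def _midx(year: int, month: int) -> int:
    return year * 12 + (month - 1)


def fire_year_months(calendar: AnalysisCalendar, label_year: int) -> list[tuple[int, int]]:
    """The 12 consecutive (year, month) pairs making up fire year ``label_year``.

    With the default September peak this is April Y .. March Y+1.
    """
    start = _midx(label_year, 1) + calendar.start_offset
    return [(idx // 12, idx % 12 + 1) for idx in range(start, start + 12)]


def fire_year_of(calendar: AnalysisCalendar, year: int, month: int) -> int:
    """Fire-year label containing calendar month (year, month)."""
    return (_midx(year, month) - calendar.start_offset) // 12


@dataclass
class AnnualSeries:
    """Regional values on the fire-year calendar, one per label year."""

    region: str
    variable: str
    units: str
    years: np.ndarray
    values: np.ndarray
    calendar: AnalysisCalendar = field(default_factory=AnalysisCalendar)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size != self.values.size:
            raise FormatError("years and values differ in length")
        if self.years.size > 1 and not np.all(np.diff(self.years) == 1):
            raise FormatError("fire-year labels must be consecutive")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name=f"{self.region}:{self.variable}")

    def window(self, first: int, last: int) -> "AnnualSeries":
        """Restrict to labels first..last inclusive."""
        keep = (self.years >= first) & (self.years <= last)
        return AnnualSeries(self.region, self.variable, self.units,
                            self.years[keep], self.values[keep], self.calendar)


def align_years(a: AnnualSeries, b: AnnualSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common fire-year labels and the two value vectors restricted to them."""
    common = np.intersect1d(a.years, b.years)
    if common.size == 0:
        raise AlignmentError(f"no common fire years between {a.variable} and {b.variable}")
    av = a.to_series().loc[common].to_numpy()
    bv = b.to_series().loc[common].to_numpy()
    return common, av, bv


def annualize(
    series: pd.Series,
    calendar: AnalysisCalendar,
    statistic: str = "mean",
    region: str = "",
    variable: str = "",
    units: str = "",
) -> AnnualSeries:
    """Collapse a monthly regional series to one value per complete fire year.

    ``sum`` for counts and emissions, ``mean`` for AOD and precipitation.
    Fire years not fully covered by the input are dropped with a warning.
    """
    if not isinstance(series.index, pd.PeriodIndex):
        raise FormatError("monthly series must be indexed by a monthly PeriodIndex")
    labels = np.array([fire_year_of(calendar, p.year, p.month) for p in series.index])
    values = series.to_numpy(dtype=float)
    out_years, out_values, dropped = [], [], []
    for year in np.unique(labels):
        sel = labels == year
        if sel.sum() < 12:
            dropped.append(int(year))
            continue
        v = values[sel]
        out_years.append(int(year))
        out_values.append(v.sum() if statistic == "sum" else v.mean())
    if dropped:
        warnings.warn(f"annualize: dropped incomplete fire years {dropped}", stacklevel=2)
    if not out_years:
        raise InsufficientDataError("no complete fire year in the monthly series")
    name = variable or (series.name or "")
    return AnnualSeries(region=region, variable=name, units=units,
                        years=np.array(out_years), values=np.array(out_values),
                        calendar=calendar)


def burning_season_composite(field_: MonthlyField, calendar: AnalysisCalendar) -> np.ndarray:
    """Per-cell mean over every burning-season month (default Aug-Oct) in the record."""
    months = field_.periods.month
    sel = np.isin(months, list(calendar.burning_months))
    if not sel.any():
        raise InsufficientDataError("no burning-season months in the field")
    with np.errstate(invalid="ignore"):
        return np.nanmean(field_.values[sel], axis=0)


def align_deforestation_year(
    table: AnnualRegionalTable,
    lag: int = 0,
    calendar: AnalysisCalendar | None = None,
) -> AnnualSeries:
    """Re-label reporting-year deforestation onto the fire-year axis.

    The reporting year Y covers 1 August Y-1 to 31 July Y.  At ``lag=0`` fire
    year Y (Apr Y - Mar Y+1) is paired with reporting year Y, i.e. the
    deforestation completed just before that burning season.  At ``lag=+1`` it
    is paired with reporting year Y+1, the deforestation overlapping the
    season itself.
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or +1")
    if np.any(np.diff(table.years) != 1):
        gaps = [int(y) for y in range(table.years.min(), table.years.max()) if y not in table.years]
        raise AlignmentError(f"deforestation table has missing years: {gaps}")
    calendar = calendar or AnalysisCalendar()
    return AnnualSeries(region=table.region, variable=table.variable, units=table.units,
                        years=table.years - lag, values=table.values.copy(),
                        calendar=calendar)


@dataclass
class OnsetResult:
    """Wet-season onset month per year plus the frequency of each onset month."""

    onsets: dict[int, int | None]
    frequency: pd.Series  # fraction of years per onset month; key None = no onset
    threshold: float
    run_length: int


def wet_season_onset(
    series: pd.Series,
    threshold: float = 100.0,
    run_length: int = 2,
    search_start_month: int = 7,
) -> OnsetResult:
    """First month starting ``run_length`` consecutive months at/above ``threshold``.

    The search window for year Y runs July Y - June Y+1 (anchored after the
    dry season); the run may complete beyond the window end if data exist.
    The comparison is inclusive (>= threshold counts as wet).
    """
    if not isinstance(series.index, pd.PeriodIndex):
        raise FormatError("monthly series must be indexed by a monthly PeriodIndex")
    values = series.to_numpy(dtype=float)
    periods = series.index
    pos = {p: i for i, p in enumerate(periods)}
    years = sorted({p.year for p in periods})
    onsets: dict[int, int | None] = {}
    for year in years:
        start = pd.Period(f"{year}-{search_start_month:02d}", freq="M")
        window = [start + k for k in range(12)]
        if window[0] not in pos or window[-1] not in pos:
            continue  # search window not fully covered
        found: int | None = None
        for p in window:
            i = pos[p]
            if i + run_length > len(values):
                break
            run = values[i:i + run_length]
            if np.all(np.isfinite(run)) and np.all(run >= threshold):
                found = p.month
                break
        onsets[year] = found
    n = len(onsets)
    counts: dict[int | None, int] = {}
    for v in onsets.values():
        counts[v] = counts.get(v, 0) + 1
    freq = pd.Series({k: c / n for k, c in counts.items()} if n else {}, dtype=float)
    return OnsetResult(onsets=onsets, frequency=freq, threshold=threshold, run_length=run_length)
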