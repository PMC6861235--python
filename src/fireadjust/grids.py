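"""Regular latitude-longitude grids, monthly fields, region masks and zonal statistics.

The analysis lives on regular 0.25 deg or 0.50 deg grids.  A :class:`MonthlyField`
is a (time, row, col) lattice of one monthly variable (precipitation in
mm/month, fire counts per month, burned-area percent of cell, AOD, or Tg of
CO2 per month) with NaN marking missing months.  A :class:`RegionMask` carries
named boolean layers (a whole-domain layer plus mutually disjoint state
layers) used for regional aggregation.

Cells are half-open ``[edge, edge + resolution)`` in both latitude and
longitude; row 0 is the southernmost row.  NetCDF files are written CF-style
(time/lat/lon dimensions, units attribute) through xarray.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import FormatError, GridError

logger = logging.getLogger(__name__)

VALID_RESOLUTIONS = (0.25, 0.50)

#: mean Earth radius derived km per degree of latitude
KM_PER_DEGREE = 111.195


def _is_multiple(value: float, step: float, tol: float = 1e-9) -> bool:
    ratio = value / step
    return abs(ratio - round(ratio)) < tol


@dataclass(frozen=True)
class GridSpec:
    """A regular lat-lon grid aligned to the 0.25/0.50 degree lattice."""

    resolution: float
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not any(abs(self.resolution - r) < 1e-12 for r in VALID_RESOLUTIONS):
            raise GridError(f"resolution must be one of {VALID_RESOLUTIONS}, got {self.resolution}")
        for name in ("lat_min", "lat_max", "lon_min", "lon_max"):
            if not _is_multiple(getattr(self, name), self.resolution):
                raise GridError(f"{name}={getattr(self, name)} is not a multiple of {self.resolution}")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise GridError("grid extent must be positive in both axes")

    @property
    def n_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def n_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.resolution

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def cell_index(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Half-open cell membership: returns (row, col, in_bounds).

        A point exactly on the maximum latitude/longitude edge is out of
        bounds (the partition is ``[edge, edge + res)``).
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        row = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        ok = (
            (lat >= self.lat_min) & (lat < self.lat_max)
            & (lon >= self.lon_min) & (lon < self.lon_max)
        )
        return row, col, ok

    def cell_areas(self) -> np.ndarray:
        """Spherical-Earth cosine-latitude cell areas in km^2, shape (n_rows, n_cols)."""
        dy = self.resolution * KM_PER_DEGREE
        dx = self.resolution * KM_PER_DEGREE * np.cos(np.deg2rad(self.lat_centers))
        return np.repeat((dx * dy)[:, None], self.n_cols, axis=1)


def _month_index(year: int, month: int) -> int:
    return year * 12 + (month - 1)


@dataclass
class MonthlyField:
    """A gridded monthly variable: values[time, row, col] with NaN = missing."""

    grid: GridSpec
    variable: str
    units: str
    start: tuple[int, int]  # (year, month) of the first time step
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        y, m = self.start
        if not 1 <= m <= 12:
            raise FormatError(f"start month {m} out of range")

    @property
    def n_months(self) -> int:
        return self.values.shape[0]

    @property
    def periods(self) -> pd.PeriodIndex:
        start = pd.Period(f"{self.start[0]}-{self.start[1]:02d}", freq="M")
        return pd.period_range(start, periods=self.n_months, freq="M")

    def time_index_of(self, year: int, month: int) -> int:
        """Position of calendar month (year, month) along the time axis."""
        idx = _month_index(year, month) - _month_index(*self.start)
        if not 0 <= idx < self.n_months:
            raise IndexError(f"({year},{month}) outside the field's time span")
        return idx

    def cell_series(self, row: int, col: int) -> pd.Series:
        return pd.Series(self.values[:, row, col], index=self.periods, name=self.variable)


@dataclass
class RegionMask:
    """Named boolean layers on a grid: one whole-domain layer plus disjoint states."""

    grid: GridSpec
    regions: Mapping[str, np.ndarray]
    domain: str = "BLA"
    cell_area: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        regions = {}
        for name, layer in self.regions.items():
            layer = np.asarray(layer, dtype=bool)
            if layer.shape != self.grid.shape:
                raise GridError(f"mask layer {name!r} shape {layer.shape} != grid {self.grid.shape}")
            regions[name] = layer
        self.regions = regions
        if self.cell_area is None:
            self.cell_area = self.grid.cell_areas()
        states = [v for k, v in regions.items() if k != self.domain]
        if states:
            stack = np.stack(states)
            if (stack.sum(axis=0) > 1).any():
                raise GridError("state mask layers overlap")
            if self.domain in regions:
                union = stack.any(axis=0)
                if not np.array_equal(union, regions[self.domain]):
                    raise GridError(f"union of state layers does not equal the {self.domain!r} layer")

    @property
    def names(self) -> list[str]:
        return list(self.regions)

    def layer(self, region: str) -> np.ndarray:
        try:
            return self.regions[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}; known: {self.names}") from None


@dataclass
class AnnualRegionalTable:
    """Year-labelled regional values (e.g. PRODES-style annual deforestation)."""

    region: str
    variable: str
    units: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size != self.values.size:
            raise FormatError("years and values differ in length")
        if self.years.size and not np.array_equal(np.diff(self.years), np.ones(self.years.size - 1)):
            raise FormatError("years must be strictly increasing and consecutive")


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style through xarray; NETCDF3 container, float64 payload)
# ---------------------------------------------------------------------------

def write_monthly_field(field_: MonthlyField, path) -> None:
    times = field_.periods.to_timestamp()
    ds = xr.Dataset(
        {field_.variable: (("time", "lat", "lon"), field_.values, {"units": field_.units})},
        coords={
            "time": ("time", times),
            "lat": ("lat", field_.grid.lat_centers),
            "lon": ("lon", field_.grid.lon_centers),
        },
        attrs={"resolution": field_.grid.resolution},
    )
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def _gridspec_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridSpec:
    def infer(centers: np.ndarray) -> tuple[float, float, float]:
        if centers.size < 2:
            raise GridError("need at least 2 cells per axis to infer the grid")
        steps = np.diff(centers)
        res = float(steps[0])
        if not np.allclose(steps, res, atol=1e-9):
            raise GridError("coordinate spacing is not uniform")
        return res, float(centers[0] - res / 2), float(centers[-1] + res / 2)

    res_lat, lat_min, lat_max = infer(np.asarray(lat, dtype=float))
    res_lon, lon_min, lon_max = infer(np.asarray(lon, dtype=float))
    if abs(res_lat - res_lon) > 1e-9:
        raise GridError("latitude and longitude resolutions differ")
    return GridSpec(round(res_lat, 6), round(lat_min, 6), round(lat_max, 6),
                    round(lon_min, 6), round(lon_max, 6))


def read_monthly_field(path, variable: str | None = None) -> MonthlyField:
    """Read a CF-style NetCDF monthly field; validates grid and time contiguity."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if variable is None:
        candidates = [v for v in ds.data_vars if set(ds[v].dims) == {"time", "lat", "lon"}]
        if len(candidates) != 1:
            raise FormatError(f"cannot infer variable among {list(ds.data_vars)}")
        variable = candidates[0]
    da = ds[variable].transpose("time", "lat", "lon")
    times = pd.DatetimeIndex(da["time"].values)
    periods = times.to_period("M")
    diffs = np.diff(periods.asi8)
    if periods.size == 0:
        raise FormatError("empty time axis")
    if periods.size > 1 and not np.all(diffs == 1):
        raise FormatError("time axis is not contiguous calendar months")
    grid = _gridspec_from_coords(da["lat"].values, da["lon"].values)
    units = str(da.attrs.get("units", ""))
    return MonthlyField(grid=grid, variable=variable, units=units,
                        start=(periods[0].year, periods[0].month),
                        values=np.asarray(da.values, dtype=float))


def write_region_mask(mask: RegionMask, path) -> None:
    data = {name: (("lat", "lon"), layer.astype(np.int8)) for name, layer in mask.regions.items()}
    data["cell_area"] = (("lat", "lon"), mask.cell_area)
    ds = xr.Dataset(
        data,
        coords={"lat": mask.grid.lat_centers, "lon": mask.grid.lon_centers},
        attrs={"domain": mask.domain},
    )
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def read_region_mask(path) -> RegionMask:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = _gridspec_from_coords(ds["lat"].values, ds["lon"].values)
    cell_area = None
    regions = {}
    for name in ds.data_vars:
        if name == "cell_area":
            cell_area = np.asarray(ds[name].values, dtype=float)
        else:
            regions[name] = np.asarray(ds[name].values).astype(bool)
    return RegionMask(grid=grid, regions=regions,
                      domain=str(ds.attrs.get("domain", "BLA")), cell_area=cell_area)


# ---------------------------------------------------------------------------
# Point detections -> gridded monthly counts
# ---------------------------------------------------------------------------

def grid_point_detections(
    points: pd.DataFrame,
    grid: GridSpec,
    min_confidence: float = 80.0,
    start: tuple[int, int] | None = None,
    n_months: int | None = None,
) -> MonthlyField:
    """Bin point fire detections into monthly per-cell counts.

    ``points`` has columns latitude, longitude, acq_date (ISO), confidence.
    Detections below ``min_confidence`` (inclusive threshold: >= passes) are
    excluded; points outside the grid bounds are logged and dropped.
    """
    required = {"latitude", "longitude", "acq_date", "confidence"}
    missing = required - set(points.columns)
    if missing:
        raise FormatError(f"detection table missing columns {sorted(missing)}")
    pts = points[points["confidence"] >= min_confidence]
    dates = pd.to_datetime(pts["acq_date"])
    row, col, ok = grid.cell_index(pts["latitude"].to_numpy(), pts["longitude"].to_numpy())
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("grid_point_detections: dropped %d points outside grid bounds", n_dropped)
    periods = dates.dt.to_period("M")
    if start is None:
        if ok.any():
            first = periods[np.asarray(ok)].min()
            start = (first.year, first.month)
        else:
            start = (2001, 1)
    if n_months is None:
        if ok.any():
            last = periods[np.asarray(ok)].max()
            n_months = (last.year * 12 + last.month) - (start[0] * 12 + start[1]) + 1
        else:
            n_months = 1
    t0 = _month_index(*start)
    tidx = (dates.dt.year * 12 + dates.dt.month - 1).to_numpy() - t0
    in_time = (tidx >= 0) & (tidx < n_months)
    keep = np.asarray(ok) & in_time
    counts = np.zeros((n_months,) + grid.shape)
    np.add.at(counts, (tidx[keep], row[keep], col[keep]), 1.0)
    return MonthlyField(grid=grid, variable="fire_count", units="count/month",
                        start=start, values=counts)


def read_point_detections(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Regridding and regional aggregation
# ---------------------------------------------------------------------------

def regrid_mean(field_: MonthlyField, target: GridSpec) -> MonthlyField:
    """Average a 0.25 deg field up to 0.50 deg by 2x2 block means.

    Partially missing blocks use the mean of the available cells; an
    all-missing block stays missing.
    """
    src = field_.grid
    if abs(src.resolution - 0.25) > 1e-9 or abs(target.resolution - 0.50) > 1e-9:
        raise GridError("regrid_mean expects a 0.25 deg source and 0.50 deg target")
    aligned = (
        abs(src.lat_min - target.lat_min) < 1e-9 and abs(src.lat_max - target.lat_max) < 1e-9
        and abs(src.lon_min - target.lon_min) < 1e-9 and abs(src.lon_max - target.lon_max) < 1e-9
        and src.n_rows == 2 * target.n_rows and src.n_cols == 2 * target.n_cols
    )
    if not aligned:
        raise GridError("target cells do not tile 2x2 blocks of the source grid")
    v = field_.values
    nt = v.shape[0]
    blocks = v.reshape(nt, target.n_rows, 2, target.n_cols, 2)
    # all-missing blocks legitimately stay missing; avoid the empty-slice warning
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(blocks, axis=(2, 4))
    return MonthlyField(grid=target, variable=field_.variable, units=field_.units,
                        start=field_.start, values=out)


def aggregate_region(
    field_: MonthlyField,
    mask: RegionMask,
    region: str,
    method: str = "sum",
) -> pd.Series:
    """Monthly regional series from a gridded field.

    ``sum`` for counts/emissions, unweighted ``mean`` for AOD and
    precipitation, ``area_percent`` = cell-area-weighted mean burned
    fraction.  A month with zero non-missing cells in the region is missing.
    """
    if not (field_.grid == mask.grid):
        raise GridError("field and mask are on different grids")
    layer = mask.layer(region)
    v = field_.values[:, layer]  # (time, n_region_cells)
    finite = np.isfinite(v)
    any_data = finite.any(axis=1)
    out = np.full(v.shape[0], np.nan)
    if method == "sum":
        out[any_data] = np.nansum(v[any_data], axis=1)
    elif method == "mean":
        with np.errstate(invalid="ignore"):
            out[any_data] = np.nanmean(v[any_data], axis=1)
    elif method == "area_percent":
        w = mask.cell_area[layer]
        vw = np.where(finite, v, 0.0)
        wsum = (finite * w).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = (vw * w).sum(axis=1) / wsum
        out[wsum > 0] = res[wsum > 0]
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return pd.Series(out, index=field_.periods, name=f"{region}:{field_.variable}")


#: aggregation convention per variable family (units of the tables: counts, %, AOD, Tg)
DEFAULT_AGGREGATION = {
    "fire_count": "sum",
    "co2": "sum",
    "burned_area": "area_percent",
    "aod": "mean",
    "precipitation": "mean",
}
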