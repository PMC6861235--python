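"""End-to-end pipeline: simulate/load -> adjust -> trends -> ratios -> report.

The pipeline reproduces the regional table structure of the analysis: absolute
trends with 95% CIs (full and precipitation-adjusted), relative percentage
trends, period ratio comparisons, a correlation matrix with lag-0 and lag+1
deforestation pairings, monthly climatologies, and burning-season composites.
Every output is a pure function of (inputs, config, seed); a run manifest with
the config hash makes any table reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .adjustment import PrecipAdjustmentModel, PrecipAdjustmentResults
from .calendars import (AnalysisCalendar, AnnualSeries, align_deforestation_year,
                        annualize, burning_season_composite, wet_season_onset)
from .exceptions import FireAdjustError, InsufficientDataError
from .grids import (DEFAULT_AGGREGATION, AnnualRegionalTable, GridSpec, MonthlyField,
                    RegionMask, aggregate_region, read_monthly_field, read_region_mask,
                    regrid_mean, write_monthly_field, write_region_mask)
from .synthetic import (FireConfig, SyntheticConfig, default_grid,
                        generate_deforestation, generate_fire_parameter,
                        generate_precipitation, make_config, synthetic_region_mask)
from .trends import (correlate, linear_trend, period_comparison, ratio_series,
                     relative_trend)

logger = logging.getLogger(__name__)

#: display rounding per variable family (counts, %, AOD, Tg)
DISPLAY_DECIMALS = {"fire_count": 0, "burned_area": 3, "aod": 4, "co2": 1,
                    "deforestation": 0}


@dataclass
class VariableSpec:
    name: str
    aggregation: str
    years: tuple[int, int]
    grid: str = "native"   # 'native' (0.25 deg) or 'coarse' (0.50 deg, precip averaged up)


def default_variables(first: int = 2001, last: int = 2016) -> list[VariableSpec]:
    return [
        VariableSpec("fire_count", "sum", (first, last)),
        VariableSpec("burned_area", "area_percent", (first, last - 1)),
        VariableSpec("aod", "mean", (first, last), grid="coarse"),
        VariableSpec("co2", "sum", (first, last)),
    ]


@dataclass
class PipelineConfig:
    outdir: str = "fireadjust_output"
    preset: str | None = "coupled"
    seed: int = 0
    inputs: dict = field(default_factory=dict)   # precip/mask/deforestation/<variable> paths
    regions: list[str] = field(default_factory=lambda: ["BLA", "RO", "MT", "PA", "TO"])
    ratio_region: str = "BLA"
    variables: list[VariableSpec] = field(default_factory=default_variables)
    period1: tuple[int, int] = (2001, 2008)
    period2: tuple[int, int] = (2009, 2016)
    deforestation_lag: int = 0
    peak_month: int = 9
    burning_months: tuple[int, ...] = (8, 9, 10)
    onset_threshold_mm: float = 100.0
    onset_run_length: int = 2
    relative_base: str = "mean"
    max_window_months: int = 24
    recenter_adjusted: bool = False
    clip_nonnegative: bool = False
    grid_cells: int = 10        # synthetic grid edge length (0.25 deg cells)
    n_years: int = 18
    start_year: int = 2000
    write_plots: bool = False

    @property
    def calendar(self) -> AnalysisCalendar:
        return AnalysisCalendar(peak_month=self.peak_month,
                                burning_months=tuple(self.burning_months))

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        # the hash identifies the analysis, not where it is written
        payload.pop("outdir", None)
        payload.pop("write_plots", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "variables" in raw:
        raw["variables"] = [VariableSpec(name=v["name"],
                                         aggregation=v.get("aggregation",
                                                           DEFAULT_AGGREGATION.get(v["name"], "sum")),
                                         years=tuple(v["years"]),
                                         grid=v.get("grid", "native"))
                            for v in raw["variables"]]
    for key in ("period1", "period2"):
        if key in raw:
            raw[key] = tuple(raw[key])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FireAdjustError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Static checks; an empty report means the config is runnable."""
    problems: list[str] = []
    if config.preset is None:
        for key in ("precip", "mask", "deforestation"):
            if key not in config.inputs:
                problems.append(f"missing input path {key!r}")
            elif not Path(config.inputs[key]).exists():
                problems.append(f"input file not found: {config.inputs[key]}")
        for v in config.variables:
            if v.name not in config.inputs:
                problems.append(f"missing input path for variable {v.name!r}")
            elif not Path(config.inputs[v.name]).exists():
                problems.append(f"input file not found: {config.inputs[v.name]}")
    elif config.preset not in ("null", "coupled", "decoupling"):
        problems.append(f"unknown preset {config.preset!r}")
    years_lo = config.start_year
    years_hi = config.start_year + config.n_years - 1
    for label, (lo, hi) in (("period1", config.period1), ("period2", config.period2)):
        if config.preset is not None and (lo < years_lo or hi > years_hi):
            problems.append(f"{label} {lo}-{hi} outside data years {years_lo}-{years_hi}")
    for v in config.variables:
        if v.years[0] > v.years[1]:
            problems.append(f"variable {v.name}: empty year range {v.years}")
        if v.grid not in ("native", "coarse"):
            problems.append(f"variable {v.name}: unknown grid {v.grid!r} "
                            "(use 'native' or 'coarse'; coarse triggers the regrid)")
    if config.deforestation_lag not in (0, 1):
        problems.append("deforestation_lag must be 0 or 1")
    return problems


# ---------------------------------------------------------------------------
# Simulation of the full fixture set
# ---------------------------------------------------------------------------

#: per-variable generative settings (level, trend, coupling) under the presets
_VARIABLE_FIRE_CONFIGS = {
    "fire_count": dict(variable="fire_count", units="count/month",
                       baseline=50.0, trend=-1.0, b0_range=(-2.0, -0.5)),
    "burned_area": dict(variable="burned_area", units="% of cell",
                        baseline=5.0, trend=0.0, b0_range=(-0.06, -0.02)),
    "aod": dict(variable="aod", units="1",
                baseline=0.30, trend=-0.004, b0_range=(-0.0040, -0.0010)),
    "co2": dict(variable="co2", units="Tg/month",
                baseline=10.0, trend=-0.15, b0_range=(-0.40, -0.10)),
}


def simulate_inputs(config: PipelineConfig) -> dict:
    """Generate the full synthetic input bundle for the configured preset."""
    base = make_config(config.preset or "coupled", seed=config.seed,
                       grid=default_grid(n=config.grid_cells),
                       n_years=config.n_years, start_year=config.start_year)
    rngs = base.rngs()
    precip = generate_precipitation(base, rngs)
    coarse_possible = config.grid_cells % 2 == 0
    coarse_grid = (GridSpec(0.50, base.grid.lat_min, base.grid.lat_max,
                            base.grid.lon_min, base.grid.lon_max)
                   if coarse_possible else None)
    precip_coarse = regrid_mean(precip, coarse_grid) if coarse_grid else None

    fields: dict[str, MonthlyField] = {}
    truths: dict[str, object] = {}
    for idx, vspec in enumerate(config.variables):
        vcfg = dataclasses.replace(base, seed=config.seed + 7919 * (idx + 1))
        fire_kwargs = dict(_VARIABLE_FIRE_CONFIGS.get(vspec.name, {}))
        preset_fire = base.fire
        vcfg.fire = FireConfig(**fire_kwargs) if fire_kwargs else preset_fire
        # carry the preset's coupling/noise/step settings onto each variable
        vcfg.fire.noise_sd = preset_fire.noise_sd
        vcfg.fire.noise_frac = preset_fire.noise_frac
        vcfg.fire.step_factor = preset_fire.step_factor
        vcfg.fire.step_year = preset_fire.step_year
        if preset_fire.b0_range == (0.0, 0.0):
            vcfg.fire.b0_range = (0.0, 0.0)
            vcfg.fire.trend = 0.0
            vcfg.fire.noise_sd = 0.1 * vcfg.fire.baseline
        if vspec.grid == "coarse":
            if coarse_grid is None:
                raise FireAdjustError("coarse grid needs an even synthetic grid size")
            vcfg = dataclasses.replace(vcfg, grid=coarse_grid)
            P = precip_coarse
        else:
            P = precip
        fld, truth = generate_fire_parameter(vcfg, P, vcfg.rngs())
        fields[vspec.name] = fld
        truths[vspec.name] = truth
    deforestation = generate_deforestation(base, rngs)
    masks = {"native": synthetic_region_mask(base.grid)}
    if coarse_grid is not None:
        masks["coarse"] = synthetic_region_mask(coarse_grid)
    return {"precip": {"native": precip, "coarse": precip_coarse},
            "fields": fields, "masks": masks,
            "deforestation": deforestation, "truths": truths}


def load_inputs(config: PipelineConfig) -> dict:
    precip = read_monthly_field(config.inputs["precip"])
    coarse = None
    try:
        coarse_grid = GridSpec(0.50, precip.grid.lat_min, precip.grid.lat_max,
                               precip.grid.lon_min, precip.grid.lon_max)
        coarse = regrid_mean(precip, coarse_grid)
    except FireAdjustError:
        pass
    mask = read_region_mask(config.inputs["mask"])
    masks = {"native": mask}
    if coarse is not None:
        masks["coarse"] = synthetic_region_mask(coarse.grid) if mask.grid != coarse.grid else mask
    fields = {v.name: read_monthly_field(config.inputs[v.name], variable=v.name)
              for v in config.variables}
    df = pd.read_csv(config.inputs["deforestation"])
    region = df["region"].iloc[0]
    sub = df[df["region"] == region].sort_values("year")
    deforestation = AnnualRegionalTable(region=region, variable="deforestation",
                                        units="km^2/yr",
                                        years=sub["year"].to_numpy(),
                                        values=sub["value"].to_numpy())
    return {"precip": {"native": precip, "coarse": coarse}, "fields": fields,
            "masks": masks, "deforestation": deforestation, "truths": {}}


# ---------------------------------------------------------------------------
# The report bundle
# ---------------------------------------------------------------------------

def _display(value: float, decimals: int) -> float:
    return float(np.round(value, decimals))


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute every stage and return (and optionally write) the report bundle."""
    problems = validate_config(config)
    if problems:
        raise FireAdjustError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    cal = config.calendar

    stage = "inputs"
    try:
        data = simulate_inputs(config) if config.preset is not None else load_inputs(config)
        defo_annual = align_deforestation_year(data["deforestation"],
                                               lag=config.deforestation_lag, calendar=cal)
        defo_lag1 = align_deforestation_year(data["deforestation"], lag=1, calendar=cal)

        stage = "adjust"
        results: dict[str, PrecipAdjustmentResults] = {}
        for vspec in config.variables:
            fld = data["fields"][vspec.name]
            gridkey = "coarse" if vspec.grid == "coarse" else "native"
            model = PrecipAdjustmentModel(
                data["precip"][gridkey], fld, data["masks"][gridkey], calendar=cal,
                statistic="sum" if vspec.aggregation == "sum" else "mean",
                max_window=config.max_window_months, years=vspec.years,
                recenter_adjusted=config.recenter_adjusted,
                clip_nonnegative=config.clip_nonnegative)
            results[vspec.name] = model.fit()
            logger.info("adjust[%s]: %s cells flagged of %s", vspec.name,
                        int(results[vspec.name].unadjustable.sum()),
                        results[vspec.name].unadjustable.size)

        stage = "trends"
        table1_rows, table2_rows = [], []
        annual_rows = []
        series_store: dict[tuple[str, str, str], AnnualSeries] = {}

        def record_trend(series: AnnualSeries, variable: str, region: str, data_kind: str):
            tr = linear_trend(series)
            dec = DISPLAY_DECIMALS.get(variable, 3)
            table1_rows.append({
                "variable": variable, "region": region, "data": data_kind,
                "slope": tr.slope, "ci95": tr.ci95_half_width, "r2": tr.r2,
                "n_years": tr.n_years, "significant": tr.significant,
                "slope_display": _display(tr.slope, dec),
                "ci95_display": _display(tr.ci95_half_width, dec),
            })
            try:
                rel = relative_trend(tr, series, base=config.relative_base)
                table2_rows.append({
                    "variable": variable, "region": region, "data": data_kind,
                    "percent_per_year": rel.percent_per_year,
                    "ci95": rel.ci95_half_width, "significant": rel.significant,
                    "base": rel.base,
                    "percent_display": _display(rel.percent_per_year, 2),
                    "ci95_display": _display(rel.ci95_half_width, 2),
                })
            except InsufficientDataError:
                pass

        for region in config.regions:
            defo_r = defo_annual if defo_annual.region == region else None
            if region == config.ratio_region or defo_annual.region == region:
                dseries = AnnualSeries(region, "deforestation", defo_annual.units,
                                       defo_annual.years, defo_annual.values, cal)
                lo, hi = config.variables[0].years
                record_trend(dseries.window(lo, hi), "deforestation", region, "full")
                series_store[("deforestation", region, "full")] = dseries
            for vspec in config.variables:
                res = results[vspec.name]
                for kind in ("observed", "adjusted"):
                    s = res.regional_annual_series(region, which=kind,
                                                   method=vspec.aggregation)
                    s = s.window(*vspec.years)
                    data_kind = "full" if kind == "observed" else "PA"
                    record_trend(s, vspec.name, region, data_kind)
                    series_store[(vspec.name, region, data_kind)] = s
                    for y, v in zip(s.years, s.values):
                        annual_rows.append({"variable": vspec.name, "region": region,
                                            "data": data_kind, "fire_year": int(y),
                                            "value": v})

        stage = "correlations"
        corr_rows = []
        for region in config.regions:
            for vspec in config.variables:
                obs = series_store[(vspec.name, region, "full")]
                for lag, defo in ((0, defo_annual), (1, defo_lag1)):
                    defo_r = AnnualSeries(region, "deforestation", defo.units,
                                          defo.years, defo.values, cal)
                    c = correlate(obs, defo_r)
                    corr_rows.append({"region": region, "a": vspec.name,
                                      "b": "deforestation", "lag": lag,
                                      "r2": c.r2, "significant": c.significant,
                                      "n_years": c.n_years})
            names = [v.name for v in config.variables]
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    c = correlate(series_store[(a, region, "full")],
                                  series_store[(b, region, "full")])
                    corr_rows.append({"region": region, "a": a, "b": b, "lag": 0,
                                      "r2": c.r2, "significant": c.significant,
                                      "n_years": c.n_years})

        stage = "ratios"
        table3_rows = []
        for vspec in config.variables:
            for data_kind in ("full", "PA"):
                s = series_store[(vspec.name, config.ratio_region, data_kind)]
                ratio = ratio_series(s, defo_annual)
                p2 = (config.period2[0], min(config.period2[1], vspec.years[1]))
                pc = period_comparison(ratio, config.period1, p2)
                table3_rows.append({
                    "variable": vspec.name, "data": data_kind,
                    "period1_mean": pc.period1_mean, "period1_ci95": pc.period1_ci95,
                    "period2_mean": pc.period2_mean, "period2_ci95": pc.period2_ci95,
                    "factor": pc.factor, "factor_ci95": pc.factor_ci95,
                    "significant": pc.significant, "method": pc.method,
                })

        stage = "climatology"
        cycle_rows = []
        onset_rows = []
        for region in config.regions:
            mask = data["masks"]["native"]
            p_monthly = aggregate_region(data["precip"]["native"], mask, region, "mean")
            clim = p_monthly.groupby(p_monthly.index.month).mean()
            for m, v in clim.items():
                cycle_rows.append({"region": region, "variable": "precipitation",
                                   "month": int(m), "value": v})
            onset = wet_season_onset(p_monthly, threshold=config.onset_threshold_mm,
                                     run_length=config.onset_run_length)
            for month, frac in onset.frequency.items():
                onset_rows.append({"region": region,
                                   "onset_month": -1 if month is None else int(month),
                                   "fraction_of_years": frac})
            for vspec in config.variables:
                gridkey = "coarse" if vspec.grid == "coarse" else "native"
                s = aggregate_region(data["fields"][vspec.name], data["masks"][gridkey],
                                     region, vspec.aggregation)
                clim = s.groupby(s.index.month).mean()
                for m, v in clim.items():
                    cycle_rows.append({"region": region, "variable": vspec.name,
                                       "month": int(m), "value": v})

        stage = "composites"
        composites = {}
        for vspec in config.variables:
            fld = data["fields"][vspec.name]
            composites[vspec.name] = (fld.grid, burning_season_composite(fld, cal))

        bundle = {
            "table1": pd.DataFrame(table1_rows),
            "table2": pd.DataFrame(table2_rows),
            "table3": pd.DataFrame(table3_rows),
            "correlations": pd.DataFrame(corr_rows),
            "annual_series": pd.DataFrame(annual_rows),
            "annual_cycle": pd.DataFrame(cycle_rows),
            "wet_season_onset": pd.DataFrame(onset_rows),
            "results": results,
            "composites": composites,
            "truths": data["truths"],
            "manifest": {
                "config_hash": config.hash(),
                "seed": config.seed,
                "version": __version__,
                "preset": config.preset,
                "metadata": {
                    "significance": "per-series two-sided 95% tests, "
                                    "no multiple-testing correction",
                    "r2_significance": "t-test on r, n-2 df",
                    "relative_base": config.relative_base,
                },
            },
        }
    except Exception:
        if write and outdir.exists():
            for f in outdir.glob("*.csv"):
                f.unlink()  # remove partial outputs
        logger.exception("pipeline failed at stage %r", stage)
        raise

    if write:
        for name in ("table1", "table2", "table3", "correlations",
                     "annual_series", "annual_cycle", "wet_season_onset"):
            bundle[name].to_csv(outdir / f"{name}.csv", index=False)
        for vname, (grid, comp) in composites.items():
            ds = xr.Dataset({f"{vname}_burning_season": (("lat", "lon"), comp)},
                            coords={"lat": grid.lat_centers, "lon": grid.lon_centers})
            ds.to_netcdf(outdir / f"composite_{vname}.nc", engine="scipy",
                         format="NETCDF3_64BIT")
        for vname, res in results.items():
            ds = xr.Dataset(
                {"T_opt": (("lat", "lon"), res.T_opt.astype(np.int32)),
                 "b0": (("lat", "lon"), res.b0),
                 "r": (("lat", "lon"), res.r),
                 "fp_adjusted": (("fire_year", "lat", "lon"), res.adjusted)},
                coords={"lat": res.model.fire.grid.lat_centers,
                        "lon": res.model.fire.grid.lon_centers,
                        "fire_year": res.years})
            ds.to_netcdf(outdir / f"adjusted_{vname}.nc", engine="scipy",
                         format="NETCDF3_64BIT")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
        if config.write_plots:
            from .plotting import plot_report
            plot_report(bundle, outdir)
    return bundle
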