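# fireadjust

Precipitation-adjusted trend analysis for gridded fire data.

## The scientific problem

Fire activity in seasonally dry tropical forests — active-fire counts, burned
area, smoke aerosol optical depth (AOD), and fire CO₂ emissions — varies from
year to year for two distinct reasons: the weather (a dry year burns more) and
human ignition pressure (land clearing, pasture management). Disentangling the
two matters for policy: a decline in deforestation only translates into a
decline in fire if fire sources are still coupled to deforestation. Raw annual
fire series are too noisy to answer that question, because meteorological
interannual variability swamps the underlying trend.

`fireadjust` implements a per-grid-cell statistical adjustment that removes
the precipitation-driven component of an annual fire series, then provides
the downstream regional analysis: linear trends with confidence intervals,
relative trends, cross-variable correlations, fire-to-deforestation ratio
series, and a two-period "decoupling" comparison. A seeded synthetic-data
generator with known ground truth makes every stage testable end to end
without any satellite downloads.

## The model

All series are annual, indexed by **fire year**: a 12-month window from five
months before to six months after the September burning-season peak
(April–March by default), labelled by its starting calendar year.

For each grid cell and each candidate window length `T ∈ {1, …, 24}` months:

1. **Antecedent precipitation.** `AP(y; T)` is the mean monthly precipitation
   over the `T` months immediately preceding the peak month of fire year `y`.
2. **Detrending.** Both `AP` and the annual fire parameter `FP` are split by
   OLS-on-year into a linear component and residual interannual variability
   (IAV): `FP = FP_TREND + FP_IAV`, and likewise for `AP`. The decomposition
   is exact.
3. **No-intercept regression.** `FP_IAV(y) = b0 · AP_IAV(y) + ε(y)`, with
   `b0 = Σ(AP_IAV·FP_IAV) / Σ(AP_IAV²)`.
4. **Window selection.** `T_opt` maximises the absolute Pearson correlation
   between `FP_IAV` and `AP_IAV`; ties break to the smallest `T`.
5. **Precipitation-induced series.** `FP_precip(y) = b0 · AP(y; T_opt)`,
   using the full (not detrended) antecedent precipitation.
6. **Adjusted series.** `FP_PA(y) = FP(y) − FP_precip(y)`.

Because step 5 uses the full `AP`, the adjusted series is shifted in level by
the mean induced term (with `b0 < 0` the shift is upward); the option
`recenter_adjusted=True` adds the observed mean back if a level-preserving
variant is wanted. Cells whose fire series has zero variance (never any fire)
are passed through unadjusted and flagged.

Downstream, trends are OLS slopes with Student-t 95% confidence intervals
(`n − 2` degrees of freedom); a trend is significant when the interval
excludes zero. The decoupling comparison splits a fire-to-deforestation ratio
series into two periods (2001–2008 vs 2009–2016 by default), forms each
period's mean with a t-based SEM interval, and reports the between-period
factor with a delta-method confidence interval.

## Worked example

Generate a coupled synthetic scene (100 cells, 18 fire years, fire counts
driven by antecedent precipitation with per-cell hidden parameters), fit the
adjustment, and compare regional trends before and after:

```python
import fireadjust as fa

cfg = fa.make_config("coupled", seed=42)
rngs = cfg.rngs()
precip = fa.generate_precipitation(cfg, rngs)
fire, truth = fa.generate_fire_parameter(cfg, precip, rngs)
mask = fa.synthetic_region_mask(cfg.grid)

results = fa.PrecipAdjustmentModel(precip, fire, mask, cfg.calendar).fit()
print(results.summary())
```

```
Precipitation adjustment results
================================
variable:            fire_count [count/month]
grid:                (10, 10) at 0.25 deg
fire years:          2000-2017 (n=18)
cells fitted:        100/100 (0 passed through unadjusted)
window T_opt:        median 7 months, range 1-12
coupling b0:         median -1.212
|r| at T_opt:        median 0.996
```

The hidden per-cell parameters are recovered from the data alone:

```python
print("true window in cell (0, 0):", truth.T_field[0, 0],
      "estimated:", results.T_opt[0, 0])
print("true coupling:", round(truth.b0_field[0, 0], 3),
      "estimated:", round(results.b0[0, 0], 3))
```

```
true window in cell (0, 0): 11 estimated: 11
true coupling: -1.893 estimated: -1.951
```

Regional aggregation and the trend comparison:

```python
observed = results.regional_annual_series("BLA", which="observed")
adjusted = results.regional_annual_series("BLA", which="adjusted")
print("observed trend:", fa.linear_trend(observed))
print("adjusted trend:", fa.linear_trend(adjusted))
```

```
observed trend: TrendResult(slope=-99.97, ci95_half_width=134.55, r2=0.134,
                            n_years=18, significant=False, ...)
adjusted trend: TrendResult(slope=-40.87, ci95_half_width=2.48, r2=0.987,
                            n_years=18, significant=True, ...)
```

The observed series has a real decline that the 95% interval cannot
distinguish from zero (±134.5 around −100.0); after removing the
precipitation-driven variability the interval collapses to ±2.5 and the
decline is unambiguous. (The adjusted slope differs from the observed one
because the subtracted term `b0·AP` carries the sample trend of antecedent
precipitation with it.)

## Command-line pipeline

```bash
fireadjust simulate --preset coupled --seed 5 --out inputs/   # NetCDF + CSV fixtures
fireadjust validate --config config.yml                        # static checks
fireadjust run --config config.yml --seed 5 --out results/     # full analysis
```

`run` writes `table1.csv` (absolute trends ± CI, full vs adjusted, per region
and variable), `table2.csv` (relative %/yr trends), `table3.csv` (period
ratio means and decoupling factors), `correlations.csv`, annual series and
climatology CSVs, per-variable NetCDF lattices of `T_opt`, `b0`, `r` and the
adjusted series, and a `manifest.json` with a config hash for provenance.
Rerunning the same config and seed produces byte-identical tables.

## Reproduction

The summary metrics (identity error bounds, parameter-recovery rates,
confidence-interval calibration, decoupling-factor recovery, variance
dampening, determinism) are produced by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With seed 1 this reports, among others: window recovery rate 1.0 on a 20×20
grid at 10% noise, median coupling relative error 0.018, trend-CI coverage
0.952, null correlation rejection rate 0.049, mean estimated step factor
2.503 with CI coverage 0.952, and variance-dampening share 1.0 across 20
region×variable combinations. The script is fully seeded; the same seed
reproduces the same JSON.

See `docs/methods.md` for the methods note (estimator details, synthetic
generator design and its limits, numerical choices).
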