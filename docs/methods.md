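# Methods note

This note records the statistical model, the estimators, the synthetic-data
generator's design and realism limits, and the numerical choices made in the
implementation. Notation: `FP` is an annual fire parameter (counts, burned
fraction, AOD, or CO₂ emissions) in one grid cell; `P` is monthly
precipitation; `y` indexes fire years.

## 1. Calendars

A **fire year** is the 12-month window running from five months before to six
months after the burning-season peak month (September by default), i.e.
April–March, labelled by its starting calendar year. Every calendar month
belongs to exactly one fire year for any peak month (partition property,
tested exhaustively). Deforestation is reported on an August–July year
labelled by its end year; at lag 0 reporting year `Y` (deforested 1 Aug `Y−1`
to 31 Jul `Y`) pairs with fire year `Y`, at lag +1 with fire year `Y−1`.

## 2. The per-cell adjustment

For window length `T` and fire year `y` with peak month `m`:

```
AP(y; T) = (1/T) · Σ_{k=1..T} P(month m−k of fire year y)
```

Both `AP(·; T)` and `FP` are decomposed exactly by OLS-on-year into a fitted
line plus residuals (`TREND + IAV`). The coupling is estimated by
no-intercept OLS on the residuals:

```
b0(T) = Σ_y AP_IAV·FP_IAV / Σ_y AP_IAV²
```

`T_opt = argmax_T |r(T)|` where `r` is the Pearson correlation of the two IAV
series; ties break to the smallest `T` (parsimony). The precipitation-induced
series is `FP_precip(y) = b0(T_opt)·AP(y; T_opt)` using the **full**
antecedent precipitation, and the adjusted series is
`FP_PA = FP − FP_precip`, with no clipping.

Consequences of using the full `AP`, recorded deliberately:

- `FP_PA` is shifted in level by `−b0·mean(AP)` (upward for `b0 < 0`); the
  series is a statistical construct, not a physical count. The option
  `recenter_adjusted=True` adds the observed mean back.
- The adjusted trend equals the observed trend minus `b0` times the sample
  trend of `AP`, so in a noiseless simulation the adjusted series is exactly
  linear but with a slope `trend − b0·slope(AP)` rather than the generator's
  configured fire trend. Tests assert this exact identity.
- In a step-change ("decoupling") scene, the step survives in `FP_PA` but its
  multiplicative factor is diluted by the level shift; factor-recovery
  calibration is therefore performed directly on ratio series with a
  configured step.

Edge cases: cells whose annual fire series has zero variance are passed
through unadjusted and flagged (`unadjustable`); a window with any missing
precipitation month drops that year for that `T`; a window for which
`Σ AP_IAV² = 0` is undefined and skipped.

## 3. Regional statistics

- **Aggregation**: per variable — counts and emissions are summed over the
  region, AOD is averaged, burned fraction is an area-weighted percentage of
  the region (cell areas from the spherical cosine-latitude rule,
  111.195 km/deg).
- **Trends**: OLS slope on fire year; 95% CI = `t₀.₉₇₅,ₙ₋₂ · s / √Sxx`;
  significance ⇔ the CI excludes zero; `R²` defined as 0 for a flat series.
- **Relative trends**: `100 · slope / mean(series)` with the CI scaled
  identically; undefined (flagged) when the mean is non-positive.
- **Correlations**: Pearson `r` with a two-sided t-test at 5%; no
  multiple-testing correction (recorded in the output manifest).
- **Ratio series**: `FP / deforestation` per year; years with non-positive
  deforestation become missing (logged).
- **Period comparison**: per-period mean with a t-based SEM 95% interval;
  `factor = mean₂ / mean₁`; the factor CI uses first-order (delta-method)
  propagation of the two SEMs with `n₁ + n₂ − 2` degrees of freedom;
  significance ⇔ the factor CI excludes 1. Monte-Carlo calibration (500
  replicates, ×2.5 step, 10% noise) gives mean factor 2.50 and 95.2% CI
  coverage.

## 4. Synthetic generator

Design goal: every estimator above must be a *sharp* test against known
ground truth, so the fire generator inverts the estimator's own model rather
than simulating fire physics.

- **Precipitation**: sinusoidal seasonal cycle (mean 175 mm/month, amplitude
  140, March peak ≈ 315 mm, September ≈ 35 mm) + a Gaussian interannual
  anomaly shared by all months of a fire year (sd 15 mm) + per-cell-month
  Gaussian jitter (sd 30 mm) + optional linear trend, truncated at 0. The
  record starts 24 months before the first fire year so every window length
  up to 24 is computable. The month-level jitter is a *requirement, not a
  nicety*: with only a fire-year-shared anomaly, all windows inside one fire
  year would be perfectly collinear and `T` would be unidentifiable.
- **Fire parameter**: per cell, `T_true ~ U{1..12}` and
  `b0_true ~ U(−2, −0.5)` (negative coupling: wet antecedent conditions
  suppress fire). Annual values are
  `baseline + trend·t + b0_true·AP_IAV(T_true) + noise`, with noise sd
  defaulting to 10% of the coupled-signal sd. Annual values are spread over
  the fire-year months with a fixed unimodal profile (Aug 30%, Sep 45%,
  Oct 15%, remaining 10% uniform), normalised to sum to exactly 1 so monthly
  sums reproduce the annual truth bit-for-bit.
- **Deforestation**: linear rise from 18,000 to a 27,000 km²/yr peak in
  2004, geometric decline to a 6,500 km²/yr plateau in 2009, multiplicative
  plateau noise (cv 8%).
- **Point detections**: each cell-month count (rounded, clipped at 0) is
  realised as uniform points inside the cell with confidence `U(60, 100)`, so
  a ≥80 confidence filter keeps 50% in expectation; gridding the points with
  `min_confidence=0` reproduces the rounded field exactly (inverse-operation
  test).
- **Presets**: `null` (no coupling, no trends — false-positive control),
  `coupled` (the defaults above), `decoupling` (×2.5 annual step from 2009
  against flat deforestation).
- **Determinism**: one integer seed is spawned via `SeedSequence` into named
  independent streams (anomaly, jitter, b0, T, noise, deforestation, points);
  identical configs give bit-identical fields.

Realism and limits: the generator reproduces the *statistical structure* the
estimator relies on (seasonality, shared interannual anomaly, antecedent
coupling, window heterogeneity) but not fire physics — no spatial
autocorrelation between cells, no human-ignition covariates, linear response
only, and fire "counts" are continuous before point realisation. Recovery
rates on synthetic data are therefore upper bounds on real-data performance.

## 5. Numerical choices

- All arithmetic in float64; NetCDF I/O through xarray's scipy backend
  (NetCDF3 64-bit container) with bit-exact float64 round trips and NaN as
  the missing value.
- The grid fit is vectorised: a cumulative-sum stack gives all 24 AP windows
  at once, and the per-window statistics (`Σx²`, `Σxy`, `Σy²`) are formed by
  `einsum`; a per-cell fallback handles precipitation records with gaps.
  A 20×20 grid × 16 years × 24 windows fits in ~0.1 s.
- Grid cells are half-open `[edge, edge + resolution)`; confidence filtering
  is inclusive (≥ 80); regridding 0.25°→0.50° is a 2×2 block `nanmean`.
- Window search maximises `|r|` with exact comparisons; a separately coded
  brute-force oracle (scipy `pearsonr` + `polyfit`) agrees on 100% of 200
  random cells.
- The pipeline's config hash (sha256 over the config excluding the output
  path) is written to `manifest.json`; all CSV/JSON outputs are byte-stable
  across reruns.
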