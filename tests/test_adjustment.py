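"""Core precipitation-adjustment algorithm: detrending, window search, adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fireadjust as fa
from fireadjust.exceptions import (AlignmentError, InsufficientDataError,
                                   UndefinedFitError)


def monthly_series(values, start="2001-01"):
    idx = pd.period_range(start, periods=len(values), freq="M")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_b0(fp_iav, ap_iav, grid_width=8.0, n_grid=160001):
    """Minimise the sum of squared errors over a dense b0 grid."""
    b0s = np.linspace(-grid_width, grid_width, n_grid)
    sse = ((fp_iav[None, :] - b0s[:, None] * ap_iav[None, :]) ** 2).sum(axis=1)
    return b0s[np.argmin(sse)], b0s[1] - b0s[0]


def brute_force_select(P, fp, calendar, max_window=24):
    """Exhaustive, independently coded 24-window search (scipy-based)."""
    from scipy import stats
    years = np.asarray(fp.index, dtype=int)
    best = (-1.0, None)
    for T in range(1, max_window + 1):
        ap = []
        for y in years:
            peak = pd.Period(f"{y}-{calendar.peak_month:02d}", freq="M")
            ap.append(np.mean([P.loc[peak - k] for k in range(1, T + 1)]))
        ap = np.asarray(ap)
        ap_iav = ap - np.polyval(np.polyfit(years, ap, 1), years)
        fp_iav = fp.to_numpy() - np.polyval(np.polyfit(years, fp.to_numpy(), 1), years)
        if np.allclose(ap_iav, 0):
            continue
        r = stats.pearsonr(fp_iav, ap_iav).statistic if np.ptp(fp_iav) > 0 else 0.0
        if abs(r) > best[0] + 1e-12:
            best = (abs(r), T)
    return best[1]


class TestDetrend:
    def test_perfectly_linear(self):
        res = fa.detrend([1, 2, 3, 4, 5], [2001, 2002, 2003, 2004, 2005])
        np.testing.assert_allclose(res.trend_component, [1, 2, 3, 4, 5], atol=1e-12)
        np.testing.assert_allclose(res.iav_component, 0, atol=1e-12)

    def test_constant_series(self):
        res = fa.detrend([3.0, 3.0, 3.0], [0, 1, 2])
        np.testing.assert_allclose(res.trend_component, 3.0)
        np.testing.assert_allclose(res.iav_component, 0, atol=1e-12)

    def test_closed_form_hand_example(self):
        res = fa.detrend([2.0, 1.0, 3.0], [0, 1, 2])
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(1.5)
        np.testing.assert_allclose(res.iav_component, [0.5, -1.0, 0.5], atol=1e-12)

    def test_too_few_years(self):
        with pytest.raises(InsufficientDataError):
            fa.detrend([1.0, 2.0], [0, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40),
           st.integers(1900, 2100))
    def test_exact_reconstruction_and_zero_mean_iav(self, values, y0):
        years = np.arange(y0, y0 + len(values))
        res = fa.detrend(values, years)
        scale = max(np.abs(values).max(), 1.0)
        np.testing.assert_allclose(res.trend_component + res.iav_component,
                                   values, atol=1e-9 * scale)
        assert abs(res.iav_component.sum()) <= 1e-9 * scale * len(values)


class TestAntecedentPrecip:
    def test_constant_input_any_window(self, calendar):
        P = monthly_series([100.0] * 120, start="1999-01")
        for T in (1, 6, 24):
            ap = fa.antecedent_precip(P, calendar, T, [2001, 2002])
            np.testing.assert_allclose(ap.to_numpy(), 100.0)

    def test_single_month_window_is_august(self, calendar):
        P = monthly_series(np.arange(60, dtype=float), start="2000-01")
        ap = fa.antecedent_precip(P, calendar, 1, [2001])
        august_2001 = P.loc[pd.Period("2001-08", freq="M")]
        assert ap.loc[2001] == august_2001

    def test_three_month_window_hand_value(self, calendar):
        # Mar-Aug 2001 = [300, 200, 150, 100, 50, 20]
        values = np.zeros(24)
        values[14:20] = [300, 200, 150, 100, 50, 20]  # Mar 2001 at index 14
        P = monthly_series(values, start="2000-01")
        ap = fa.antecedent_precip(P, calendar, 3, [2001])
        assert ap.loc[2001] == pytest.approx((100 + 50 + 20) / 3)

    def test_insufficient_head_start_drops_years(self, calendar):
        P = monthly_series([100.0] * 30, start="2001-01")
        with pytest.warns(UserWarning):
            ap = fa.antecedent_precip(P, calendar, 12, [2001, 2002])
        assert list(ap.index) == [2002]

    def test_missing_month_invalidates_window(self, calendar):
        values = np.full(60, 100.0)
        values[31] = np.nan  # Aug 2001
        P = monthly_series(values, start="1999-01")
        with pytest.warns(UserWarning):
            ap = fa.antecedent_precip(P, calendar, 2, [2001, 2002])
        assert list(ap.index) == [2002]


class TestNoInterceptFit:
    def test_exact_proportionality(self):
        x = np.array([1.0, -2.0, 0.5, 0.5])
        f = fa.fit_no_intercept(2 * x, x)
        assert f.b0 == pytest.approx(2.0)
        assert f.r == pytest.approx(1.0)

    def test_orthogonal_inputs_give_zero(self):
        f = fa.fit_no_intercept([1.0, 1.0, 0.0], [1.0, -1.0, 0.0])
        assert f.b0 == pytest.approx(0.0)

    def test_closed_form_vs_brute_force(self):
        ap = np.array([1.0, -1.0, 0.0])
        fp = np.array([2.0, 0.0, 1.0])
        f = fa.fit_no_intercept(fp, ap)
        assert f.b0 == pytest.approx(1.0)
        np.testing.assert_allclose(f.residuals, [1.0, 1.0, 1.0], atol=1e-12)
        b0_bf, step = brute_force_b0(fp, ap)
        assert abs(f.b0 - b0_bf) <= step

    def test_zero_regressor_undefined(self):
        with pytest.raises(UndefinedFitError):
            fa.fit_no_intercept([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_sse_on_random_series(self, seed):
        r = np.random.default_rng(seed)
        ap = r.normal(0, 1, 10)
        fp = r.normal(0, 2, 10)
        f = fa.fit_no_intercept(fp, ap)
        b0_bf, step = brute_force_b0(fp, ap)
        assert abs(f.b0 - b0_bf) <= step
        # residual orthogonality and variance non-increase (OLS optimality)
        assert abs(f.residuals @ ap) <= 1e-9 * max(np.abs(fp).max(), 1.0) * 10
        assert f.residuals @ f.residuals <= fp @ fp + 1e-12


class TestSelectWindow:
    def _coupled_cell(self, T_true, b0_true, seed=0, noise_sd=0.0, n_years=16):
        """Build FP = trend + b0 * AP_IAV(T_true) + noise from random precipitation."""
        r = np.random.default_rng(seed)
        cal = fa.AnalysisCalendar()
        n_months = 24 + 12 * n_years
        P = monthly_series(r.uniform(20, 320, n_months), start=f"{2001 - 2}-04")
        years = np.arange(2001, 2001 + n_years)
        ap = fa.antecedent_precip(P, cal, T_true, years)
        ap_iav = fa.detrend(ap.to_numpy(), years).iav_component
        fp = 100.0 - 2.0 * (years - years[0]) + b0_true * ap_iav
        fp = fp + r.normal(0, noise_sd, n_years)
        return P, pd.Series(fp, index=years), cal

    def test_noiseless_construction_recovered_exactly(self):
        P, fp, cal = self._coupled_cell(T_true=5, b0_true=-3.0, seed=1)
        fit = fa.select_window(P, fp, cal)
        assert fit.T_opt == 5
        assert abs(fit.r) == pytest.approx(1.0)
        assert fit.b0 == pytest.approx(-3.0)

    def test_tie_breaks_to_smallest_window(self, calendar):
        # constant precipitation everywhere except one informative month makes
        # windows 1 and 2 carry identical (scaled) anomalies -> identical |r|
        r = np.random.default_rng(3)
        n_years = 10
        values = np.full(24 + 12 * n_years, 100.0)
        P = monthly_series(values, start="1999-04")
        years = np.arange(2001, 2001 + n_years)
        # vary only August: AP(1) = aug, AP(2) = (jul + aug)/2 = 50 + aug/2
        aug = r.uniform(50, 150, n_years)
        for y, v in zip(years, aug):
            P.loc[pd.Period(f"{y}-08", freq="M")] = v
        fp = pd.Series(2.0 * aug, index=years)
        fit = fa.select_window(P, fp, calendar)
        assert abs(fit.candidate_r[0]) == pytest.approx(abs(fit.candidate_r[1]))
        assert fit.T_opt == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_agrees_with_brute_force_oracle_on_noise(self, seed):
        """On pure white-noise FP the selected window matches an exhaustive search."""
        r = np.random.default_rng(seed)
        P, _, cal = self._coupled_cell(T_true=1, b0_true=0.0, seed=seed)
        years = np.arange(2001, 2017)
        fp = pd.Series(r.normal(100, 10, 16), index=years)
        fit = fa.select_window(P, fp, cal)
        assert fit.T_opt == brute_force_select(P, fp, cal)

    def test_flat_fire_parameter_yields_zero_coupling(self):
        P, fp, cal = self._coupled_cell(T_true=3, b0_true=-2.0, seed=7)
        flat = pd.Series(np.full(fp.size, 4.0), index=fp.index)
        fit = fa.select_window(P, flat, cal)
        assert fit.b0 == 0.0
        assert fit.r == 0.0


class TestAdjust:
    def test_zero_induction_identity(self):
        fp = pd.Series([20.0, 25.0, 30.0], index=[2001, 2002, 2003])
        zero = pd.Series(np.zeros(3), index=fp.index)
        adj = fa.adjust(fp, zero)
        np.testing.assert_array_equal(adj.adjusted, fp.to_numpy())

    def test_elementwise_subtraction(self):
        fp = pd.Series([20.0, 25.0], index=[2001, 2002])
        ind = pd.Series([10.0, 12.0], index=[2001, 2002])
        np.testing.assert_array_equal(fa.adjust(fp, ind).adjusted, [10.0, 13.0])

    def test_label_mismatch_raises(self):
        fp = pd.Series([1.0, 2.0], index=[2001, 2002])
        ind = pd.Series([1.0, 2.0], index=[2002, 2003])
        with pytest.raises(AlignmentError):
            fa.adjust(fp, ind)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_reconstruction_identity(self, seed):
        r = np.random.default_rng(seed)
        years = np.arange(2001, 2011)
        fp = pd.Series(r.normal(0, 100, 10), index=years)
        ind = pd.Series(r.normal(0, 50, 10), index=years)
        adj = fa.adjust(fp, ind)
        np.testing.assert_allclose(adj.adjusted + adj.precipitation_induced,
                                   adj.observed, rtol=0, atol=1e-9)

    def test_precip_induced_scaling(self):
        P, fp, cal = 0, 0, 0  # unused
        fit = fa.CellFit(T_opt=1, b0=-3.5, r=-1.0, residuals=np.zeros(3),
                         years=np.array([2001, 2002, 2003]),
                         candidate_r=np.zeros(24), candidate_b0=np.zeros(24),
                         fp_detrend=None, ap_detrend=None)
        ap = pd.Series([2.0, 4.0, 0.0], index=[2001, 2002, 2003])
        np.testing.assert_array_equal(fa.precip_induced(fit, ap).to_numpy(),
                                      [-7.0, -14.0, 0.0])


class TestGridModel:
    def test_zero_fire_everywhere_flagged(self, coupled_bundle):
        cfg, P, F, truth, mask = coupled_bundle
        zero = fa.MonthlyField(grid=F.grid, variable="fire_count", units=F.units,
                               start=F.start, values=np.zeros_like(F.values))
        res = fa.PrecipAdjustmentModel(P, zero, mask).fit()
        assert res.unadjustable.all()
        np.testing.assert_array_equal(res.adjusted, 0.0)
        np.testing.assert_array_equal(res.b0, 0.0)

    def test_single_active_cell_regional_series(self, coupled_bundle):
        cfg, P, F, truth, mask = coupled_bundle
        values = np.zeros_like(F.values)
        values[:, 2, 3] = F.values[:, 2, 3]
        single = fa.MonthlyField(grid=F.grid, variable="fire_count", units=F.units,
                                 start=F.start, values=values)
        res = fa.PrecipAdjustmentModel(P, single, mask).fit()
        fit, adj = fa.adjust_cell(P.cell_series(2, 3), single.cell_series(2, 3)
                                  .groupby(lambda p: fa.fire_year_of(cfg.calendar,
                                                                     p.year, p.month))
                                  .sum(), cfg.calendar)
        regional = res.regional_series("BLA", method="sum")
        np.testing.assert_allclose(regional["adjusted"].to_numpy(), adj.adjusted,
                                   rtol=1e-9)

    def test_vectorised_fit_matches_scalar_path(self, coupled_bundle):
        """The fast lattice fit agrees with the per-cell scalar pathway."""
        cfg, P, F, truth, mask = coupled_bundle
        res = fa.PrecipAdjustmentModel(P, F, mask).fit()
        rng = np.random.default_rng(5)
        for _ in range(8):
            i, j = rng.integers(0, F.grid.n_rows), rng.integers(0, F.grid.n_cols)
            fp_monthly = F.cell_series(i, j)
            fp = fp_monthly.groupby(
                lambda p: fa.fire_year_of(cfg.calendar, p.year, p.month)).sum()
            fit = fa.select_window(P.cell_series(i, j), fp, cfg.calendar)
            assert res.T_opt[i, j] == fit.T_opt
            assert res.b0[i, j] == pytest.approx(fit.b0, rel=1e-9)
            assert res.r[i, j] == pytest.approx(fit.r, rel=1e-9)

    def test_orthogonality_and_variance_nonincrease(self, coupled_bundle):
        cfg, P, F, truth, mask = coupled_bundle
        res = fa.PrecipAdjustmentModel(P, F, mask).fit()
        years = res.years.astype(float)
        t = years - years.mean()
        for (i, j) in [(0, 0), (4, 7), (9, 9)]:
            fp = res.observed[:, i, j]
            fit = fa.select_window(P.cell_series(i, j),
                                   pd.Series(fp, index=res.years), cfg.calendar)
            ap_iav = fit.ap_detrend.iav_component
            scale = max(np.abs(fit.fp_detrend.iav_component).max(), 1.0)
            assert abs(fit.residuals @ ap_iav) <= 1e-9 * scale * len(years)
            assert fit.residuals @ fit.residuals <= (
                fit.fp_detrend.iav_component @ fit.fp_detrend.iav_component) + 1e-9
            # de-trended adjusted series is uncorrelated with AP_IAV at T_opt
            adj = res.adjusted[:, i, j]
            adj_iav = fa.detrend(adj, res.years).iav_component
            denom = np.linalg.norm(adj_iav) * np.linalg.norm(ap_iav)
            if denom > 0:
                assert abs(adj_iav @ ap_iav) / denom < 1e-6

    def test_noiseless_adjusted_is_exactly_linear(self):
        """Zero-noise coupling: adjusted series collapses to a straight line."""
        import dataclasses
        cfg = fa.make_config("coupled", seed=9)
        cfg.fire = dataclasses.replace(cfg.fire, noise_frac=None, noise_sd=None)
        rngs = cfg.rngs()
        P = fa.generate_precipitation(cfg, rngs)
        F, truth = fa.generate_fire_parameter(cfg, P, rngs)
        mask = fa.synthetic_region_mask(cfg.grid)
        res = fa.PrecipAdjustmentModel(P, F, mask).fit()
        np.testing.assert_array_equal(res.T_opt, truth.T_field)
        np.testing.assert_allclose(res.b0, truth.b0_field, rtol=1e-9)
        years = res.years.astype(float)
        for (i, j) in [(0, 0), (5, 5)]:
            adj = res.adjusted[:, i, j]
            resid = fa.detrend(adj, res.years).iav_component
            assert np.abs(resid).max() <= 1e-9 * max(np.abs(adj).max(), 1.0)
            # slope identity: trend - b0 * slope(AP at T_true)
            ap = fa.antecedent_precip(P.cell_series(i, j), cfg.calendar,
                                      int(truth.T_field[i, j]), res.years)
            ap_slope = fa.detrend(ap.to_numpy(), res.years).slope
            expected = truth.fire_trend_field[i, j] - truth.b0_field[i, j] * ap_slope
            assert fa.detrend(adj, res.years).slope == pytest.approx(expected, rel=1e-9)

    def test_grid_mismatch_rejected(self, coupled_bundle):
        cfg, P, F, truth, mask = coupled_bundle
        other = fa.GridSpec(0.50, P.grid.lat_min, P.grid.lat_max,
                            P.grid.lon_min, P.grid.lon_max)
        coarse_P = fa.regrid_mean(P, other)
        with pytest.raises(fa.GridError):
            fa.PrecipAdjustmentModel(coarse_P, F, mask)

    def test_summary_mentions_variable_and_cells(self, coupled_bundle):
        cfg, P, F, truth, mask = coupled_bundle
        res = fa.PrecipAdjustmentModel(P, F, mask).fit()
        text = res.summary()
        assert "fire_count" in text and "cells fitted" in text
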