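"""Curve prediction, MMT search/bootstrap, annual anchors, climate trends."""

import numpy as np
import pandas as pd
import pytest

from tvdlnm import (BasisSpec, DailySeries, RunConfig, ScenarioTruth,
                    annual_indicators, find_mmt, ns_basis, predict_curve,
                    simulate_city, temperature_trends)
from tvdlnm.crossbasis import crossbasis_prediction_vector
from tvdlnm.tvmodel import TimeSliceCoefs

LIN = BasisSpec("linear", (), (0.0, 40.0), intercept=False)
CONST = BasisSpec("const")


def make_slice(beta, vcov):
    return TimeSliceCoefs(centre=pd.Timestamp("2000-07-01"),
                          beta=np.atleast_1d(np.asarray(beta, float)),
                          vcov=np.atleast_2d(np.asarray(vcov, float)))


class TestPredictCurve:
    def test_null_coefficients_give_unit_crr(self):
        ts = make_slice([0.0], [[0.01]])
        c = predict_curve(ts, np.arange(10.0, 31.0), 20.0, LIN, CONST, 0)
        np.testing.assert_array_equal(c.crr, 1.0)
        assert (c.crr_low <= c.crr).all() and (c.crr <= c.crr_high).all()

    def test_scalar_closed_form(self):
        # w(x) = x, beta = 0.05, ref 20 -> crr(25) = exp(0.25)
        ts = make_slice([0.05], [[0.0]])
        c = predict_curve(ts, np.arange(10.0, 31.0), 20.0, LIN, CONST, 0)
        i = np.where(c.grid == 25.0)[0][0]
        np.testing.assert_allclose(c.crr[i], np.exp(0.25), rtol=1e-12)

    def test_reference_identity(self):
        ts = make_slice([0.3], [[0.02]])
        grid = np.arange(10.0, 31.0)
        c = predict_curve(ts, grid, 20.0, LIN, CONST, 0)
        i = np.where(grid == 20.0)[0][0]
        assert c.crr[i] == 1.0 and c.se[i] == 0.0

    def test_reference_outside_grid_rejected(self):
        ts = make_slice([0.3], [[0.02]])
        with pytest.raises(ValueError, match="outside grid"):
            predict_curve(ts, np.arange(10.0, 31.0), 45.0, LIN, CONST, 0)

    def test_ci_consistency_where_effect_insignificant(self):
        # |log_crr| < 1.96 se  ->  CI straddles 1
        ts = make_slice([0.01], [[0.04]])
        c = predict_curve(ts, np.arange(18.0, 23.0, 0.5), 20.0, LIN, CONST, 0)
        weak = np.abs(c.log_crr) < 1.96 * c.se
        assert (c.crr_low[weak] < 1.0).all() and (c.crr_high[weak] > 1.0).all()


def quadratic_slice(minimum=21.0, scale=0.01):
    """Project a quadratic with known minimum onto a rich natural-spline
    space so the constrained argmin can be checked against the truth."""
    espec = BasisSpec("ns", (14.0, 18.0, 21.0, 24.0, 27.0), (8.0, 32.0),
                      intercept=False)
    dense = np.linspace(9.0, 31.0, 400)
    B = np.column_stack([np.ones_like(dense), ns_basis(dense, espec)])
    target = scale * (dense - minimum) ** 2
    coef, *_ = np.linalg.lstsq(B, target, rcond=None)
    return espec, coef[1:]


class TestFindMMT:
    config = RunConfig(seed=5, n_boot=200)

    def exposure(self):
        rng = np.random.default_rng(0)
        return rng.uniform(10.0, 30.0, 2000)

    def test_quadratic_minimum_recovered(self, rng):
        espec, beta = quadratic_slice(21.0)
        ts = make_slice(beta, np.zeros((len(beta), len(beta))))
        est = find_mmt(ts, self.exposure(), self.config, espec, CONST, rng)
        assert abs(est.mmt - 21.0) <= 0.1 + 0.05

    def test_monotone_curve_clamps_to_boundary(self, rng):
        ts = make_slice([-0.1], [[1e-6]])
        est = find_mmt(ts, self.exposure(), self.config, LIN, CONST, rng)
        assert est.mmt == pytest.approx(est.constrained_range[1], abs=0.11)
        assert est.boundary_dominated

    def test_degenerate_bootstrap_with_zero_covariance(self, rng):
        espec, beta = quadratic_slice(20.0)
        ts = make_slice(beta, np.zeros((len(beta), len(beta))))
        est = find_mmt(ts, self.exposure(), self.config, espec, CONST, rng)
        assert est.eci_high - est.eci_low == 0.0 and est.se < 1e-12

    def test_flat_curve_rejected(self, rng):
        ts = make_slice([0.0], [[0.01]])
        with pytest.raises(ValueError, match="flat"):
            find_mmt(ts, self.exposure(), self.config, LIN, CONST, rng)

    def test_bootstrap_deterministic_under_seed(self):
        espec, beta = quadratic_slice(22.0)
        V = 1e-4 * np.eye(len(beta))
        ts = make_slice(beta, V)
        a = find_mmt(ts, self.exposure(), self.config, espec, CONST,
                     np.random.default_rng(77))
        b = find_mmt(ts, self.exposure(), self.config, espec, CONST,
                     np.random.default_rng(77))
        assert (a.mmt, a.eci_low, a.eci_high, a.se) == \
               (b.mmt, b.eci_low, b.eci_high, b.se)

    def test_widening_constraint_cannot_raise_minimum(self, rng):
        espec, beta = quadratic_slice(21.0)
        ts = make_slice(beta, np.zeros((len(beta), len(beta))))
        narrow = find_mmt(ts, self.exposure(), self.config.replace(
            mmt_constraint=(10.0, 90.0)), espec, CONST, rng)
        wide = find_mmt(ts, self.exposure(), self.config.replace(
            mmt_constraint=(1.0, 99.0)), espec, CONST, rng)
        W = crossbasis_prediction_vector(
            np.array([narrow.mmt, wide.mmt]), espec, CONST, 0)
        log_narrow, log_wide = W @ ts.beta
        assert log_wide <= log_narrow + 1e-12


class TestAnnualIndicators:
    def test_anchor_ordering_and_reference(self, small_sim, small_fit, rng):
        _, series, truth_mmt, _ = small_sim
        design, fit = small_fit
        ann = annual_indicators(fit, design, 2001, rng)
        assert ann.p1 <= ann.p10 <= ann.p90 <= ann.p99
        assert ann.mmt.constrained_range[0] <= ann.mmt.mmt \
            <= ann.mmt.constrained_range[1]
        # re-centred at the MMT every anchor cRR must be >= ~1 grid-step down
        for est, lo, hi in ann.crr.values():
            assert lo <= est <= hi

    def test_missing_year_rejected(self, small_fit, rng):
        design, fit = small_fit
        with pytest.raises(ValueError, match="not in series"):
            annual_indicators(fit, design, 2050, rng)


class TestTemperatureTrends:
    @staticmethod
    def drift_series(slope, n_years=6, seed=0):
        truth = ScenarioTruth(deaths_per_day=50)
        series, *_ = simulate_city(truth, n_years, seed=seed)
        df = series.frame.copy()
        t = np.arange(len(df)) / 365.25
        df["tmean"] = df["tmean"] + slope * t
        return DailySeries(df)

    def test_generated_drift_recovered(self):
        slopes = []
        for seed in range(5):
            table = temperature_trends(self.drift_series(0.05, seed=seed))
            slopes.append(
                table.loc[table["indicator"] == "amt", "slope"].iloc[0])
        assert abs(np.median(slopes) - 0.05) < 0.04

    def test_repeated_annual_cycle_has_zero_slope(self):
        one_year = 19.0 + 4.0 * np.cos(2 * np.pi * np.arange(365) / 365)
        frame = pd.DataFrame({
            "date": pd.date_range("2001-01-01", periods=365 * 3),
            "tmean": np.tile(one_year, 3), "rh": 70.0, "pm10": 30.0,
            "holiday": False, "deaths_all": 1})
        table = temperature_trends(DailySeries(frame))
        np.testing.assert_allclose(table["slope"], 0.0, atol=1e-12)

    def test_fewer_than_three_years_rejected(self):
        frame = pd.DataFrame({
            "date": pd.date_range("2001-01-01", periods=500),
            "tmean": 20.0, "rh": 70.0, "pm10": 30.0, "holiday": False,
            "deaths_all": 1})
        with pytest.raises(ValueError, match="3 calendar years"):
            temperature_trends(DailySeries(frame))
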