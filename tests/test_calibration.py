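"""Calibration tests: exact 4PL recovery, linear sensitivity, inversion
round trips, and estimator unbiasedness under additive noise."""

import numpy as np
import pandas as pd
import pytest

from specklequant.calibration import (
    CalibrationError,
    LinearFit,
    fit_linear_sensitivity,
    fit_logistic,
    invert_concentration,
)


def make_curve(concs, means):
    return pd.DataFrame(
        {
            "concentration_ng_per_ml": concs,
            "mean_zncc": means,
            "sd_zncc": 0.0,
            "n": 10,
        }
    )


def four_pl(c, lower, upper, mid, b):
    return lower + (upper - lower) / (1.0 + (np.asarray(c) / mid) ** b)


CONCS = np.array([1.0, 5.0, 10.0, 20.0, 30.0, 50.0, 100.0, 500.0, 1000.0])


class TestLogisticFit:
    def test_noise_free_recovery(self):
        truth = dict(lower=0.55, upper=0.99, mid=80.0, b=1.3)
        curve = make_curve(CONCS, four_pl(CONCS, *truth.values()))
        fit = fit_logistic(curve)
        assert fit.lower_asymptote == pytest.approx(truth["lower"], rel=1e-6)
        assert fit.upper_asymptote == pytest.approx(truth["upper"], rel=1e-6)
        assert fit.midpoint == pytest.approx(truth["mid"], rel=1e-6)
        assert fit.slope_factor == pytest.approx(truth["b"], rel=1e-6)
        assert fit.r_squared > 1 - 1e-10

    def test_rising_curve_also_recovered(self):
        curve = make_curve(CONCS, four_pl(CONCS, 0.9, 0.2, 50.0, -1.0))
        fit = fit_logistic(curve)
        assert fit.upper_asymptote >= fit.lower_asymptote
        np.testing.assert_allclose(fit.predict(CONCS), curve["mean_zncc"], atol=1e-8)

    def test_flat_curve_degenerate(self):
        with pytest.raises(CalibrationError, match="degenerate|span"):
            fit_logistic(make_curve(CONCS, np.full(9, 0.8)))

    def test_too_few_points(self):
        with pytest.raises(CalibrationError, match=">= 4"):
            fit_logistic(make_curve([1.0, 10.0, 100.0], [0.9, 0.8, 0.7]))

    def test_monotone_over_data_span(self):
        curve = make_curve(CONCS, four_pl(CONCS, 0.6, 0.95, 60.0, 0.9))
        fit = fit_logistic(curve)
        pred = fit.predict(np.logspace(0, 3, 50))
        assert np.all(np.diff(pred) < 1e-12)


class TestLinearSensitivity:
    def test_exact_line_recovery(self):
        c = np.array([1.0, 5.0, 10.0, 20.0, 30.0, 50.0])
        fit = fit_linear_sensitivity(make_curve(c, 1.0 - 0.0012 * c))
        assert fit.sensitivity == pytest.approx(0.0012, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_restricts_to_range(self):
        curve = make_curve(CONCS, 1.0 - 0.0012 * np.minimum(CONCS, 60.0))
        fit = fit_linear_sensitivity(curve, 1.0, 50.0)
        assert fit.sensitivity == pytest.approx(0.0012, abs=1e-12)

    def test_two_points_exact(self):
        fit = fit_linear_sensitivity(make_curve([2.0, 40.0], [0.99, 0.90]))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.predict(2.0) == pytest.approx(0.99)

    def test_insufficient_points(self):
        with pytest.raises(CalibrationError, match=">= 2"):
            fit_linear_sensitivity(make_curve([100.0, 500.0], [0.8, 0.7]))

    def test_inverse_variance_weighting_recovers_exact_line(self):
        c = np.array([1.0, 5.0, 10.0, 20.0, 30.0, 50.0])
        curve = make_curve(c, 1.0 - 0.0012 * c)
        curve["sd_zncc"] = np.linspace(0.001, 0.003, 6)
        fit = fit_linear_sensitivity(curve, weighted=True)
        assert fit.sensitivity == pytest.approx(0.0012, abs=1e-12)
        # heteroscedastic noise: weighted estimator still unbiased
        rng = np.random.default_rng(3)
        est = []
        for _ in range(200):
            noisy = curve.copy()
            noisy["mean_zncc"] = (
                1.0 - 0.0012 * c + rng.normal(0, noisy["sd_zncc"] / np.sqrt(10))
            )
            est.append(fit_linear_sensitivity(noisy, weighted=True).slope)
        est = np.asarray(est)
        sem = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() + 0.0012) < 3 * sem

    def test_unbiased_under_noise(self):
        """|slope| estimate over 200 noisy replicates is unbiased within
        Monte-Carlo error."""
        c = np.array([1.0, 5.0, 10.0, 20.0, 30.0, 50.0])
        true_slope = -0.0012
        sigma = 0.002
        rng = np.random.default_rng(7)
        est = []
        for _ in range(200):
            z = 1.0 + true_slope * c + rng.normal(0, sigma, c.size)
            est.append(fit_linear_sensitivity(make_curve(c, z)).slope)
        est = np.asarray(est)
        sem = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - true_slope) < 3 * sem


class TestInversion:
    def test_logistic_round_trip(self):
        curve = make_curve(CONCS, four_pl(CONCS, 0.55, 0.99, 80.0, 1.3))
        fit = fit_logistic(curve)
        for c in (5.0, 20.0, 300.0):
            z = float(fit.predict(c))
            c_hat, extrapolated = invert_concentration(fit, z)
            assert not extrapolated
            assert c_hat == pytest.approx(c, abs=1e-9 * max(c, 1))

    def test_midpoint_identity(self):
        fit = fit_logistic(make_curve(CONCS, four_pl(CONCS, 0.5, 0.9, 50.0, 1.0)))
        c_hat, _ = invert_concentration(fit, 0.7)  # half-way response
        assert c_hat == pytest.approx(50.0, rel=1e-6)

    def test_out_of_span_sets_flag(self):
        fit = fit_logistic(make_curve(CONCS, four_pl(CONCS, 0.55, 0.99, 80.0, 1.3)))
        c_hat, extrapolated = invert_concentration(fit, 0.999)  # above upper asymptote
        assert extrapolated and c_hat == pytest.approx(fit.c_min)
        c_hat, extrapolated = invert_concentration(fit, 0.1)  # below lower asymptote
        assert extrapolated and c_hat == pytest.approx(fit.c_max)

    def test_linear_round_trip_and_boundaries(self):
        fit = fit_linear_sensitivity(
            make_curve([1.0, 10.0, 30.0, 50.0], 1.0 - 0.0012 * np.array([1, 10, 30, 50.0]))
        )
        c_hat, extrapolated = invert_concentration(fit, float(fit.predict(20.0)))
        assert not extrapolated and c_hat == pytest.approx(20.0, abs=1e-9)
        c_hat, extrapolated = invert_concentration(fit, 2.0)  # impossibly high ZNCC
        assert extrapolated and c_hat == fit.fit_range[0]

    def test_zero_slope_not_invertible(self):
        fit = LinearFit(slope=0.0, intercept=0.9, fit_range=(1.0, 50.0), r_squared=0.0)
        with pytest.raises(CalibrationError, match="not invertible"):
            invert_concentration(fit, 0.9)

    def test_nonfinite_z_rejected(self):
        fit = LinearFit(slope=-0.001, intercept=1.0, fit_range=(1.0, 50.0), r_squared=1.0)
        with pytest.raises(ValueError, match="finite"):
            invert_concentration(fit, np.nan)
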