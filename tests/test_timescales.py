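"""Curve normalization, threshold timescales, and Boltzmann fitting."""

import math

import numpy as np
import pytest

from deadhesion import (
    DeadhesionCurve,
    NormalizationError,
    NotReachedError,
    boltzmann,
    curve_from_trajectory,
    extract_model_timescales,
    fit_boltzmann,
    half_saturation_time,
    integrate_deadhesion,
    normalize_curve,
)

T = np.arange(0.0, 300.5, 1.0)


def logistic_curve(tau1, tau2, times=T, source="model", **kw):
    return DeadhesionCurve(times=times, values=boltzmann(times, tau1, tau2), source=source, **kw)


class TestNormalizeCurve:
    def test_constant_signal_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_curve(T, np.full(T.size, 5.0))

    def test_model_trajectory_round_trip(self, uniform_bonds, linear_prestretch, base_params):
        traj = integrate_deadhesion(base_params, uniform_bonds, linear_prestretch, dt=2e-3, n_grid=201)
        curve = normalize_curve(traj.times, traj.length_series, kind="length", source="model")
        assert curve.values[0] == pytest.approx(0.0, abs=1e-6)
        assert curve.values[-1] == pytest.approx(1.0, abs=1e-6)

    def test_noisy_synthetic_recovers_sigmoid_within_noise(self):
        rng = np.random.default_rng(42)
        sigma = 0.01
        truth = boltzmann(T, 80.0, 30.0)
        raw = 1000.0 * (1.0 - 0.8 * (truth + rng.normal(0, sigma, T.size)))
        curve = normalize_curve(T, raw, kind="area", source="synthetic_experiment")
        # within the noise band of the generating sigmoid (re-anchored at 0)
        expected = (truth - truth[0]) / (np.median(truth[-30:]) - truth[0])
        assert np.max(np.abs(curve.values - expected)) < 6 * sigma

    def test_noise_indistinguishable_net_change_rejected(self):
        rng = np.random.default_rng(0)
        raw = 100.0 + rng.normal(0, 1.0, T.size) - 0.005 * T  # drift ~ noise
        with pytest.raises(NormalizationError):
            normalize_curve(T, raw)


class TestHalfSaturationTime:
    def test_exact_logistic(self):
        curve = logistic_curve(150.0, 5.0)
        assert half_saturation_time(curve) == pytest.approx(150.0, abs=0.3)

    def test_step_data_linear_interpolation(self):
        curve = DeadhesionCurve(
            times=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
            values=np.array([0.0, 0.0, 1.0, 1.0, 1.0]),
        )
        assert half_saturation_time(curve) == pytest.approx(1.5)

    def test_refinement_insensitivity(self):
        dense = logistic_curve(80.0, 30.0, times=np.linspace(0, 300, 3001))
        coarse = logistic_curve(80.0, 30.0, times=np.linspace(0, 300, 61))
        assert abs(
            half_saturation_time(dense) / half_saturation_time(coarse) - 1
        ) < 5e-3

    def test_no_crossing_reports_max(self):
        curve = DeadhesionCurve(times=T, values=np.full(T.size, 0.2))
        with pytest.raises(NotReachedError) as err:
            half_saturation_time(curve)
        assert err.value.max_value == pytest.approx(0.2)

    def test_first_upward_crossing_after_global_min(self):
        # noisy start dips below 0 before the rise; the crossing reported
        # is the one after the minimum
        times = np.arange(0.0, 10.0, 1.0)
        values = np.array([0.6, 0.2, -0.02, 0.1, 0.3, 0.55, 0.8, 0.9, 1.0, 1.0])
        curve = DeadhesionCurve(times=times, values=values, source="experiment")
        assert half_saturation_time(curve) == pytest.approx(4.8)


class TestFitBoltzmann:
    def test_noiseless_recovery_printed_constants(self):
        # the softest-gel condition constants: tau1 80 s, tau2 30 s
        fit = fit_boltzmann(logistic_curve(80.0, 30.0))
        assert fit.converged
        assert fit.tau1 == pytest.approx(80.0, rel=1e-6)
        assert fit.tau2 == pytest.approx(30.0, rel=1e-6)

    def test_step_limit_small_width(self):
        values = np.where(T >= 50.0, 1.0, 0.0)
        curve = DeadhesionCurve(times=T, values=values)
        fit = fit_boltzmann(curve)
        assert abs(fit.tau1 - 50.0) < 1.0
        assert fit.tau2 < 1.0

    def test_monte_carlo_bias_and_stderr(self):
        rng = np.random.default_rng(7)
        tau1s, tau2s, se1s = [], [], []
        truth = boltzmann(T, 80.0, 30.0)
        for _ in range(500):
            noisy = truth + rng.normal(0, 0.02, T.size)
            curve = DeadhesionCurve(times=T, values=np.clip(noisy, -0.04, 1.04), source="experiment")
            fit = fit_boltzmann(curve)
            tau1s.append(fit.tau1)
            tau2s.append(fit.tau2)
            se1s.append(fit.tau1_stderr)
        assert np.mean(tau1s) == pytest.approx(80.0, rel=0.02)
        assert np.mean(tau2s) == pytest.approx(30.0, rel=0.02)
        assert np.std(tau1s) == pytest.approx(np.mean(se1s), rel=0.3)

    def test_idempotent_on_own_fit(self):
        fit = fit_boltzmann(logistic_curve(60.0, 12.0))
        refit = fit_boltzmann(logistic_curve(fit.tau1, fit.tau2))
        assert refit.tau1 == pytest.approx(fit.tau1, rel=1e-10)
        assert refit.tau2 == pytest.approx(fit.tau2, rel=1e-10)

    def test_units_propagate(self):
        sec = logistic_curve(80.0, 30.0, time_unit="s")
        scaled = logistic_curve(80.0 / 60, 30.0 / 60, times=T / 60, time_unit="scaled")
        f_sec, f_scaled = fit_boltzmann(sec), fit_boltzmann(scaled)
        assert f_sec.time_unit == "s"
        assert f_sec.tau1 == pytest.approx(60 * f_scaled.tau1, rel=1e-8)

    def test_sigmoid_crosses_half_at_tau1(self):
        fit = fit_boltzmann(logistic_curve(45.0, 9.0))
        assert boltzmann(np.array([fit.tau1]), fit.tau1, fit.tau2)[0] == 0.5

    def test_free_amplitude_variant(self):
        raw = 0.8 * boltzmann(T, 70.0, 20.0) + 0.1
        curve = DeadhesionCurve(times=T, values=raw, source="experiment")
        fit = fit_boltzmann(curve, free_amplitude=True)
        assert fit.converged
        assert fit.tau1 == pytest.approx(70.0, rel=1e-4)

    def test_too_few_samples_rejected(self):
        curve = DeadhesionCurve(times=T[:6], values=boltzmann(T[:6], 2.0, 0.5))
        with pytest.raises(Exception):
            fit_boltzmann(curve)


class TestExtractModelTimescales:
    def test_consistency_with_fit_on_exact_logistic(self):
        curve = logistic_curve(80.0, 30.0)
        ts = extract_model_timescales(curve)
        fit = fit_boltzmann(curve)
        assert ts.tau1 == pytest.approx(fit.tau1, rel=2e-3)
        assert ts.tau2 == pytest.approx(fit.tau2, rel=2e-3)

    def test_tau2_positive_for_monotone_curves(self):
        curve = logistic_curve(30.0, 8.0)
        assert extract_model_timescales(curve).tau2 > 0

    def test_incomplete_curve_rejected(self):
        curve = DeadhesionCurve(times=T, values=np.minimum(boltzmann(T, 80.0, 30.0), 0.7))
        with pytest.raises(NotReachedError):
            extract_model_timescales(curve)

    @pytest.mark.parametrize("beta,gamma", [(100.0, 1.0), (300.0, 0.5)])
    def test_cross_method_agreement_on_near_sigmoidal_output(
        self, beta, gamma, uniform_bonds, linear_prestretch
    ):
        # model curves are close to a Boltzmann sigmoid at high stiffness
        # ratio (at low stiffness they are exponential-like and the two
        # width definitions measure different things)
        from deadhesion import DimensionlessParams

        p = DimensionlessParams(beta, gamma, 0.1)
        traj = integrate_deadhesion(p, uniform_bonds, linear_prestretch, dt=2e-3, n_grid=201)
        curve = curve_from_trajectory(traj)
        ts = extract_model_timescales(curve)
        fit = fit_boltzmann(curve)
        assert ts.tau1 == pytest.approx(fit.tau1, rel=0.1)
        assert ts.tau2 == pytest.approx(fit.tau2, rel=0.1)


def test_curve_validation():
    with pytest.raises(Exception):
        DeadhesionCurve(times=T[:4], values=np.zeros(4))
    with pytest.raises(Exception):
        DeadhesionCurve(times=T, values=np.full(T.size, 1.2), source="model")
    with pytest.warns(UserWarning):
        DeadhesionCurve(times=T, values=np.full(T.size, 1.2), source="experiment")
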