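"""De-adhesion time integration: bond kinetics, PDE, and edge-ODE limit."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from deadhesion import (
    BondField,
    DimensionlessParams,
    DisplacementProfile,
    PrestretchField,
    decay_bond_density,
    decay_bond_density_force,
    dirac_edge_ode,
    integrate_deadhesion,
)
from deadhesion.timescales import curve_from_trajectory, half_saturation_time

PARAMS = DimensionlessParams(10.0, 1.0, 0.1)


def small_field(density=(1.0, 1.0)):
    return BondField(np.array([-0.5, 0.5]), np.asarray(density, dtype=float))


class TestBondDecay:
    def test_zero_rate_unchanged(self):
        field = small_field((1.0, 2.0))
        out = decay_bond_density(field, 0.0, 5.0)
        assert np.array_equal(out.density, field.density)

    def test_semigroup_property(self):
        field = small_field((1.0, 0.3))
        one_shot = decay_bond_density(field, 0.7, 3.0)
        split = field
        for _ in range(7):
            split = decay_bond_density(split, 0.7, 3.0 / 7)
        assert np.allclose(split.density, one_shot.density, rtol=1e-14)

    def test_matches_richardson_extrapolated_euler(self):
        # explicit Euler of drho/dt = -k rho at steps h and h/2,
        # Richardson-combined, converges to the exact exponential
        k, T = 1.3, 1.0
        exact = decay_bond_density(small_field(), k, T).density[0]
        def euler(h):
            return (1.0 - k * h) ** round(T / h)
        richardson = 2.0 * euler(T / 20000) - euler(T / 10000)
        assert abs(exact - richardson) < 1e-8

    def test_negative_rate_rejected(self):
        with pytest.raises(Exception):
            decay_bond_density(small_field(), -1.0, 1.0)


class TestForceDependentDecay:
    def _profile(self, u):
        x = np.array([-0.5, 0.5])
        disp = np.asarray(u, dtype=float)
        return DisplacementProfile(x, disp, np.zeros(2), PARAMS.stiffness_ratio * disp)

    def test_zero_coupling_reduces_to_plain_decay(self):
        field = small_field((1.0, 0.5))
        prof = self._profile((-0.3, 0.3))
        p0 = DimensionlessParams(10.0, 1.0, 0.1, 0.0)
        out = decay_bond_density_force(field, prof, p0, 0.2)
        ref = decay_bond_density(field, 1.0, 0.2)
        assert np.array_equal(out.density, ref.density)

    def test_zero_force_reduces_to_plain_decay(self):
        field = small_field((1.0, 0.5))
        prof = self._profile((0.0, 0.0))
        p = DimensionlessParams(10.0, 1.0, 0.1, 500.0)
        out = decay_bond_density_force(field, prof, p, 0.2)
        ref = decay_bond_density(field, 1.0, 0.2)
        assert np.allclose(out.density, ref.density, rtol=1e-15)

    def test_frozen_force_closed_form(self):
        # constant per-bond force F over [0, T]:
        # density = initial * exp(-k * e^{alpha F} * T)
        p = DimensionlessParams(10.0, 0.8, 0.1, 3.0)
        u_edge = 0.05
        field = small_field((2.0, 2.0))
        prof = self._profile((-u_edge, u_edge))
        T = 0.4
        out = field
        for _ in range(10):
            out = decay_bond_density_force(out, prof, p, T / 10)
        force = p.stiffness_ratio * u_edge
        expected = 2.0 * math.exp(-0.8 * math.exp(3.0 * force) * T)
        assert out.density[0] == pytest.approx(expected, rel=1e-8)

    def test_decay_never_slower_than_force_independent(self):
        field = small_field((1.0, 1.0))
        prof = self._profile((-0.2, 0.2))
        p = DimensionlessParams(10.0, 1.0, 0.1, 10.0)
        fast = decay_bond_density_force(field, prof, p, 0.1)
        slow = decay_bond_density(field, 1.0, 0.1)
        assert np.all(fast.density <= slow.density + 1e-15)

    def test_clamped_exponent_warns(self):
        field = small_field((1.0, 1.0))
        prof = self._profile((-0.5, 0.5))
        p = DimensionlessParams(100.0, 1.0, 0.1, 1e4)
        with pytest.warns(UserWarning, match="clamped"):
            decay_bond_density_force(field, prof, p, 1e-3)


class TestIntegrateDeadhesion:
    def test_no_breakage_is_static(self, uniform_bonds, linear_prestretch):
        p = DimensionlessParams(10.0, 0.0, 0.1)
        traj = integrate_deadhesion(p, uniform_bonds, linear_prestretch, t_end=0.5, dt=1e-2, n_grid=101)
        assert np.allclose(traj.normalized_length, 0.0, atol=1e-10)
        assert np.allclose(traj.bond_densities[-1], traj.bond_densities[0])

    def test_long_format_export(self, uniform_bonds, linear_prestretch, base_params):
        traj = integrate_deadhesion(base_params, uniform_bonds, linear_prestretch, dt=5e-3, n_grid=51)
        frame = traj.to_frame()
        assert list(frame.columns) == ["time", "x_scaled", "displacement", "bond_density"]
        assert len(frame) == traj.times.size * traj.grid.size

    def test_trajectory_invariants(self, uniform_bonds, linear_prestretch, base_params):
        traj = integrate_deadhesion(base_params, uniform_bonds, linear_prestretch, dt=2e-3, n_grid=201)
        # irreversible breakage
        assert np.all(np.diff(traj.bond_densities, axis=0) <= 1e-15)
        # monotone retraction
        assert np.all(np.diff(traj.length_series) <= 1e-9)
        # completes: bonds exhausted, length at the rest length
        assert traj.termination == "completed"
        span = traj.prestretch_span
        assert traj.length_series[-1] == pytest.approx(1.0 - span, abs=2e-3 * span)
        assert traj.normalized_length[0] == pytest.approx(0.0, abs=1e-12)
        assert traj.normalized_length[-1] >= 0.999

    def test_large_rate_single_exponential_relaxation(self, uniform_bonds, linear_prestretch):
        # bonds gone at t = 0+: the profile loses its sigmoidal shape and
        # follows free Kelvin-Voigt relaxation with the internal time
        eta = 0.1
        p = DimensionlessParams(10.0, 1000.0, eta)
        traj = integrate_deadhesion(p, uniform_bonds, linear_prestretch, dt=1e-4, n_grid=201)
        c = curve_from_trajectory(traj)
        t_half = half_saturation_time(c)
        assert t_half == pytest.approx(eta * math.log(2.0), rel=0.05)
        mask = c.times >= t_half
        ref = 1.0 - (1.0 - np.interp(t_half, c.times, c.values)) * np.exp(
            -(c.times[mask] - t_half) / eta
        )
        assert np.max(np.abs(c.values[mask] - ref)) <= 0.02

    def test_self_convergence(self, uniform_bonds, linear_prestretch, base_params):
        coarse = integrate_deadhesion(base_params, uniform_bonds, linear_prestretch, dt=2e-3, n_grid=501)
        fine = integrate_deadhesion(base_params, uniform_bonds, linear_prestretch, dt=1e-3, n_grid=1001)
        th = [
            half_saturation_time(curve_from_trajectory(t)) for t in (coarse, fine)
        ]
        assert abs(th[1] / th[0] - 1) < 5e-3

    def test_contractility_invariance_linear_model(self, uniform_bonds, linear_prestretch, base_params):
        curves = []
        for factor in (0.5, 1.0, 2.0):
            traj = integrate_deadhesion(
                base_params, uniform_bonds, linear_prestretch.scaled(factor), dt=2e-3, n_grid=201
            )
            curves.append((traj.times, traj.normalized_length))
        t = np.linspace(0, min(c[0][-1] for c in curves), 300)
        interped = [np.interp(t, *c) for c in curves]
        for other in interped[1:]:
            assert np.max(np.abs(other - interped[0])) <= 1e-8

    def test_contractility_separates_with_force_coupling(self, uniform_bonds):
        p = DimensionlessParams(1.0, 1.0, 0.1, 100.0)
        t_halves = []
        for edge in (0.005, 0.01, 0.02):
            traj = integrate_deadhesion(
                p, uniform_bonds, PrestretchField.linear(edge), dt=2e-3, n_grid=201, force_dependent=True
            )
            t_halves.append(half_saturation_time(curve_from_trajectory(traj)))
        assert t_halves[0] > t_halves[1] > t_halves[2]


class TestDiracEdgeOde:
    def test_no_breakage_static(self):
        p = DimensionlessParams(10.0, 0.0, 0.1)
        curve = dirac_edge_ode(p, 0.5, 0.01, t_end=1.0)
        assert np.allclose(curve.values, 0.0, atol=1e-9)

    def test_matches_integrating_factor_solution(self):
        # linear scalar ODE: exact solution by integrating factor,
        # evaluated with adaptive quadrature
        beta, gamma, eta, n0, s = 10.0, 1.0, 0.1, 0.5, 0.02
        p = DimensionlessParams(beta, gamma, eta)
        curve = dirac_edge_ode(p, n0, s / 2, t_end=4.0, n_samples=41)

        def P(t):
            # int_0^t (2 + beta n0 e^{-g u}) / (2 eta) du
            return (2 * t + beta * n0 * (1 - math.exp(-gamma * t)) / gamma) / (2 * eta)

        a0 = -s / (2 + beta * n0)
        a_inf = -s / 2

        def a_exact(t):
            integral, _ = quad(lambda u: math.exp(P(u) - P(t)), 0.0, t, limit=400,
                               epsabs=1e-14, epsrel=1e-12)
            return a0 * math.exp(-P(t)) - s / (2 * eta) * integral

        idx = [5, 10, 20, 40]
        for i in idx:
            t = curve.times[i]
            expected = (a_exact(t) - a0) / (a_inf - a0)
            assert curve.values[i] == pytest.approx(expected, abs=1e-8)

    def test_right_bound_on_uniform_pde(self, uniform_bonds, linear_prestretch, base_params):
        ode_curve = dirac_edge_ode(base_params, 0.5, 0.01)
        traj = integrate_deadhesion(base_params, uniform_bonds, linear_prestretch, dt=2e-3, n_grid=201)
        t_ode = half_saturation_time(ode_curve)
        t_pde = half_saturation_time(curve_from_trajectory(traj))
        assert t_ode >= t_pde
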