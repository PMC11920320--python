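"""Point-source diffusion: density solution, detectable radius, D estimator."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from osteokinetics import (
    DetectionThreshold,
    PointSourceModel,
    RadiusSeries,
    detectable_radius_squared,
    estimate_diffusion,
    fit_radius_linear,
    point_source_density,
    volume_to_radius,
)
from osteokinetics.errors import InputError, NotYetDetectableError


class TestVolumeToRadius:
    def test_unit_sphere(self):
        assert volume_to_radius(4.0 * np.pi / 3.0) == pytest.approx(1.0)

    def test_zero(self):
        assert volume_to_radius(0.0) == 0.0

    def test_against_bisection_oracle(self):
        oracle = brentq(lambda r: 4.0 / 3.0 * np.pi * r**3 - 500.0, 0.0, 100.0)
        assert oracle == pytest.approx(4.924, abs=1e-3)
        assert volume_to_radius(500.0) == pytest.approx(oracle, rel=1e-12)

    def test_negative_volume_rejected(self):
        with pytest.raises(InputError):
            volume_to_radius(-1.0)


def crank_nicolson_oracle(model, r_eval, t0, t_end, r_max=5.0, nr=1000, nt=2000):
    """Independent PDE oracle: integrate u_t = D*(u_rr + 2/r*u_r) + rho*u by
    Crank-Nicolson on w = r*u (which obeys w_t = D*w_rr + rho*w), starting
    from the narrow Gaussian profile at t0."""
    r = np.linspace(0.0, r_max, nr + 1)
    dr = r[1] - r[0]
    dt = (t_end - t0) / nt
    w = r * point_source_density(model, r, t0)
    lam = model.D * dt / (2.0 * dr**2)
    mu = model.rho * dt / 2.0
    n_int = nr - 1  # interior nodes; w = 0 at both boundaries
    # (I - dt/2 A) w+ = (I + dt/2 A) w-,  A = D d_rr + rho
    ab = np.zeros((3, n_int))
    ab[0, 1:] = -lam
    ab[1, :] = 1.0 + 2.0 * lam - mu
    ab[2, :-1] = -lam
    for _ in range(nt):
        wi = w[1:-1]
        rhs = (1.0 - 2.0 * lam + mu) * wi
        rhs[1:] += lam * wi[:-1]
        rhs[:-1] += lam * wi[1:]
        w[1:-1] = solve_banded((1, 1), ab, rhs)
    return np.interp(r_eval, r, np.where(r > 0, w / np.maximum(r, dr), 0.0))


class TestPointSourceDensity:
    model = PointSourceModel(D=0.01, rho=1.5, C0=1e6)

    @pytest.mark.parametrize("t", [1.0, 5.0, 20.0])
    def test_total_mass_grows_exponentially(self, t):
        total, _ = quad(
            lambda r: 4.0 * np.pi * r**2 * point_source_density(self.model, r, t),
            0.0,
            np.inf,
        )
        assert total == pytest.approx(self.model.C0 * np.exp(self.model.rho * t), rel=1e-6)

    def test_monotone_decreasing_in_radius(self):
        r = np.linspace(0.0, 5.0, 200)
        u = point_source_density(self.model, r, 3.0)
        assert np.all(np.diff(u) < 0)

    def test_dirac_initial_condition_excludes_t_zero(self):
        with pytest.raises(InputError):
            point_source_density(self.model, 1.0, 0.0)

    def test_matches_crank_nicolson_pde_oracle(self):
        exact = point_source_density(self.model, 2.0, 10.0)
        numeric = crank_nicolson_oracle(self.model, 2.0, t0=0.5, t_end=10.0)
        assert numeric == pytest.approx(exact, rel=0.01)

    def test_solves_pde_by_finite_differences(self):
        # residual u_t - D*(u_rr + 2/r u_r) - rho*u small relative to max u
        r = np.linspace(0.05, 3.0, 300)
        t = np.linspace(1.0, 5.0, 400)
        u = np.array([point_source_density(self.model, r, ti) for ti in t])
        u_t = np.gradient(u, t, axis=0, edge_order=2)
        u_r = np.gradient(u, r, axis=1, edge_order=2)
        u_rr = np.gradient(u_r, r, axis=1, edge_order=2)
        lap = u_rr + 2.0 / r * u_r
        residual = u_t - self.model.D * lap - self.model.rho * u
        core = (slice(2, -2), slice(2, -2))
        assert np.abs(residual[core]).max() < 1e-3 * np.abs(u).max()


class TestDetectableRadius:
    model = PointSourceModel(D=0.01, rho=1.5, C0=1.0)
    threshold = DetectionThreshold(ratio=1e-3)

    def test_round_trip_returns_threshold_density(self):
        for t in (5.0, 20.0, 50.0):
            r_star = np.sqrt(detectable_radius_squared(self.model, self.threshold, t))
            u = point_source_density(self.model, r_star, t)
            assert u == pytest.approx(self.threshold.ratio * self.model.C0, rel=1e-10)

    def test_derived_value(self):
        # cross-checked by root-finding on the density profile
        r2 = detectable_radius_squared(self.model, self.threshold, 20.0)
        assert r2 == pytest.approx(28.42, abs=0.01)
        u_star = self.threshold.ratio * self.model.C0
        root = brentq(
            lambda r: point_source_density(self.model, r, 20.0) - u_star, 1e-6, 50.0
        )
        assert np.sqrt(r2) == pytest.approx(root, rel=1e-10)

    def test_asymptotic_ratio_tends_to_one(self):
        # r*^2/(4 D rho t^2) = 1 - ln(8 u*/C0 (pi D t)^1.5)/(rho t): the
        # deviation is exactly the log-term ratio, which is o(1) in t
        ts = np.array([10.0, 100.0, 1000.0, 10000.0])
        for t in ts:
            ratio = detectable_radius_squared(self.model, self.threshold, t) / (
                4.0 * self.model.D * self.model.rho * t**2
            )
            log_term = np.log(
                8.0 * self.threshold.ratio * (np.pi * self.model.D * t) ** 1.5
            ) / (self.model.rho * t)
            assert ratio - 1.0 == pytest.approx(-log_term, rel=1e-9)
        final = detectable_radius_squared(self.model, self.threshold, ts[-1]) / (
            4.0 * self.model.D * self.model.rho * ts[-1] ** 2
        )
        assert final == pytest.approx(1.0, abs=1e-3)

    def test_not_yet_detectable_error_names_time(self):
        slow = PointSourceModel(D=1.0, rho=0.01, C0=1.0)
        nearly = DetectionThreshold(ratio=0.99)
        with pytest.raises(NotYetDetectableError) as err:
            detectable_radius_squared(slow, nearly, 1.0)
        assert err.value.time == 1.0


class TestEstimateDiffusion:
    def test_exactly_linear_radii_recover_constant_d(self):
        # HOS-scale values: linear front r = 2*sqrt(D*rho)*t
        d_true, rho = 1.19e-2, 1.5
        t = np.linspace(11, 28, 8)
        series = RadiusSeries("HOS", t, 2.0 * np.sqrt(d_true * rho) * t)
        summary = estimate_diffusion(series, rho)
        np.testing.assert_allclose(summary.per_timepoint_D, d_true, rtol=1e-12)
        assert summary.D_bar == pytest.approx(d_true, rel=1e-12)
        assert summary.sd == pytest.approx(0.0, abs=1e-15)
        assert summary.cv == pytest.approx(0.0, abs=1e-12)
        assert summary.valid
        assert summary.tier == "High"

    def test_estimator_error_matches_log_term_ratio(self):
        model = PointSourceModel(D=0.01, rho=1.5, C0=1.0)
        threshold = DetectionThreshold(ratio=1e-3)
        t = np.arange(10.0, 61.0, 10.0)
        radii = np.sqrt([detectable_radius_squared(model, threshold, ti) for ti in t])
        summary = estimate_diffusion(RadiusSeries("x", t, radii), model.rho)
        rel_err = np.abs(summary.per_timepoint_D - model.D) / model.D
        closed_form = (
            np.abs(np.log(8.0 * threshold.ratio * (np.pi * model.D * t) ** 1.5))
            / (model.rho * t)
        )
        np.testing.assert_allclose(rel_err, closed_form, rtol=0.01)
        assert np.all(np.diff(rel_err) < 0)  # consistency: error decays in t

    def test_summary_arithmetic_matches_numpy(self, rng):
        t = np.linspace(5, 50, 10)
        r = 0.5 * t * (1 + 0.1 * rng.standard_normal(10))
        summary = estimate_diffusion(RadiusSeries("x", t, np.abs(r)), 1.2)
        d = np.abs(r) ** 2 / (4 * 1.2 * t**2)
        assert summary.D_bar == pytest.approx(d.mean())
        assert summary.sd == pytest.approx(d.std(ddof=1))
        assert summary.cv == pytest.approx(d.std(ddof=1) / d.mean())

    def test_time_zero_rejected(self):
        with pytest.raises(InputError):
            RadiusSeries("x", np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def test_single_point_rejected(self):
        with pytest.raises(InputError):
            estimate_diffusion(RadiusSeries("x", np.array([1.0]), np.array([1.0])), 1.0)


class TestRadiusLinearFit:
    def test_perfect_line(self):
        series = RadiusSeries("x", np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]))
        slope, intercept, r2 = fit_radius_linear(series)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_asymptotic_radii_give_front_speed(self):
        d_true, rho = 5e-3, 1.8
        t = np.linspace(5, 40, 8)
        series = RadiusSeries("x", t, 2.0 * np.sqrt(d_true * rho) * t)
        slope, _, _ = fit_radius_linear(series)
        assert slope == pytest.approx(2.0 * np.sqrt(d_true * rho), rel=1e-12)
        assert slope**2 / (4.0 * rho) == pytest.approx(d_true, rel=1e-12)

    def test_slope_implied_d_in_asymptotic_regime(self):
        # rho*t >= 60 over the window: slope^2/(4 rho) within 10% of D
        model = PointSourceModel(D=0.01, rho=1.5, C0=1.0)
        threshold = DetectionThreshold(ratio=1e-3)
        t = np.linspace(40.0, 80.0, 9)
        radii = np.sqrt([detectable_radius_squared(model, threshold, ti) for ti in t])
        slope, _, _ = fit_radius_linear(RadiusSeries("x", t, radii))
        assert slope**2 / (4.0 * model.rho) == pytest.approx(model.D, rel=0.10)
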