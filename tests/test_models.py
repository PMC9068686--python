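"""Model registry and closed-form Ornstein–Uhlenbeck oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import solve_continuous_lyapunov

import stochphase as sp
from stochphase.models import NoLimitCycleError

from conftest import random_admissible_oup

A_PRINTED = np.array([[0.1598, -0.52], [0.7227, -0.319]])
B_PRINTED = math.sqrt(2 * 0.01125) * np.diag([1.0, 0.5])


def lyapunov_covariance(p):
    """Independent stationary covariance: solve A C + C A^T + 2G = 0."""
    return solve_continuous_lyapunov(p.A, -2 * p.G)


def flux_period(p):
    """Independent mean period: numerically integrate the stationary
    Gaussian current component across a ray from the origin."""
    C = lyapunov_covariance(p)
    Ci = np.linalg.inv(C)
    M = p.A + p.G @ Ci
    norm = 1.0 / (2 * math.pi * math.sqrt(np.linalg.det(C)))

    def jy(x):
        rho = norm * math.exp(-0.5 * Ci[0, 0] * x * x)
        return (M[1, 0] * x) * rho

    hi = 20 * math.sqrt(abs(C[0, 0]))
    val, _ = quad(jy, 0, hi, limit=200)
    return 1.0 / abs(val)


class TestRegistry:
    def test_zero_noise_spiral_has_zero_diffusion(self):
        m = sp.make_model("spiral_sink", eps=0.0)
        assert np.allclose(m.diffusion_matrix(0.3, -0.2), 0.0)

    def test_heteroclinic_drift_vanishes_at_origin(self):
        m = sp.make_model("heteroclinic")
        assert np.allclose(m.drift_at(0.0, 0.0), 0.0)
        assert m.boundary_flavor == "reflecting_adjoint"

    def test_wilson_cowan_sigmoid_midpoint(self):
        # at threshold input the logistic activation is exactly 1/2,
        # so  dE/dt = -E + 1/2  at that point
        m = sp.make_model("wilson_cowan")
        p = m.params
        # choose E with c1*E - c2*I + P = theta_e, picking I = 0
        E = (p["theta_e"] - p["P"]) / p["c1"]
        fx, _ = m.drift(E, 0.0)
        assert fx == pytest.approx(-E + 0.5, abs=1e-12)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            sp.make_model("lorenz")

    def test_non_psd_diffusion_rejected(self):
        with pytest.raises(ValueError):
            sp.CanonicalOUP(mu=-0.1, omega=1.0, eps=0.01, beta_d=0.9, beta_c=0.9)

    def test_malformed_domain_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            sp.make_model("van_der_pol", domain=(1.0, -1.0, 0.0, 1.0))


class TestCanonicalize:
    def test_printed_matrix_gives_printed_mu_omega(self):
        p = sp.oup_canonicalize(A_PRINTED, B_PRINTED)
        assert p.mu == pytest.approx(-0.0796, abs=5e-5)
        assert p.omega == pytest.approx(0.564, abs=5e-4)

    def test_canonical_isotropic_input_is_fixed_point(self):
        A = np.array([[-0.3, -1.1], [1.1, -0.3]])
        p = sp.oup_canonicalize(A, 0.2 * np.eye(2))
        assert np.allclose(p.transform, np.eye(2))
        assert p.beta_d == pytest.approx(0.0, abs=1e-12)
        assert p.beta_c == pytest.approx(0.0, abs=1e-12)
        assert p.eps == pytest.approx(0.02, abs=1e-12)

    def test_transform_conjugates_to_canonical_form(self):
        p = sp.oup_canonicalize(A_PRINTED, B_PRINTED)
        S = p.transform
        assert np.allclose(np.linalg.inv(S) @ A_PRINTED @ S,
                           [[p.mu, -p.omega], [p.omega, p.mu]], atol=1e-12)

    def test_anisotropy_invariant_under_normalization(self):
        # rescaling/rotating the eigenvector changes (eps, bD, bc) but not
        # mu, omega, bD^2 + bc^2, nor the mean period
        rng = np.random.default_rng(42)
        p0 = sp.oup_canonicalize(A_PRINTED, B_PRINTED)
        b2 = p0.beta_c ** 2 + p0.beta_d ** 2
        for _ in range(5):
            c, phi = rng.uniform(0.2, 3.0), rng.uniform(0, 2 * np.pi)
            R = c * np.array([[np.cos(phi), -np.sin(phi)],
                              [np.sin(phi), np.cos(phi)]])
            S2 = p0.transform @ R
            A2 = np.linalg.inv(S2) @ A_PRINTED @ S2
            B2 = np.linalg.inv(S2) @ B_PRINTED
            q = sp.oup_canonicalize(A2, B2)
            assert q.mu == pytest.approx(p0.mu, rel=1e-9)
            assert q.omega == pytest.approx(p0.omega, rel=1e-9)
            assert q.beta_c ** 2 + q.beta_d ** 2 == pytest.approx(b2, rel=1e-8)
            assert sp.oup_mean_period(q) == pytest.approx(
                sp.oup_mean_period(p0), rel=1e-9)

    def test_real_eigenvalues_rejected(self):
        with pytest.raises(ValueError, match="real"):
            sp.oup_canonicalize(np.diag([-1.0, -2.0]), np.eye(2))


class TestMeanPeriod:
    def test_isotropic_collapses_to_2pi_over_omega(self):
        p = sp.CanonicalOUP(mu=-0.3, omega=0.9, eps=0.01)
        assert sp.oup_mean_period(p) == pytest.approx(2 * math.pi / 0.9, rel=1e-14)

    def test_small_damping_limit(self):
        p = sp.CanonicalOUP(mu=-1e-8, omega=0.7, eps=0.01, beta_d=0.5)
        assert sp.oup_mean_period(p) == pytest.approx(2 * math.pi / 0.7, rel=1e-8)

    def test_matches_flux_integral_oracle(self, oup_params):
        # the independent oracle: Lyapunov covariance + numerical flux
        # integral of the stationary Gaussian current
        assert sp.oup_mean_period(oup_params) == pytest.approx(
            flux_period(oup_params), rel=1e-8)

    def test_closed_form_equals_oracle_on_random_parameters(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = random_admissible_oup(rng)
            assert sp.oup_mean_period(p) == pytest.approx(flux_period(p),
                                                          rel=1e-6)


class TestStationaryCovariance:
    def test_isotropic_is_scaled_identity(self):
        p = sp.CanonicalOUP(mu=-0.4, omega=1.0, eps=0.02)
        Pi, Pi_inv, det = sp.oup_stationary_covariance(p)
        assert np.allclose(Pi, np.eye(2) / 0.4)

    def test_det_closed_form_consistent(self, oup_params):
        Pi, _, det = sp.oup_stationary_covariance(oup_params)
        assert np.linalg.det(Pi) == pytest.approx(det, rel=1e-12)

    def test_solves_lyapunov_equation(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = random_admissible_oup(rng)
            Pi, _, _ = sp.oup_stationary_covariance(p)
            C = lyapunov_covariance(p)
            assert np.allclose(p.eps * Pi, C, rtol=1e-10, atol=1e-14)

    def test_unstable_rejected(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = sp.CanonicalOUP(mu=0.1, omega=1.0, eps=0.01)
        with pytest.raises(ValueError):
            sp.oup_stationary_covariance(p)


class TestOmegaTermOracle:
    def test_isotropic_vanishes(self):
        p = sp.CanonicalOUP(mu=-0.3, omega=1.0, eps=0.02)
        assert sp.oup_omega_term(np.array([0.4, -0.7]), p) == 0.0

    def test_scaling_homogeneity(self, oup_params):
        x = np.array([0.5, 0.3])
        for c in (0.5, 2.0, -3.0):
            assert sp.oup_omega_term(c * x, oup_params) == pytest.approx(
                sp.oup_omega_term(x, oup_params) / c ** 2, rel=1e-12)

    def test_matches_generic_definition(self, oup_params):
        # Omega = 2 sum G_ij d_i ln(u) d_j psi with u = r, psi = atan2(y, x)
        p = oup_params
        G = p.G
        h = 1e-6
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0.3, 1.0, 2)
            lnu = lambda z: 0.5 * math.log(z[0] ** 2 + z[1] ** 2)
            psi = lambda z: math.atan2(z[1], z[0])
            d = lambda f, i: (f(x + h * np.eye(2)[i]) - f(x - h * np.eye(2)[i])) / (2 * h)
            om = 2 * sum(G[i, j] * d(lnu, i) * d(psi, j)
                         for i in range(2) for j in range(2))
            assert sp.oup_omega_term(x, p) == pytest.approx(om, rel=1e-5)

    def test_origin_rejected(self, oup_params):
        with pytest.raises(ValueError):
            sp.oup_omega_term(np.zeros(2), oup_params)


class TestDeltaPsiOracle:
    def test_isotropic_vanishes(self):
        p = sp.CanonicalOUP(mu=-0.3, omega=1.0, eps=0.02)
        assert sp.oup_delta_psi(np.array([0.4, 0.1]), p) == 0.0

    def test_point_reflection_symmetry(self, oup_params):
        x = np.array([0.37, -0.21])
        assert sp.oup_delta_psi(x, oup_params) == pytest.approx(
            sp.oup_delta_psi(-x, oup_params), rel=1e-14)

    @staticmethod
    def _drag_residual(p, pts, h=1e-5):
        """max |L+[dpsi] - Omega| over pts, by central differences on the
        closed forms (the eps-quadratic part of the full balance)."""
        worst = 0.0
        for x in pts:
            e = np.eye(2)
            f = lambda z: float(sp.oup_delta_psi(z, p))
            grad = np.array([(f(x + h * e[i]) - f(x - h * e[i])) / (2 * h)
                             for i in range(2)])
            hess = np.empty((2, 2))
            for i in range(2):
                for j in range(2):
                    hess[i, j] = (f(x + h * e[i] + h * e[j]) - f(x + h * e[i] - h * e[j])
                                  - f(x - h * e[i] + h * e[j]) + f(x - h * e[i] - h * e[j])) / (4 * h * h)
            drift = p.A @ x
            lhs = drift @ grad + np.sum(p.G * hess)
            worst = max(worst, abs(lhs - float(sp.oup_omega_term(x, p))))
        return worst

    def test_residual_quarters_when_eps_halves(self, oup_params):
        # the closed form solves the drag balance with an O(eps^2) error
        from dataclasses import replace
        rng = np.random.default_rng(5)
        ang = rng.uniform(0, 2 * np.pi, 8)
        rad = rng.uniform(0.25, 1.2, 8)
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        p1 = oup_params
        p2 = replace(p1, eps=p1.eps / 2, transform=p1.transform)
        r1 = self._drag_residual(p1, pts)
        r2 = self._drag_residual(p2, pts)
        assert r1 > 0
        assert r2 == pytest.approx(r1 / 4, rel=0.05)


class TestDeterministicPeriod:
    def test_wilson_cowan_period(self, printed=5.26):
        T = sp.deterministic_period(sp.make_model("wilson_cowan"))
        assert T == pytest.approx(printed, rel=5e-3)

    def test_van_der_pol_period(self, printed=6.663):
        T = sp.deterministic_period(sp.make_model("van_der_pol"))
        assert T == pytest.approx(printed, rel=5e-3)

    def test_spiral_sink_has_no_cycle(self):
        with pytest.raises(NoLimitCycleError):
            sp.deterministic_period(sp.make_model("spiral_sink"),
                                    seed_point=(0.5, 0.5))
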