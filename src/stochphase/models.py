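"""Planar Langevin models and closed-form Ornstein–Uhlenbeck results.

A stochastic oscillator is specified as the Itô SDE

    dX/dt = f(X) + g(X) xi(t),      X in R^2,

with ``f`` the drift field, ``g`` the noise matrix and ``xi`` white noise.
The diffusion matrix entering the Kolmogorov operators is G = (1/2) g g^T.
This module holds the packaged example systems — a linear spiral sink
(two-dimensional Ornstein–Uhlenbeck process), noisy Wilson–Cowan and
Van der Pol oscillators, and a noisy heteroclinic oscillator — together
with every closed-form quantity known for the linear case: the canonical
form (mu, omega, eps, beta_D, beta_c), the stationary Gaussian covariance,
the mean-return-time period, and the analytic phase-difference field that
seeds the numerical solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels

__all__ = [
    "LangevinModel",
    "CanonicalOUP",
    "make_model",
    "linear_model",
    "oup_canonicalize",
    "oup_model",
    "oup_mean_period",
    "oup_stationary_covariance",
    "oup_stationary_density",
    "oup_stationary_current",
    "oup_omega_term",
    "oup_delta_psi",
    "deterministic_period",
    "NoLimitCycleError",
    "MODEL_NAMES",
]

MODEL_NAMES = ("spiral_sink", "wilson_cowan", "van_der_pol", "heteroclinic", "custom")

#: per-model grid defaults: (x-, x+, y-, y+), N, M
DEFAULT_DOMAINS = {
    "spiral_sink": (-1.5, 1.5, -1.5, 1.5),
    "wilson_cowan": (-0.3, 1.0, -0.1, 0.9),
    "van_der_pol": (-2.5, 2.5, -2.5, 2.5),
    "heteroclinic": (-math.pi / 2, math.pi / 2, -math.pi / 2, math.pi / 2),
}
DEFAULT_RESOLUTION = (120, 120)


class NoLimitCycleError(RuntimeError):
    """The noiseless flow converges to an equilibrium instead of a cycle."""


@dataclass
class LangevinModel:
    """A planar Langevin system dX/dt = f(X) + g(X) xi(t).

    Attributes
    ----------
    drift : callable
        Vectorized vector field: ``drift(X, Y) -> (FX, FY)`` for arrays of
        equal shape.
    diffusion : callable
        ``diffusion(X, Y) -> (G11, G12, G22)``, the symmetric diffusion
        matrix G = (1/2) g g^T evaluated pointwise (broadcast for constant G).
    domain : tuple
        Rectangle (x-, x+, y-, y+) the operators are discretized on.
    boundary_flavor : str
        ``"one_sided"`` (inward one-sided stencils at the border, for
        unbounded systems truncated to a large box) or
        ``"reflecting_adjoint"`` (adjoint of the conservative reflecting
        forward closure, for genuinely bounded systems).
    g_const : ndarray or None
        The constant 2x2 noise matrix, if the noise is additive.
    drift_kernel, kernel_params
        Scalar numba kernel + parameter vector for the Monte-Carlo
        integrators; ``None`` for custom models (a slower numpy fallback
        is used then).
    """

    name: str
    drift: Callable
    diffusion: Callable
    domain: tuple
    boundary_flavor: str = "one_sided"
    params: Mapping = field(default_factory=dict)
    noise: Callable | None = None
    g_const: np.ndarray | None = None
    drift_kernel: Callable | None = None
    kernel_params: np.ndarray | None = None
    canonical_oup: "CanonicalOUP | None" = None
    limit_cycle_seed: tuple | None = None

    def __post_init__(self):
        if self.boundary_flavor not in ("one_sided", "reflecting_adjoint"):
            raise ValueError(f"unknown boundary flavor {self.boundary_flavor!r}")
        x_lo, x_hi, y_lo, y_hi = self.domain
        if not (x_lo < x_hi and y_lo < y_hi):
            raise ValueError(f"malformed domain {self.domain!r}")
        self._check_psd()

    def _check_psd(self):
        """Diffusion must be symmetric PSD wherever we evaluate it."""
        x_lo, x_hi, y_lo, y_hi = self.domain
        xs = np.linspace(x_lo, x_hi, 7)
        ys = np.linspace(y_lo, y_hi, 7)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        g11, g12, g22 = (np.broadcast_to(np.asarray(v, float), X.shape)
                         for v in self.diffusion(X, Y))
        tol = 1e-12 * (1.0 + np.max(np.abs(g11)) + np.max(np.abs(g22)))
        if np.any(g11 < -tol) or np.any(g22 < -tol) or \
                np.any(g11 * g22 - g12 ** 2 < -tol):
            raise ValueError("diffusion matrix is not positive semidefinite")

    def diffusion_matrix(self, x, y):
        g11, g12, g22 = self.diffusion(np.asarray(x, float), np.asarray(y, float))
        return np.array([[g11, g12], [g12, g22]], dtype=float)

    def drift_at(self, x, y):
        fx, fy = self.drift(np.asarray(x, float), np.asarray(y, float))
        return np.array([fx, fy], dtype=float)


# ---------------------------------------------------------------------------
# canonical Ornstein–Uhlenbeck process
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalOUP:
    """Linear spiral sink in canonical coordinates.

    dX/dt = A X + B xi with A = [[mu, -omega], [omega, mu]] and diffusion
    G = eps * [[1 + beta_d, beta_c], [beta_c, 1 - beta_d]].  ``transform``
    is the change-of-variables matrix S with S^-1 A_orig S = A when the
    model was canonicalized from general coordinates (identity otherwise).
    """

    mu: float
    omega: float
    eps: float
    beta_d: float = 0.0
    beta_c: float = 0.0
    transform: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")
        if self.mu >= 0:
            warnings.warn("mu >= 0: no stationary density exists", stacklevel=3)
        if self.beta_c ** 2 + self.beta_d ** 2 > 1 + 1e-12:
            raise ValueError("beta_c^2 + beta_d^2 > 1: diffusion not PSD")

    @property
    def A(self) -> np.ndarray:
        return np.array([[self.mu, -self.omega], [self.omega, self.mu]])

    @property
    def G(self) -> np.ndarray:
        return self.eps * np.array([[1 + self.beta_d, self.beta_c],
                                    [self.beta_c, 1 - self.beta_d]])


def oup_canonicalize(A, B) -> CanonicalOUP:
    """Bring a linear SDE dX = A X dt + B dW to canonical spiral form.

    The eigenvalues of ``A`` must be a complex-conjugate pair mu +/- i omega.
    The transform uses the eigenvector for mu + i*omega scaled to first
    component 1; mu, omega and beta_c^2 + beta_d^2 are invariant under any
    admissible normalization, the individual (eps, beta_d, beta_c) are not.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    mu = 0.5 * np.trace(A)
    disc = np.linalg.det(A) - mu ** 2
    if disc <= 0:
        raise ValueError("eigenvalues of A are real: not a spiral")
    omega = math.sqrt(disc)
    if mu >= 0:
        warnings.warn("A is not stable (mu >= 0)", stacklevel=2)
    lam = mu + 1j * omega
    # eigenvector with first component 1 (fall back to the second row if A12 = 0)
    if abs(A[0, 1]) > 1e-300:
        v = np.array([1.0, (lam - A[0, 0]) / A[0, 1]])
    else:
        v = np.array([1.0, A[1, 0] / (lam - A[1, 1])])
    S = np.column_stack([v.real, -v.imag])
    Si = np.linalg.inv(S)
    G = 0.5 * B @ B.T
    Gc = Si @ G @ Si.T
    eps = 0.5 * (Gc[0, 0] + Gc[1, 1])
    if eps > 0:
        beta_d = (Gc[0, 0] - Gc[1, 1]) / (2 * eps)
        beta_c = Gc[0, 1] / eps
    else:
        beta_d = beta_c = 0.0
    return CanonicalOUP(mu=mu, omega=omega, eps=eps, beta_d=beta_d,
                        beta_c=beta_c, transform=S)


def oup_mean_period(p: CanonicalOUP) -> float:
    """Closed-form mean-return-time period of the canonical spiral sink.

    T = (2*pi/omega) * sqrt((omega^2 + mu^2*(1 - beta_c^2 - beta_d^2))
                            / (mu^2 + omega^2)),

    obtained by integrating the x-component of the stationary Gaussian
    current along the positive y-axis: 1/T = omega / (2*pi*|mu|*sqrt(det Pi))
    with det Pi from :func:`oup_stationary_covariance`.  Depends on the
    anisotropy only through beta_c^2 + beta_d^2 (normalization invariant)
    and reduces to 2*pi/omega for isotropic noise or mu -> 0.
    """
    if p.omega <= 0:
        raise ValueError("omega must be positive")
    b2 = p.beta_c ** 2 + p.beta_d ** 2
    return (2 * math.pi / p.omega) * math.sqrt(
        (p.omega ** 2 + p.mu ** 2 * (1 - b2)) / (p.mu ** 2 + p.omega ** 2))


def oup_stationary_covariance(p: CanonicalOUP):
    """Stationary covariance structure: (Pi, Pi^-1, det Pi).

    The stationary density is the zero-mean Gaussian with covariance
    eps * Pi; Pi solves the Lyapunov equation A (eps Pi) + (eps Pi) A^T + 2 G = 0.
    """
    if p.mu >= 0:
        raise ValueError("mu must be negative for a stationary density")
    mu, om, bd, bc = p.mu, p.omega, p.beta_d, p.beta_c
    den = -mu * (om ** 2 + mu ** 2)
    pi11 = ((1 + bd) * mu ** 2 + om ** 2 + mu * om * bc) / den
    pi22 = ((1 - bd) * mu ** 2 + om ** 2 - mu * om * bc) / den
    pi12 = (bd * om - bc * mu) / (om ** 2 + mu ** 2)
    Pi = np.array([[pi11, pi12], [pi12, pi22]])
    det = (om ** 2 + mu ** 2 * (1 - bc ** 2 - bd ** 2)) / (mu ** 2 * (mu ** 2 + om ** 2))
    return Pi, np.linalg.inv(Pi), det


def oup_stationary_density(p: CanonicalOUP) -> Callable:
    """Vectorized Gaussian stationary density with covariance eps*Pi."""
    Pi, Pi_inv, det = oup_stationary_covariance(p)
    norm = 1.0 / (2 * math.pi * p.eps * math.sqrt(det))

    def density(x, y):
        q = (Pi_inv[0, 0] * x ** 2 + 2 * Pi_inv[0, 1] * x * y
             + Pi_inv[1, 1] * y ** 2)
        return norm * np.exp(-q / (2 * p.eps))

    return density


def oup_stationary_current(p: CanonicalOUP) -> Callable:
    """Closed-form stationary probability current (Jx, Jy) of the spiral sink.

    J = (A x) P0 - eps * Gtilde grad P0 with grad P0 = -P0 * Pi^-1 x / eps,
    i.e. J = P0 * (A + Gtilde Pi^-1) x.
    """
    Pi, Pi_inv, _ = oup_stationary_covariance(p)
    density = oup_stationary_density(p)
    Gt = np.array([[1 + p.beta_d, p.beta_c], [p.beta_c, 1 - p.beta_d]])
    Mmat = p.A + Gt @ Pi_inv

    def current(x, y):
        rho = density(x, y)
        return (Mmat[0, 0] * x + Mmat[0, 1] * y) * rho, \
               (Mmat[1, 0] * x + Mmat[1, 1] * y) * rho

    return current


def oup_omega_term(x, p: CanonicalOUP):
    """Analytic noise-drag term Omega(x) for the canonical spiral sink.

    Omega = 2 sum_ij G_ij d_i ln(u) d_j psi with u = r, psi = arctan(x2/x1);
    Omega(c x) = Omega(x) / c^2 and Omega diverges at the origin.
    """
    x = np.asarray(x, float)
    x1, x2 = x[..., 0] if x.ndim > 1 else x[0], x[..., 1] if x.ndim > 1 else x[1]
    r4 = (x1 ** 2 + x2 ** 2) ** 2
    if np.any(r4 == 0):
        raise ValueError("Omega diverges at the origin")
    return -4 * p.eps * (p.beta_d * x1 * x2 / r4
                         - p.beta_c * (x1 ** 2 - x2 ** 2) / (2 * r4))


def oup_delta_psi(x, p: CanonicalOUP):
    """Analytic phase difference Delta-psi = Theta - psi for the spiral sink.

    Delta-psi = eps*(gamma*(x^2-y^2) + 2*alpha*x*y) / ((omega^2+mu^2)(x^2+y^2)^2)
    with gamma = -beta_c*mu + beta_d*omega, alpha = beta_c*omega + beta_d*mu.
    Even under point reflection (x, y) -> (-x, -y).

    This quadrupolar field satisfies L+[dpsi] = Omega with an O(eps^2 / r^4)
    residual, which makes it the natural initial seed for the least-squares
    solver near the phaseless point; the full bounded-domain solution adds a
    slowly varying radial component ~ (Delta-omega/mu) ln r tied to the
    constant Delta-omega forcing.
    """
    x = np.asarray(x, float)
    x1, x2 = x[..., 0] if x.ndim > 1 else x[0], x[..., 1] if x.ndim > 1 else x[1]
    r2 = x1 ** 2 + x2 ** 2
    if np.any(r2 == 0):
        raise ValueError("Delta-psi is singular at the origin")
    gam = -p.beta_c * p.mu + p.beta_d * p.omega
    alp = p.beta_c * p.omega + p.beta_d * p.mu
    return (p.eps * (gam * (x1 ** 2 - x2 ** 2) + 2 * alp * x1 * x2)
            / ((p.omega ** 2 + p.mu ** 2) * r2 ** 2))


# ---------------------------------------------------------------------------
# model factory
# ---------------------------------------------------------------------------

def _constant_diffusion(G):
    G = np.asarray(G, float)

    def diffusion(x, y):
        shape = np.broadcast(np.asarray(x), np.asarray(y)).shape
        return (np.full(shape, G[0, 0]), np.full(shape, G[0, 1]),
                np.full(shape, G[1, 1]))

    return diffusion


def linear_model(A, B, domain=None, name="linear") -> LangevinModel:
    """A linear SDE dX = A X dt + B dW in its original coordinates."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    G = 0.5 * B @ B.T
    if domain is None:
        domain = DEFAULT_DOMAINS["spiral_sink"]
    kp = np.array([A[0, 0], A[0, 1], A[1, 0], A[1, 1]])
    canonical = None
    tr = 0.5 * np.trace(A)
    if np.linalg.det(A) - tr ** 2 > 0 and tr < 0:
        canonical = oup_canonicalize(A, B)
    return LangevinModel(
        name=name,
        drift=lambda x, y, _p=kp: _kernels.drift_linear.py_func(x, y, _p),
        diffusion=_constant_diffusion(G),
        domain=tuple(domain),
        params={"A": A, "B": B},
        g_const=B.copy(),
        drift_kernel=_kernels.drift_linear,
        kernel_params=kp,
        canonical_oup=canonical,
    )


def oup_model(p: CanonicalOUP, domain=None) -> LangevinModel:
    """The canonical spiral sink as a LangevinModel (g = sqrt(2G), symmetric root)."""
    G = p.G
    # symmetric matrix square root of 2G
    w, V = np.linalg.eigh(2 * G)
    g = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    if domain is None:
        domain = DEFAULT_DOMAINS["spiral_sink"]
    A = p.A
    kp = np.array([A[0, 0], A[0, 1], A[1, 0], A[1, 1]])
    return LangevinModel(
        name="spiral_sink",
        drift=lambda x, y, _p=kp: _kernels.drift_linear.py_func(x, y, _p),
        diffusion=_constant_diffusion(G),
        domain=tuple(domain),
        params={"mu": p.mu, "omega": p.omega, "eps": p.eps,
                "betaD": p.beta_d, "betaC": p.beta_c},
        g_const=g,
        drift_kernel=_kernels.drift_linear,
        kernel_params=kp,
        canonical_oup=replace(p, transform=np.eye(2)),
    )


# c4 = 3 reproduces the reported oscillator (deterministic period 5.26,
# leading eigenvalue -0.435 + 1.049i); see the methods note on this choice.
_WC_DEFAULTS = dict(c1=13.0, c2=12.0, c3=6.0, c4=3.0, a_e=1.3, a_i=2.0,
                    theta_e=4.0, theta_i=1.5, P=2.5, Q=0.0, D_e=0.1, D_i=0.05)
_SPIRAL_DEFAULTS = dict(mu=-0.0796, omega=0.564, eps=0.0046, betaD=-0.74,
                        betaC=0.11)


def make_model(name: str, **params) -> LangevinModel:
    """Build a packaged model by name, with optional parameter overrides.

    Names: ``spiral_sink`` (canonical OUP; pass either mu/omega/eps/betaD/betaC
    or matrices A, B for original coordinates), ``wilson_cowan``,
    ``van_der_pol``, ``heteroclinic`` and ``custom`` (supply drift, diffusion
    or noise matrix g, and domain explicitly).
    """
    if name == "spiral_sink":
        if "A" in params:
            return linear_model(params["A"], params["B"],
                                domain=params.get("domain"), name="spiral_sink")
        kw = {**_SPIRAL_DEFAULTS, **params}
        p = CanonicalOUP(mu=kw["mu"], omega=kw["omega"], eps=kw["eps"],
                         beta_d=kw["betaD"], beta_c=kw["betaC"])
        return oup_model(p, domain=kw.get("domain"))

    if name == "wilson_cowan":
        kw = {**_WC_DEFAULTS, **params}
        kp = np.array([kw["c1"], kw["c2"], kw["c3"], kw["c4"], kw["a_e"],
                       kw["a_i"], kw["theta_e"], kw["theta_i"], kw["P"], kw["Q"]])
        de, di = float(kw["D_e"]), float(kw["D_i"])
        if min(de, di) < 0:
            raise ValueError("noise amplitudes must be nonnegative")
        g = np.diag([de, di])
        return LangevinModel(
            name="wilson_cowan",
            drift=lambda x, y, _p=kp: _kernels.drift_wilson_cowan.py_func(x, y, _p),
            diffusion=_constant_diffusion(0.5 * g @ g.T),
            domain=tuple(kw.get("domain", DEFAULT_DOMAINS["wilson_cowan"])),
            params=kw,
            g_const=g,
            drift_kernel=_kernels.drift_wilson_cowan,
            kernel_params=kp,
            limit_cycle_seed=(0.4, 0.2),
        )

    if name == "van_der_pol":
        kw = {"D": 0.1, "noise_ratio": 0.1, **params}
        amp = math.sqrt(2 * float(kw["D"]))
        g = np.diag([amp, float(kw["noise_ratio"]) * amp])
        kp = np.zeros(1)
        return LangevinModel(
            name="van_der_pol",
            drift=lambda x, y, _p=kp: _kernels.drift_van_der_pol.py_func(x, y, _p),
            diffusion=_constant_diffusion(0.5 * g @ g.T),
            domain=tuple(kw.get("domain", DEFAULT_DOMAINS["van_der_pol"])),
            params=kw,
            g_const=g,
            drift_kernel=_kernels.drift_van_der_pol,
            kernel_params=kp,
            limit_cycle_seed=(1.0, 0.0),
        )

    if name == "heteroclinic":
        kw = {"alpha": 0.1, "D": 0.01125, **params}
        amp = math.sqrt(2 * float(kw["D"]))
        g = amp * np.eye(2)
        kp = np.array([float(kw["alpha"])])
        return LangevinModel(
            name="heteroclinic",
            drift=lambda x, y, _p=kp: _kernels.drift_heteroclinic.py_func(x, y, _p),
            diffusion=_constant_diffusion(0.5 * g @ g.T),
            domain=tuple(kw.get("domain", DEFAULT_DOMAINS["heteroclinic"])),
            boundary_flavor="reflecting_adjoint",
            params=kw,
            g_const=g,
            drift_kernel=_kernels.drift_heteroclinic,
            kernel_params=kp,
        )

    if name == "custom":
        if "g" in params:
            g = np.asarray(params["g"], float)
            params = {**params, "diffusion": _constant_diffusion(0.5 * g @ g.T),
                      "g_const": g}
        return LangevinModel(
            name=params.get("label", "custom"),
            drift=params["drift"],
            diffusion=params["diffusion"],
            domain=tuple(params["domain"]),
            boundary_flavor=params.get("boundary_flavor", "one_sided"),
            params={k: v for k, v in params.items()
                    if k not in ("drift", "diffusion", "domain", "g_const")},
            noise=params.get("noise"),
            g_const=params.get("g_const"),
        )

    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


# ---------------------------------------------------------------------------
# deterministic limit-cycle period
# ---------------------------------------------------------------------------

def deterministic_period(model: LangevinModel, seed_point=None,
                         t_transient=200.0, n_returns=5, rtol=1e-10) -> float:
    """Period of the attracting limit cycle of the noiseless drift.

    Integrates past transients from ``seed_point``, then measures Poincaré
    return times through the hyperplane normal to the flow at the cycle
    point of maximal first coordinate.  Raises :class:`NoLimitCycleError`
    when the flow settles onto an equilibrium instead.
    """
    if seed_point is None:
        seed_point = model.limit_cycle_seed or (0.5, 0.5)

    def rhs(t, z):
        fx, fy = model.drift(z[0], z[1])
        return [float(fx), float(fy)]

    sol = solve_ivp(rhs, (0, t_transient), list(seed_point), rtol=rtol,
                    atol=1e-12, dense_output=True, max_step=1.0)
    z_end = sol.y[:, -1]
    # probe a window for stationarity: an equilibrium has a collapsing orbit
    probe = solve_ivp(rhs, (0, 20.0), z_end, rtol=rtol, atol=1e-12,
                      t_eval=np.linspace(0, 20.0, 400), max_step=1.0)
    spread = probe.y.max(axis=1) - probe.y.min(axis=1)
    if np.max(spread) < 1e-6:
        raise NoLimitCycleError(
            "no limit cycle: the noiseless flow converges to an equilibrium")

    # section anchor: cycle point of maximal first coordinate
    i_max = int(np.argmax(probe.y[0]))
    p = probe.y[:, i_max]
    fp = np.array(rhs(0.0, p))
    fp /= np.linalg.norm(fp)

    def section(t, z):
        return fp[0] * (z[0] - p[0]) + fp[1] * (z[1] - p[1])

    section.direction = 1.0
    span = 50.0 * 20.0  # generous: many periods
    ev = solve_ivp(rhs, (0, span), p, rtol=rtol, atol=1e-12, events=section,
                   max_step=1.0)
    t_ev = ev.t_events[0]
    # discard crossings far from the anchor (other branches of the section line)
    pts = ev.y_events[0]
    close = np.linalg.norm(pts - p, axis=1) < 0.5 * max(np.max(spread), 1e-3) + 1e-9
    t_ev = t_ev[close]
    if len(t_ev) < n_returns + 1:
        raise NoLimitCycleError("could not collect enough Poincaré returns")
    periods = np.diff(t_ev[: n_returns + 1])
    if np.std(periods) > 1e-4 * np.mean(periods):
        raise NoLimitCycleError("return times do not converge to a fixed period")
    return float(np.mean(periods))
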