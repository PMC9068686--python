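"""Low-lying spectrum of the discretized Kolmogorov operators.

Three eigenmodes carry the phase-reduction content of a planar stochastic
oscillator: the stationary density P0 (forward operator, eigenvalue 0),
the slowest-decaying complex mode (backward operator, lambda_1 = mu + i*omega)
whose argument is the stochastic asymptotic phase psi(x) and whose modulus
u(x) is the oscillation amplitude, and the slowest-decaying purely real
mode Sigma (the stochastic isostable coordinate; its zero level set is the
"stochastic limit cycle" used to anchor zero phase).

Eigenpairs are extracted with a shift-invert Arnoldi solve targeted just
above zero, which captures the whole low-lying window in one factorization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import eigs

from .gridops import DiscreteOperator, RectGrid

__all__ = [
    "SpectralMode",
    "PhaseField",
    "NotOscillatoryError",
    "stationary_density",
    "leading_complex_mode",
    "floquet_mode",
    "amplitude_phase",
    "align_zero_phase",
    "zero_phase_anchor",
    "spectrum_window",
    "wrap_angle",
    "wrap_to_pi",
]

TWO_PI = 2.0 * math.pi


class NotOscillatoryError(RuntimeError):
    """The leading nontrivial eigenvalue is real: the system does not meet
    the robustly-oscillatory condition (complex lambda_1 with a spectral gap)."""


def wrap_angle(a):
    """Wrap to [0, 2*pi); rounding can make np.mod return the modulus itself."""
    w = np.mod(a, TWO_PI)
    return np.where(w >= TWO_PI, 0.0, w)


def wrap_to_pi(a):
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), TWO_PI)


@dataclass
class SpectralMode:
    """An eigenvalue with its grid eigenfunction."""

    eigenvalue: complex
    values: np.ndarray  # (N, M)
    kind: str  # "stationary" | "complex_leading" | "floquet"
    grid: RectGrid
    info: dict

    @property
    def flat(self):
        return self.values.ravel()


@dataclass
class PhaseField:
    """Angles wrapped to [0, 2*pi) on the grid, plus amplitude companion.

    ``orientation`` is the counterclockwise winding sign of the field around
    the phaseless point; the temporal mean phase velocity is +omega > 0 by
    the lambda_1 sign convention regardless of the spatial rotation sense.
    """

    values: np.ndarray  # wrapped angles, (N, M)
    grid: RectGrid
    amplitude: np.ndarray | None = None
    phaseless: tuple | None = None
    anchor: tuple | None = None
    orientation: int = 1
    label: str = "psi"

    def value_at(self, x, y):
        """Branch-cut-free point evaluation via cos/sin interpolation."""
        c = _linear_interp(self.grid, np.cos(self.values))(x, y)
        s = _linear_interp(self.grid, np.sin(self.values))(x, y)
        out = wrap_angle(np.arctan2(s, c))
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out.reshape(-1)[0])
        return out

    def winding_number(self, center=None, radius=None, n=720):
        """Winding of the field along a counterclockwise circle."""
        if center is None:
            center = self.phaseless
        if center is None:
            raise ValueError("no center available for the winding loop")
        x_lo, x_hi, y_lo, y_hi = self.grid.bounds
        if radius is None:
            radius = 0.8 * min(center[0] - x_lo, x_hi - center[0],
                               center[1] - y_lo, y_hi - center[1])
        t = np.linspace(0.0, TWO_PI, n, endpoint=True)
        vals = self.value_at(center[0] + radius * np.cos(t),
                             center[1] + radius * np.sin(t))
        return int(np.rint(np.sum(wrap_to_pi(np.diff(vals))) / TWO_PI))


def _linear_interp(grid, values):
    f = RegularGridInterpolator((grid.x, grid.y), values, method="linear",
                                bounds_error=False, fill_value=None)
    return lambda x, y: f(np.stack(np.broadcast_arrays(x, y), axis=-1))


# ---------------------------------------------------------------------------
# eigen-solves
# ---------------------------------------------------------------------------

def _operator_scale(op: DiscreteOperator) -> float:
    return float(np.abs(op.matrix.diagonal()).max())


def spectrum_window(op: DiscreteOperator, k=20, seed=0, sigma=None):
    """The ``k`` eigenpairs nearest a small positive shift (cached on the operator).

    Shift-invert targets the low-lying spectrum: the trivial ~0 eigenvalue,
    the leading complex pair and the leading real (Floquet) mode all live in
    this window for the packaged models.
    """
    scale = _operator_scale(op)
    if sigma is None:
        sigma = max(1e-6 * scale, 1e-8)
    key = (int(k), int(seed), float(sigma))
    if key in op._cache:
        return op._cache[key]
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(op.matrix.shape[0])
    vals, vecs = eigs(op.matrix.tocsc(), k=k, sigma=sigma, which="LM", v0=v0)
    order = np.argsort(-vals.real)
    out = (vals[order], vecs[:, order])
    op._cache[key] = out
    return out


def stationary_density(fwd: DiscreteOperator, k=6, seed=0,
                       negative_tol=1e-3) -> SpectralMode:
    """Stationary probability density P0: the null mode of the forward operator.

    Normalized to unit quadrature integral; sign-fixed positive.  Raises if
    the near-zero eigenvalue is not separated from the rest of the spectrum
    or if the eigenvector has negative parts exceeding ``negative_tol`` of
    its maximum (before clipping).  The default tolerance allows the small
    (~1e-6 .. 1e-4 of max) undershoot a non-monotone second-order scheme
    produces along steep density ridges at high cell Peclet number; the
    achieved value is recorded in ``info``.
    """
    grid = fwd.grid
    scale = _operator_scale(fwd)
    vals, vecs = spectrum_window(fwd, k=k, seed=seed)
    i0 = int(np.argmin(np.abs(vals)))
    lam0 = vals[i0]
    if abs(lam0) > 1e-6 * scale:
        raise RuntimeError(f"no eigenvalue near zero (closest: {lam0:.3e})")
    others = np.delete(np.abs(vals), i0)
    if others.size and others.min() < 1e-6 * scale:
        raise RuntimeError("stationary eigenvalue not separated from the "
                           "rest of the spectrum")
    v = vecs[:, i0]
    # null mode of a real operator: rotate to the real axis
    v = v * np.exp(-1j * np.angle(v[np.argmax(np.abs(v))]))
    v = v.real
    if v.sum() < 0:
        v = -v
    worst = -v.min() / v.max() if v.max() > 0 else np.inf
    if worst > negative_tol:
        raise RuntimeError(f"stationary mode has negative parts "
                           f"({worst:.2e} of max, tol {negative_tol:.0e})")
    v = np.clip(v, 0.0, None)
    v = v / np.sum(grid.weights * v)
    return SpectralMode(0.0, grid.reshape(v), "stationary", grid,
                        {"raw_eigenvalue": complex(lam0),
                         "negative_fraction_of_max": float(worst)})


def leading_complex_mode(bwd: DiscreteOperator, k=20, seed=0) -> SpectralMode:
    """Slowest-decaying complex mode (lambda_1 = mu + i*omega, Q*).

    Among nontrivial eigenvalues (the exact-kernel constant mode excluded)
    picks the one of largest real part with nonzero imaginary part, on the
    omega > 0 branch.  ``info`` reports the quality factor |omega/mu| and
    whether every other nontrivial eigenvalue satisfies Re < 2*mu
    (the robustly-oscillatory gap condition).
    """
    grid = bwd.grid
    scale = _operator_scale(bwd)
    vals, vecs = spectrum_window(bwd, k=k, seed=seed)
    ztol = 1e-7 * scale
    itol = 1e-9 * scale
    nontrivial = np.abs(vals) > ztol
    cplx = nontrivial & (np.abs(vals.imag) > itol)
    if not np.any(cplx):
        raise NotOscillatoryError(
            "no complex eigenvalue in the low-lying window: the system is "
            "not robustly oscillatory")
    idx = np.flatnonzero(cplx)
    i1 = idx[np.argmax(vals.real[idx])]
    real_candidates = np.flatnonzero(nontrivial & ~cplx)
    if real_candidates.size and vals.real[real_candidates].max() >= vals.real[i1]:
        raise NotOscillatoryError(
            "leading nontrivial eigenvalue is real: the system is not "
            "robustly oscillatory")
    lam1 = vals[i1]
    v = vecs[:, i1]
    if lam1.imag < 0:
        lam1 = lam1.conjugate()
        v = v.conjugate()
    mu, omega = lam1.real, lam1.imag
    rest = vals[nontrivial & (np.abs(vals - lam1) > itol)
                & (np.abs(vals - lam1.conjugate()) > itol)]
    gap_ok = bool(np.all(rest.real < 2 * mu)) if rest.size else True
    v = v / np.abs(v).max()
    return SpectralMode(lam1, grid.reshape(v), "complex_leading", grid,
                        {"mu": mu, "omega": omega,
                         "quality_factor": abs(omega / mu) if mu != 0 else np.inf,
                         "gap_ok": gap_ok,
                         "window_eigenvalues": vals.copy()})


def floquet_mode(bwd: DiscreteOperator, k=20, seed=0) -> SpectralMode:
    """Slowest-decaying purely real nontrivial mode (lambda_Floq, Sigma).

    Sigma is scaled to unit maximum modulus; it changes sign across its zero
    level set Sigma_0 (it is quadrature-orthogonal to the stationary density).
    """
    grid = bwd.grid
    scale = _operator_scale(bwd)
    vals, vecs = spectrum_window(bwd, k=k, seed=seed)
    ztol = 1e-7 * scale
    itol = 1e-9 * scale
    real_nontrivial = (np.abs(vals) > ztol) & (np.abs(vals.imag) < itol)
    if not np.any(real_nontrivial):
        raise RuntimeError("no real nontrivial eigenvalue in the Arnoldi window")
    idx = np.flatnonzero(real_nontrivial)
    i_f = idx[np.argmax(vals.real[idx])]
    lam = float(vals[i_f].real)
    v = vecs[:, i_f]
    v = v * np.exp(-1j * np.angle(v[np.argmax(np.abs(v))]))
    imag_rel = float(np.abs(v.imag).max() / np.abs(v.real).max())
    v = v.real
    v = v / np.abs(v).max()
    return SpectralMode(lam, grid.reshape(v), "floquet", grid,
                        {"imag_residual": imag_rel})


# ---------------------------------------------------------------------------
# phase extraction and anchoring
# ---------------------------------------------------------------------------

def _refine_minimum(grid: RectGrid, field, i0, j0, half=2):
    """Sub-grid minimum via a least-squares quadratic fit on a (2*half+1)^2 patch."""
    i_lo, i_hi = max(i0 - half, 0), min(i0 + half + 1, grid.N)
    j_lo, j_hi = max(j0 - half, 0), min(j0 + half + 1, grid.M)
    xs = grid.x[i_lo:i_hi]
    ys = grid.y[j_lo:j_hi]
    Xp, Yp = np.meshgrid(xs - grid.x[i0], ys - grid.y[j0], indexing="ij")
    z = field[i_lo:i_hi, j_lo:j_hi].ravel()
    A = np.column_stack([np.ones_like(z), Xp.ravel(), Yp.ravel(),
                         Xp.ravel() ** 2, Xp.ravel() * Yp.ravel(), Yp.ravel() ** 2])
    c = np.linalg.lstsq(A, z, rcond=None)[0]
    H = np.array([[2 * c[3], c[4]], [c[4], 2 * c[5]]])
    if np.linalg.det(H) <= 0:  # not convex: keep the grid argmin
        return grid.x[i0], grid.y[j0]
    dxy = np.linalg.solve(H, [-c[1], -c[2]])
    if np.abs(dxy[0]) > grid.dx or np.abs(dxy[1]) > grid.dy:
        return grid.x[i0], grid.y[j0]
    return grid.x[i0] + dxy[0], grid.y[j0] + dxy[1]


def amplitude_phase(mode, grid: RectGrid | None = None,
                    vanish_fraction=0.01) -> PhaseField:
    """Split a complex eigenfunction Q into amplitude u = |Q| and phase arg Q.

    The phaseless point is the (sub-grid refined) argmin of u; the
    counterclockwise winding of the phase around it is recorded as the
    orientation (+1 counterclockwise rotation, -1 clockwise).
    """
    if isinstance(mode, SpectralMode):
        Q, grid = mode.values, mode.grid
    else:
        Q = np.asarray(mode)
        if grid is None:
            raise ValueError("grid required when passing a bare array")
    u = np.abs(Q)
    umax = u.max()
    if umax == 0 or np.mean(u < 1e-6 * umax) > vanish_fraction:
        raise ValueError("amplitude vanishes on more than "
                         f"{vanish_fraction:.0%} of nodes: wrong mode?")
    psi = wrap_angle(np.angle(Q))
    i0, j0 = np.unravel_index(np.argmin(u), u.shape)
    phaseless = _refine_minimum(grid, u ** 2, int(i0), int(j0))
    field = PhaseField(psi, grid, amplitude=u / umax, phaseless=phaseless)
    field.orientation = field.winding_number()
    return field


def zero_phase_anchor(sigma: SpectralMode, margin_cells=1.0):
    """Maximal-x point on the zero level set of the isostable field Sigma.

    Scans sign changes of Sigma along grid edges and linearly interpolates
    each crossing.  Raises if the level set is empty or touches the border.
    """
    S = sigma.values
    grid = sigma.grid
    pts = []
    sx = S[:-1, :] * S[1:, :]
    for i, j in zip(*np.nonzero(sx < 0)):
        t = S[i, j] / (S[i, j] - S[i + 1, j])
        pts.append((grid.x[i] + t * grid.dx, grid.y[j]))
    sy = S[:, :-1] * S[:, 1:]
    for i, j in zip(*np.nonzero(sy < 0)):
        t = S[i, j] / (S[i, j] - S[i, j + 1])
        pts.append((grid.x[i], grid.y[j] + t * grid.dy))
    if not pts:
        raise RuntimeError("isostable zero level set is empty")
    pts = np.asarray(pts)
    xa, ya = pts[np.argmax(pts[:, 0])]
    x_lo, x_hi, y_lo, y_hi = grid.bounds
    if (xa > x_hi - margin_cells * grid.dx or xa < x_lo + margin_cells * grid.dx
            or ya > y_hi - margin_cells * grid.dy
            or ya < y_lo + margin_cells * grid.dy):
        raise RuntimeError("isostable zero level set touches the boundary")
    return float(xa), float(ya)


def align_zero_phase(phase: PhaseField, sigma) -> PhaseField:
    """Shift the phase by a constant so it vanishes at the isostable anchor.

    The anchor is the maximal-x point of the Sigma = 0 contour (the
    "stochastic limit cycle"); the same anchor is reused for psi and Theta
    so the two phases are directly comparable.  Idempotent; pairwise phase
    differences are untouched.
    """
    anchor = sigma if isinstance(sigma, tuple) else zero_phase_anchor(sigma)
    offset = float(phase.value_at(*anchor))
    return replace(phase, values=wrap_angle(phase.values - offset),
                   anchor=anchor)
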