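"""Monte-Carlo verification of the mean-return-time property.

A phase field has the MRT property when the mean time for a trajectory to
gain 2*pi of (unwrapped) phase is the same for every starting point on an
isochron, and equals the mean period T.  This module simulates the SDE
with the Euler–Heun scheme, follows the interpolated phase along each
trajectory, records first 2*pi-return times, and compares the means across
sample points spread along an isochron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from . import _kernels
from .gridops import RectGrid
from .spectral import PhaseField, wrap_angle, wrap_to_pi

__all__ = [
    "PhaseInterpolant",
    "ReturnTimeReport",
    "simulate_paths",
    "phase_interpolant",
    "mean_return_time",
    "mrt_uniformity",
    "isochron_points",
]

TWO_PI = 2.0 * math.pi


class PhaseInterpolant:
    """Branch-cut-free continuous phase map built from a grid phase field.

    Bicubic splines are fitted to cos(phase) and sin(phase) separately and
    recombined through atan2, so the interpolant is continuous across the
    0/2*pi cut.  The raw cos/sin grids are retained for the compiled
    Monte-Carlo kernels, which use bilinear interpolation of the same
    fields (an O(h^2) difference, far below Monte-Carlo error).
    """

    def __init__(self, grid: RectGrid, values: np.ndarray):
        self.grid = grid
        self.cos_grid = np.ascontiguousarray(np.cos(values))
        self.sin_grid = np.ascontiguousarray(np.sin(values))
        self._cs = RectBivariateSpline(grid.x, grid.y, self.cos_grid)
        self._sn = RectBivariateSpline(grid.x, grid.y, self.sin_grid)

    def __call__(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        x_lo, x_hi, y_lo, y_hi = self.grid.bounds
        if np.any(x < x_lo) or np.any(x > x_hi) or np.any(y < y_lo) or np.any(y > y_hi):
            raise ValueError("query outside the phase-field domain")
        return wrap_angle(np.arctan2(self._sn.ev(x, y), self._cs.ev(x, y)))

    def eval_clamped(self, x, y):
        """Evaluation with out-of-domain queries clamped to the boundary."""
        x_lo, x_hi, y_lo, y_hi = self.grid.bounds
        return self(np.clip(x, x_lo, x_hi), np.clip(y, y_lo, y_hi))


def phase_interpolant(grid: RectGrid, phase) -> PhaseInterpolant:
    values = phase.values if isinstance(phase, PhaseField) else np.asarray(phase)
    return PhaseInterpolant(grid, values)


@dataclass
class ReturnTimeReport:
    """Per-start-point mean 2*pi-return times along one isochron."""

    points: np.ndarray            # (k, 2) start points
    means: np.ndarray             # (k,)
    standard_errors: np.ndarray   # (k,)
    n_paths: int
    dt: float
    horizon: float
    seed: int
    isochron_level: float
    label: str = ""
    nonreturn_fractions: np.ndarray = field(default=None)
    tolerance: float = 0.01
    extras: dict = field(default_factory=dict)

    @property
    def grand_mean(self) -> float:
        return float(np.mean(self.means))

    @property
    def flatness(self) -> float:
        """Max relative spread of the per-point means around the grand mean."""
        g = self.grand_mean
        return float(np.max(np.abs(self.means - g)) / g)

    @property
    def passed(self) -> bool:
        """MRT property verdict: every pair of per-point means agrees
        within tolerance * grand_mean + 3 combined standard errors."""
        g = self.grand_mean
        m, s = self.means, self.standard_errors
        for i in range(len(m)):
            for j in range(i + 1, len(m)):
                if abs(m[i] - m[j]) > self.tolerance * g + 3.0 * math.hypot(s[i], s[j]):
                    return False
        return True

    def consistent_with(self, T_ref, tolerance=None) -> bool:
        """Is the grand mean compatible with a reference period?

        Allows ``tolerance`` (default: the report tolerance, i.e. the
        discretization-level agreement expected between the operator and
        pathwise estimates) plus three standard errors of the grand mean.
        """
        tol = self.tolerance if tolerance is None else tolerance
        se_grand = float(np.sqrt(np.sum(self.standard_errors ** 2)) / len(self.means))
        return bool(abs(self.grand_mean - T_ref) <= tol * T_ref + 3.0 * se_grand)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x0": self.points[:, 0], "y0": self.points[:, 1],
            "mean_return_time": self.means, "standard_error": self.standard_errors,
            "n": self.n_paths,
            "nonreturn_fraction": self.nonreturn_fractions,
        })

    def to_json_dict(self) -> dict:
        return {
            "label": self.label, "isochron_level": self.isochron_level,
            "points": self.points.tolist(), "means": self.means.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "n": self.n_paths, "dt": self.dt, "horizon": self.horizon,
            "seed": self.seed, "grand_mean": self.grand_mean,
            "flatness": self.flatness, "tolerance": self.tolerance,
            "passed": self.passed,
            "nonreturn_fractions": self.nonreturn_fractions.tolist(),
        }


def _kernel_ingredients(model):
    if model.drift_kernel is None or model.g_const is None:
        return None
    return (model.drift_kernel, np.asarray(model.kernel_params, float),
            np.asarray(model.g_const, float))


def simulate_paths(model, x0, dt, horizon, n, seed, save_every=1):
    """Euler–Heun ensemble of ``n`` trajectories from ``x0``.

    Heun predictor–corrector on the drift with the plain Gaussian increment
    (identical to Euler–Maruyama for the packaged additive-noise models);
    reflecting walls for bounded domains.  Returns an array of shape
    (n, n_saved + 1, 2) including the initial state.  Reproducible given
    ``seed``; raises on trajectory blow-up.
    """
    if dt <= 0 or n < 1:
        raise ValueError("need dt > 0 and n >= 1")
    x_lo, x_hi, y_lo, y_hi = model.domain
    if not (x_lo <= x0[0] <= x_hi and y_lo <= x0[1] <= y_hi):
        raise ValueError("x0 outside the model domain")
    n_steps = max(1, int(round(horizon / dt)))
    reflect = model.boundary_flavor == "reflecting_adjoint"
    ing = _kernel_ingredients(model)
    if ing is not None:
        drift, p, g = ing
        out = _kernels.simulate_ensemble(drift, p, g, float(x0[0]), float(x0[1]),
                                         float(dt), n_steps, int(n),
                                         int(save_every), reflect,
                                         x_lo, x_hi, y_lo, y_hi, int(seed))
    else:
        out = _simulate_numpy(model, x0, dt, n_steps, n, save_every, reflect, seed)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("trajectory blow-up (NaN encountered) during simulation")
    return out


def _simulate_numpy(model, x0, dt, n_steps, n, save_every, reflect, seed):
    """Vectorized fallback for models without a compiled drift kernel."""
    rng = np.random.default_rng(seed)
    x_lo, x_hi, y_lo, y_hi = model.domain
    x = np.full(n, float(x0[0]))
    y = np.full(n, float(x0[1]))
    g = model.g_const
    n_saved = n_steps // save_every
    out = np.empty((n, n_saved + 1, 2))
    out[:, 0, 0], out[:, 0, 1] = x, y
    idx = 1
    sq = math.sqrt(dt)
    for s in range(n_steps):
        dw = rng.standard_normal((2, n)) * sq
        if g is not None:
            nx_, ny_ = g @ dw
        else:  # state-dependent noise, Itô increment at the left point
            g11, g12, g22 = model.diffusion(x, y)
            # g from G: symmetric square root per point
            raise NotImplementedError(
                "state-dependent noise requires an explicit noise callable")
        fx, fy = model.drift(x, y)
        xp, yp = x + fx * dt + nx_, y + fy * dt + ny_
        fxp, fyp = model.drift(xp, yp)
        x = x + 0.5 * (fx + fxp) * dt + nx_
        y = y + 0.5 * (fy + fyp) * dt + ny_
        if reflect:
            x = np.where(x < x_lo, 2 * x_lo - x, np.where(x > x_hi, 2 * x_hi - x, x))
            y = np.where(y < y_lo, 2 * y_lo - y, np.where(y > y_hi, 2 * y_hi - y, y))
        if (s + 1) % save_every == 0:
            out[:, idx, 0], out[:, idx, 1] = x, y
            idx += 1
    return out


def mean_return_time(phase_map: PhaseInterpolant, x0, model, n=10_000,
                     dt=1e-3, seed=0, horizon=None, T_bar=None,
                     max_nonreturn=1e-2):
    """Mean and standard error of the first 2*pi phase-return time from ``x0``.

    The phase along each path is unwrapped incrementally (per-step wrapped
    increments, assuming |increment| < pi per step); the horizon defaults to
    3*T_bar.  Raises when more than ``max_nonreturn`` of the paths fail to
    return within the horizon.
    """
    if horizon is None:
        if T_bar is None:
            raise ValueError("supply horizon or T_bar")
        horizon = 3.0 * float(T_bar)
    x_lo, x_hi, y_lo, y_hi = model.domain
    grid = phase_map.grid
    n_steps = int(round(horizon / dt))
    reflect = model.boundary_flavor == "reflecting_adjoint"
    ing = _kernel_ingredients(model)
    if ing is None:
        raise NotImplementedError("Monte-Carlo return times need a compiled "
                                  "drift kernel (packaged models provide one)")
    drift, p, g = ing
    times, returned, n_big, n_clamped = _kernels.return_times(
        drift, p, g, float(x0[0]), float(x0[1]), float(dt), n_steps, int(n),
        int(seed), phase_map.cos_grid, phase_map.sin_grid,
        grid.x[0], grid.y[0], 1.0 / grid.dx, 1.0 / grid.dy, grid.N, grid.M,
        reflect, x_lo, x_hi, y_lo, y_hi)
    frac_missing = 1.0 - returned.mean()
    if frac_missing > max_nonreturn:
        raise RuntimeError(f"{frac_missing:.2%} of paths did not return "
                           f"within the {horizon:.3g} horizon")
    t = times[returned]
    mean = float(t.mean())
    se = float(t.std(ddof=1) / math.sqrt(t.size))
    extras = {"nonreturn_fraction": float(frac_missing),
              "big_increment_steps": int(n_big),
              "clamped_queries": int(n_clamped),
              "n_returned": int(t.size)}
    if n_big > 0.01 * n * n_steps:
        raise RuntimeError("per-step phase increments frequently exceed pi/2; "
                           "refine dt for reliable unwrapping")
    return mean, se, extras


def isochron_points(phase: PhaseField, level, k=3, r_min=0.0, margin_frac=0.08):
    """Sample points on a phase level set, spread in the amplitude direction.

    Finds grid-edge crossings of the wrapped phase through ``level`` (away
    from the branch cut), keeps those at least ``r_min`` from the phaseless
    point and a margin from the border, sorts them by distance from the
    phaseless point and returns ``k`` points at evenly spaced quantiles of
    that distance.
    """
    grid = phase.grid
    c = wrap_to_pi(phase.values - level)
    X, Y = grid.meshes()
    pts = []
    for axis in (0, 1):
        a = c if axis == 0 else c.T
        Xa = (X if axis == 0 else X.T)
        Ya = (Y if axis == 0 else Y.T)
        prod = a[:-1, :] * a[1:, :]
        ok = (prod < 0) & (np.abs(a[:-1, :]) + np.abs(a[1:, :]) < math.pi)
        for i, j in zip(*np.nonzero(ok)):
            t = a[i, j] / (a[i, j] - a[i + 1, j])
            pts.append((Xa[i, j] + t * (Xa[i + 1, j] - Xa[i, j]),
                        Ya[i, j] + t * (Ya[i + 1, j] - Ya[i, j])))
    if not pts:
        raise RuntimeError("empty isochron level set")
    pts = np.asarray(pts)
    x_lo, x_hi, y_lo, y_hi = grid.bounds
    mx = margin_frac * (x_hi - x_lo)
    my = margin_frac * (y_hi - y_lo)
    inside = ((pts[:, 0] > x_lo + mx) & (pts[:, 0] < x_hi - mx)
              & (pts[:, 1] > y_lo + my) & (pts[:, 1] < y_hi - my))
    xb, yb = phase.phaseless if phase.phaseless is not None else (
        0.5 * (x_lo + x_hi), 0.5 * (y_lo + y_hi))
    dist = np.hypot(pts[:, 0] - xb, pts[:, 1] - yb)
    keep = inside & (dist >= max(r_min, 3 * max(grid.dx, grid.dy)))
    if keep.sum() < k:
        raise RuntimeError("isochron level set lies inside the exclusion disc")
    pts, dist = pts[keep], dist[keep]
    order = np.argsort(dist)
    picks = order[np.linspace(0.1 * (len(order) - 1), 0.9 * (len(order) - 1),
                              k).astype(int)]
    return pts[picks]


def mrt_uniformity(phase_map, isochron_level, k_points, model, n=10_000,
                   dt=1e-3, seed=0, T_bar=None, horizon=None, phase=None,
                   r_min=0.0, tolerance=0.01, label="") -> ReturnTimeReport:
    """Check the MRT property along one isochron.

    Runs :func:`mean_return_time` from ``k_points`` sample points on the
    ``isochron_level`` level set and reports the per-point means, their
    spread (flatness) and a pass/fail verdict against ``tolerance`` (a
    relative spread) plus three standard errors.
    """
    if k_points < 3:
        raise ValueError("need at least 3 sample points along the isochron")
    if phase is None:
        raise ValueError("supply the grid PhaseField via `phase` to locate "
                         "the isochron")
    pts = isochron_points(phase, isochron_level, k=k_points, r_min=r_min)
    means = np.empty(k_points)
    ses = np.empty(k_points)
    fracs = np.empty(k_points)
    for i, (px, py) in enumerate(pts):
        m, s, extras = mean_return_time(phase_map, (px, py), model, n=n, dt=dt,
                                        seed=seed + 1000 * i, T_bar=T_bar,
                                        horizon=horizon)
        means[i], ses[i] = m, s
        fracs[i] = extras["nonreturn_fraction"]
    return ReturnTimeReport(points=pts, means=means, standard_errors=ses,
                            n_paths=n, dt=dt,
                            horizon=horizon if horizon is not None else 3 * T_bar,
                            seed=seed, isochron_level=float(isochron_level),
                            label=label, nonreturn_fractions=fracs,
                            tolerance=tolerance)
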