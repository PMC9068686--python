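"""Numba-compiled drift kernels and SDE integrators.

Scalar drift kernels share their math with the vectorized model drifts
(via ``Dispatcher.py_func``), so each model's vector field is written once.
All integrators use the Euler–Heun scheme: Heun (predictor–corrector) on the
drift with the plain stochastic increment, which coincides with
Euler–Maruyama for additive noise.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def drift_linear(x, y, p):
    """dx/dt = A x with A = [[p0, p1], [p2, p3]]."""
    return p[0] * x + p[1] * y, p[2] * x + p[3] * y


@njit(cache=True)
def drift_wilson_cowan(x, y, p):
    """Wilson–Cowan E/I rates; p = [c1, c2, c3, c4, a_e, a_i, th_e, th_i, P, Q]."""
    se = 1.0 / (1.0 + np.exp(-p[4] * (p[0] * x - p[1] * y + p[8] - p[6])))
    si = 1.0 / (1.0 + np.exp(-p[5] * (p[2] * x - p[3] * y + p[9] - p[7])))
    return -x + se, -y + si


@njit(cache=True)
def drift_van_der_pol(x, y, p):
    """Van der Pol-type oscillator: xdot = -y + x - x^3, ydot = x."""
    return -y + x - x * x * x, x


@njit(cache=True)
def drift_heteroclinic(x, y, p):
    """Heteroclinic oscillator on [-pi/2, pi/2]^2; p = [alpha]."""
    fx = np.cos(x) * np.sin(y) + p[0] * np.sin(2.0 * x)
    fy = -np.sin(x) * np.cos(y) + p[0] * np.sin(2.0 * y)
    return fx, fy


@njit(cache=True, inline="always")
def _reflect(v, lo, hi):
    # fold back into [lo, hi]; a single reflection suffices for small steps
    if v < lo:
        v = 2.0 * lo - v
    elif v > hi:
        v = 2.0 * hi - v
    return v


@njit(cache=True, inline="always")
def _bilinear(zg, x0, y0, inv_dx, inv_dy, nx, ny, x, y):
    """Bilinear interpolation on a uniform grid; queries clamped to the grid."""
    tx = (x - x0) * inv_dx
    ty = (y - y0) * inv_dy
    if tx < 0.0:
        tx = 0.0
    elif tx > nx - 1.000001:
        tx = nx - 1.000001
    if ty < 0.0:
        ty = 0.0
    elif ty > ny - 1.000001:
        ty = ny - 1.000001
    i = int(tx)
    j = int(ty)
    fx = tx - i
    fy = ty - j
    return ((1.0 - fx) * (1.0 - fy) * zg[i, j]
            + fx * (1.0 - fy) * zg[i + 1, j]
            + (1.0 - fx) * fy * zg[i, j + 1]
            + fx * fy * zg[i + 1, j + 1])


@njit(cache=True)
def simulate_ensemble(drift, p, g, x0, y0, dt, n_steps, n_paths, save_every,
                      reflect, xlo, xhi, ylo, yhi, seed):
    """Integrate ``n_paths`` trajectories from (x0, y0), saving every ``save_every`` steps.

    Returns an array of shape (n_paths, n_saved + 1, 2) including the initial state.
    """
    np.random.seed(seed)
    n_saved = n_steps // save_every
    out = np.empty((n_paths, n_saved + 1, 2))
    sq = math.sqrt(dt)
    for k in range(n_paths):
        x = x0
        y = y0
        out[k, 0, 0] = x
        out[k, 0, 1] = y
        idx = 1
        for s in range(n_steps):
            dwx = sq * np.random.standard_normal()
            dwy = sq * np.random.standard_normal()
            nx_ = g[0, 0] * dwx + g[0, 1] * dwy
            ny_ = g[1, 0] * dwx + g[1, 1] * dwy
            fx, fy = drift(x, y, p)
            xp = x + fx * dt + nx_
            yp = y + fy * dt + ny_
            fxp, fyp = drift(xp, yp, p)
            x = x + 0.5 * (fx + fxp) * dt + nx_
            y = y + 0.5 * (fy + fyp) * dt + ny_
            if reflect:
                x = _reflect(x, xlo, xhi)
                y = _reflect(y, ylo, yhi)
            if not np.isfinite(x) or not np.isfinite(y):
                # signal blow-up through NaNs; caller raises
                out[k, :, :] = np.nan
                return out
            if (s + 1) % save_every == 0:
                out[k, idx, 0] = x
                out[k, idx, 1] = y
                idx += 1
    return out


@njit(cache=True)
def return_times(drift, p, g, x0, y0, dt, n_steps, n_paths, seed,
                 cos_grid, sin_grid, gx0, gy0, inv_dx, inv_dy, nx, ny,
                 reflect, xlo, xhi, ylo, yhi):
    """First time each path gains 2*pi of (incrementally unwrapped) phase.

    The phase along the trajectory is atan2 of bilinearly interpolated
    sin/cos grids; per-step increments are wrapped to (-pi, pi].

    Returns (times, returned_mask, n_big_steps, n_clamped) where
    ``n_big_steps`` counts per-step phase increments exceeding pi/2
    (a diagnostic for the |increment| < pi unwrapping assumption) and
    ``n_clamped`` counts interpolation queries clamped to the grid edge.
    """
    np.random.seed(seed)
    times = np.full(n_paths, np.nan)
    returned = np.zeros(n_paths, dtype=np.bool_)
    sq = math.sqrt(dt)
    n_big = 0
    n_clamped = 0
    for k in range(n_paths):
        x = x0
        y = y0
        c = _bilinear(cos_grid, gx0, gy0, inv_dx, inv_dy, nx, ny, x, y)
        s_ = _bilinear(sin_grid, gx0, gy0, inv_dx, inv_dy, nx, ny, x, y)
        th_prev = math.atan2(s_, c)
        acc = 0.0
        for s in range(n_steps):
            dwx = sq * np.random.standard_normal()
            dwy = sq * np.random.standard_normal()
            nx_ = g[0, 0] * dwx + g[0, 1] * dwy
            ny_ = g[1, 0] * dwx + g[1, 1] * dwy
            fx, fy = drift(x, y, p)
            xp = x + fx * dt + nx_
            yp = y + fy * dt + ny_
            fxp, fyp = drift(xp, yp, p)
            x = x + 0.5 * (fx + fxp) * dt + nx_
            y = y + 0.5 * (fy + fyp) * dt + ny_
            if reflect:
                x = _reflect(x, xlo, xhi)
                y = _reflect(y, ylo, yhi)
            elif x < xlo or x > xhi or y < ylo or y > yhi:
                n_clamped += 1
            c = _bilinear(cos_grid, gx0, gy0, inv_dx, inv_dy, nx, ny, x, y)
            s_ = _bilinear(sin_grid, gx0, gy0, inv_dx, inv_dy, nx, ny, x, y)
            th = math.atan2(s_, c)
            d = th - th_prev
            if d > math.pi:
                d -= TWO_PI
            elif d <= -math.pi:
                d += TWO_PI
            if abs(d) > 0.5 * math.pi:
                n_big += 1
            acc += d
            th_prev = th
            if acc >= TWO_PI:
                # linear sub-step localization of the 2*pi crossing
                frac = 1.0 - (acc - TWO_PI) / abs(d) if d != 0.0 else 1.0
                if frac < 0.0:
                    frac = 0.0
                times[k] = (s + frac) * dt
                returned[k] = True
                break
    return times, returned, n_big, n_clamped
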