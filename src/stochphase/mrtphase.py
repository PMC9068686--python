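"""Mean-return-time phase via the jump-free phase difference.

The MRT phase Theta and the asymptotic phase psi differ by a single-valued
field Delta-psi = Theta - psi obeying

    L+[Delta-psi] = Omega(x) + Delta-omega,

with the noise-drag term Omega = 2 sum_ij G_ij d_i ln(u) d_j psi and
Delta-omega = 2*pi/T - omega.  Omega diverges at the phaseless set, so the
linear system is solved in the least-squares sense over the nodes outside
an exclusion disc of radius r_min, with one gauge row pinning Delta-psi at
the anchor (constants span the operator's kernel); excluded nodes are then
filled by harmonic inpainting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr, splu

from .gridops import DiscreteOperator, RectGrid, gradient_matrices
from .spectral import PhaseField, SpectralMode, wrap_angle, wrap_to_pi

__all__ = ["DeltaPsiSolution", "omega_term", "omega_term_operator",
           "apply_to_angles", "solve_delta_psi", "mrt_phase"]


@dataclass
class DeltaPsiSolution:
    """The single-valued phase correction Delta-psi with its residual record."""

    values: np.ndarray  # (N, M), no 2*pi jumps
    grid: RectGrid
    r_min: float
    residual_max: float
    residual_rms: float
    retained: np.ndarray  # bool mask of nodes kept in the least-squares fit
    anchor: tuple
    converged: bool
    info: dict

    @property
    def flat(self):
        return self.values.ravel()


def omega_term(Q, model, grid: RectGrid | None = None) -> np.ndarray:
    """Noise-drag term Omega = 2 sum_ij G_ij d_i ln(u) d_j psi on the grid.

    Gradients are taken as Re(grad Q / Q) and Im(grad Q / Q), which is
    branch-cut free (no differencing of wrapped angles).  Values inside the
    phaseless disc are inaccurate (Omega diverges there) and are meant to be
    excluded downstream.
    """
    if isinstance(Q, SpectralMode):
        Q, grid = Q.values, Q.grid
    Q = np.asarray(Q)
    Dx, Dy = gradient_matrices(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        qx = grid.reshape(Dx @ Q.ravel()) / Q
        qy = grid.reshape(Dy @ Q.ravel()) / Q
    X, Y = grid.meshes()
    g11, g12, g22 = (np.broadcast_to(np.asarray(a, float), X.shape)
                     for a in model.diffusion(X, Y))
    omega = 2.0 * (g11 * qx.real * qx.imag
                   + g12 * (qx.real * qy.imag + qy.real * qx.imag)
                   + g22 * qy.real * qy.imag)
    return omega


def apply_to_angles(op, values):
    """Apply a discrete operator to a wrapped angle field, branch-cut free.

    Each row is evaluated in the local branch of its own node:
    out_i = sum_j L_ij * wrap_to_pi(a_j - a_i), which equals L[a] for any
    unwrapped representative because the backward operator annihilates
    constants.  Valid wherever neighbouring nodes differ by less than pi
    (everywhere except within a cell of the phaseless point).
    """
    mat = op.matrix.tocsr() if hasattr(op, "matrix") else sp.csr_matrix(op)
    a = np.ravel(np.asarray(values, float))
    rows = np.repeat(np.arange(mat.shape[0]), np.diff(mat.indptr))
    rel = wrap_to_pi(a[mat.indices] - a[rows])
    out = np.zeros(mat.shape[0])
    np.add.at(out, rows, mat.data * rel)
    if hasattr(op, "grid"):
        return op.grid.reshape(out)
    return out


def omega_term_operator(Q, bwd: DiscreteOperator) -> np.ndarray:
    """Noise-drag term via the operator identity Omega = omega - L+[psi].

    Uses the branch-free row-local application of the assembled backward
    operator to the phase psi = arg Q, so the downstream phase-difference
    solve is exactly consistent with the discretization: the resulting
    Theta = psi + Delta-psi satisfies the discrete L+[Theta] = 2*pi/T
    up to the least-squares residual.  Agrees with the gradient form
    :func:`omega_term` to O(h^2) away from the phaseless set.
    """
    if isinstance(Q, SpectralMode):
        omega = float(Q.eigenvalue.imag)
        psi = np.angle(Q.values)
    else:
        raise ValueError("omega_term_operator needs the SpectralMode "
                         "(eigenvalue and eigenfunction)")
    return omega - apply_to_angles(bwd, psi)


def solve_delta_psi(bwd: DiscreteOperator, omega_field, delta_omega, r_min,
                    phaseless, anchor, seed_field=None, method="auto",
                    residual_threshold=1e-2, iter_lim=5000,
                    atol=1e-10) -> DeltaPsiSolution:
    """Gauge-fixed least-squares solve of L+[Delta-psi] = Omega + Delta-omega.

    Rows whose node lies inside the disc of radius ``r_min`` around the
    phaseless point are dropped; a unit gauge row pins the solution to zero
    at the grid node nearest ``anchor``.  ``method``: ``"lsqr"`` (damped
    iterative least squares, honours the ``seed_field`` initial guess),
    ``"direct"`` (sparse normal equations) or ``"auto"`` (lsqr when a seed
    is available, direct otherwise, with a direct polish if the residual
    target is missed).  Nodes inside the disc are refilled by harmonic
    inpainting, so the reported residual statistics cover the retained
    nodes whose stencils do not touch inpainted values (a two-cell buffer
    outside ``r_min``); a residual above ``residual_threshold`` flags the
    result instead of failing.
    """
    grid = bwd.grid
    n = grid.N * grid.M
    X, Y = grid.meshes()
    r2 = (X - phaseless[0]) ** 2 + (Y - phaseless[1]) ** 2
    retained = (r2 >= float(r_min) ** 2).ravel()
    if not retained.any():
        raise ValueError("exclusion radius removes every node")
    b_full = np.ravel(omega_field) + float(delta_omega)

    ia = int(np.argmin(np.abs(grid.x - anchor[0])))
    ja = int(np.argmin(np.abs(grid.y - anchor[1])))
    k_anchor = grid.index(ia, ja)
    gauge = sp.csr_matrix((np.ones(1), (np.zeros(1, int), [k_anchor])),
                          shape=(1, n))
    blocks = [bwd.matrix.tocsr()[retained], gauge]
    rhs = [b_full[retained], [0.0]]
    excluded = np.flatnonzero(~retained)
    if excluded.size:
        # smooth extrapolation into the disc, expressed as low-weight
        # discrete-Laplace rows: they determine the otherwise-unconstrained
        # interior nodes without competing with the retained equations
        w_lap = 1e-3 * float(np.abs(bwd.matrix.diagonal()).max())
        blocks.insert(1, w_lap * _laplace_rows(excluded, grid))
        rhs.insert(1, np.zeros(excluded.size))
    A = sp.vstack(blocks).tocsr()
    b = np.concatenate(rhs)

    x0 = None
    if seed_field is not None:
        x0 = np.ravel(np.asarray(seed_field, float)).copy()

    # residual bookkeeping zone: stencils clear of the extrapolated disc
    buffer = float(r_min) + 2.0 * max(grid.dx, grid.dy) if r_min > 0 else 0.0
    clear = (r2 >= buffer ** 2).ravel()

    x, n_iter, used = None, 0, method
    if method == "lsqr" or (method == "auto" and x0 is not None):
        res = lsqr(A, b, x0=x0, atol=atol, btol=atol, iter_lim=iter_lim)
        x, n_iter = res[0], res[2]
        used = "lsqr"
    if method == "direct" or x is None or (
            method == "auto"
            and _max_residual(bwd, x, b_full, clear) > residual_threshold):
        x = _normal_equation_solve(A, b)
        used = "direct" if used != "lsqr" else "lsqr+direct"

    x = x - x[k_anchor]  # exact gauge
    values = grid.reshape(x).copy()

    r = (bwd.matrix @ values.ravel()) - b_full
    r = r[clear]
    res_max = float(np.abs(r).max())
    res_rms = float(np.sqrt(np.mean(r ** 2)))
    converged = res_max <= residual_threshold
    if not converged:
        warnings.warn(f"Delta-psi residual {res_max:.2e} above threshold "
                      f"{residual_threshold:.0e}; result flagged", stacklevel=2)
    return DeltaPsiSolution(values=values, grid=grid, r_min=float(r_min),
                            residual_max=res_max, residual_rms=res_rms,
                            retained=retained.reshape(grid.N, grid.M),
                            anchor=(grid.x[ia], grid.y[ja]), converged=converged,
                            info={"method": used, "iterations": int(n_iter),
                                  "delta_omega": float(delta_omega)})


def _max_residual(bwd, x, b_full, retained):
    if x is None:
        return np.inf
    r = (bwd.matrix @ x) - b_full
    return float(np.abs(r[retained]).max())


def _normal_equation_solve(A, b):
    """Exact least-squares minimizer via the sparse normal equations
    (full column rank is guaranteed by the gauge and extrapolation rows)."""
    At = A.T.tocsr()
    return splu((At @ A).tocsc()).solve(At @ b)


def _laplace_rows(nodes, grid):
    """Zero-mean discrete-Laplace rows (scale-free) for the given flat nodes."""
    N, M = grid.N, grid.M
    rows, cols, data = [], [], []
    for row, k in enumerate(nodes):
        i, j = divmod(int(k), M)
        nbs = []
        if i > 0:
            nbs.append(k - M)
        if i < N - 1:
            nbs.append(k + M)
        if j > 0:
            nbs.append(k - 1)
        if j < M - 1:
            nbs.append(k + 1)
        rows.append(row)
        cols.append(k)
        data.append(float(len(nbs)))
        for nb in nbs:
            rows.append(row)
            cols.append(nb)
            data.append(-1.0)
    return sp.csr_matrix((data, (rows, cols)), shape=(len(nodes), N * M))


def mrt_phase(psi: PhaseField, dpsi: DeltaPsiSolution) -> PhaseField:
    """Assemble the MRT phase Theta = psi + Delta-psi, anchored like psi.

    Both fields must live on the same grid and share the anchor; Theta is
    wrapped to [0, 2*pi) and re-pinned to zero at the anchor (Delta-psi is
    already gauged there, so the shift is a rounding-level correction).
    """
    if psi.grid is not dpsi.grid and psi.grid.to_json_dict() != dpsi.grid.to_json_dict():
        raise ValueError("psi and Delta-psi live on different grids")
    if psi.anchor is None:
        raise ValueError("psi must be anchored (align_zero_phase) first")
    if (abs(psi.anchor[0] - dpsi.anchor[0]) > psi.grid.dx
            or abs(psi.anchor[1] - dpsi.anchor[1]) > psi.grid.dy):
        raise ValueError("psi and Delta-psi anchors disagree")
    theta = wrap_angle(psi.values + dpsi.values)
    out = replace(psi, values=theta, label="theta")
    offset = float(out.value_at(*psi.anchor))
    out.values = wrap_angle(out.values - wrap_to_pi(offset))
    return out
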