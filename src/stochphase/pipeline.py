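"""End-to-end phase reduction: model object and fitted results.

:class:`StochasticOscillator` bundles a Langevin model with a grid and
solver settings; :meth:`StochasticOscillator.fit` runs the operator
pipeline — assemble L and L+, extract P0 / lambda_1 / lambda_Floq, anchor
the zero phase on the stochastic limit cycle, compute the mean period T
from the stationary current, solve for the phase difference Delta-psi and
form the MRT phase Theta = psi + Delta-psi — and returns a
:class:`PhaseReductionResult` carrying every estimate with its diagnostics,
a ``summary()`` table, Monte-Carlo checks and serialization helpers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .gridops import RectGrid, assemble_backward, assemble_forward, make_grid
from .meanperiod import CurrentField, MeanPeriodResult, mean_period, probability_current
from .models import LangevinModel, make_model, oup_delta_psi
from .mrtcheck import mrt_uniformity, phase_interpolant
from .mrtphase import (DeltaPsiSolution, mrt_phase, omega_term,
                       omega_term_operator, solve_delta_psi)
from .spectral import (PhaseField, SpectralMode, align_zero_phase, amplitude_phase,
                       floquet_mode, leading_complex_mode, stationary_density,
                       zero_phase_anchor)

__all__ = ["StochasticOscillator", "PhaseReductionResult"]


class StochasticOscillator:
    """A planar stochastic oscillator prepared for phase reduction.

    Parameters
    ----------
    model : LangevinModel
        The Langevin system (drift, diffusion, domain, boundary flavour).
    grid : RectGrid, optional
        Defaults to 120 x 120 nodes over the model domain.
    r_min : float, optional
        Exclusion radius around the phaseless point for the Delta-psi
        least-squares solve.  Defaults to 0 for the canonical linear model
        (whose analytic Delta-psi seeds the solver) and 10 grid cells
        otherwise (the finite-difference noise-drag term is unreliable in
        a ring around the phaseless point, not just at its centre).
    n_eigs : int
        Size of the low-lying Arnoldi window.
    """

    def __init__(self, model: LangevinModel, grid: RectGrid | None = None,
                 r_min: float | None = None, n_eigs: int = 20):
        self.model = model
        self.grid = grid if grid is not None else make_grid(model.domain, 120, 120)
        if tuple(self.grid.bounds) != tuple(map(float, model.domain)):
            raise ValueError("grid bounds do not match the model domain")
        self.n_eigs = n_eigs
        self.r_min = r_min

    @classmethod
    def from_name(cls, name, grid=None, N=120, M=120, r_min=None, n_eigs=20,
                  **params):
        model = make_model(name, **params)
        if grid is None:
            grid = make_grid(model.domain, N, M)
        return cls(model, grid, r_min=r_min, n_eigs=n_eigs)

    def _default_r_min(self) -> float:
        if self.model.canonical_oup is not None and \
                np.allclose(self.model.canonical_oup.transform, np.eye(2)):
            return 0.0
        return 10.0 * max(self.grid.dx, self.grid.dy)

    def fit(self, seed: int = 0, compute_delta_psi: bool = True
            ) -> "PhaseReductionResult":
        """Run the full operator pipeline and return the fitted result."""
        model, grid = self.model, self.grid
        bwd = assemble_backward(model, grid)
        fwd = assemble_forward(model, grid)

        q_mode = leading_complex_mode(bwd, k=self.n_eigs, seed=seed)
        sigma = floquet_mode(bwd, k=self.n_eigs, seed=seed)
        p0 = stationary_density(fwd, k=6, seed=seed)

        psi_raw = amplitude_phase(q_mode)
        anchor = zero_phase_anchor(sigma)
        psi = align_zero_phase(psi_raw, anchor)

        current = probability_current(p0, model, grid)
        period = mean_period(current, psi.phaseless, grid, ray="+x")

        mu = q_mode.info["mu"]
        omega = q_mode.info["omega"]
        delta_omega = 2 * math.pi / period.T_bar - omega

        dpsi = None
        theta = None
        if compute_delta_psi:
            r_min = self.r_min if self.r_min is not None else self._default_r_min()
            seed_field = None
            oup = model.canonical_oup
            if oup is not None and np.allclose(oup.transform, np.eye(2)):
                X, Y = grid.meshes()
                # dodge an exact origin node (odd grids): the seed only needs
                # to be accurate away from the phaseless point anyway
                Xs = np.where((X ** 2 + Y ** 2) == 0, 0.5 * grid.dx, X)
                seed_field = oup_delta_psi(np.stack([Xs, Y], axis=-1), oup)
                seed_field = seed_field - seed_field[
                    np.argmin(np.abs(grid.x - anchor[0])),
                    np.argmin(np.abs(grid.y - anchor[1]))]
            if seed_field is not None:
                # canonical linear model: gradient-form drag with the
                # analytic seed, no exclusion needed
                om_field = omega_term(q_mode, model)
            else:
                # operator-consistent drag: Theta then satisfies the
                # discrete MRT equation on the retained rows
                om_field = omega_term_operator(q_mode, bwd)
            dpsi = solve_delta_psi(bwd, om_field, delta_omega, r_min,
                                   psi.phaseless, anchor,
                                   seed_field=seed_field)
            theta = mrt_phase(psi, dpsi)

        return PhaseReductionResult(
            oscillator=self, model=model, grid=grid, backward=bwd, forward=fwd,
            q_mode=q_mode, sigma_mode=sigma, p0=p0, psi=psi, theta=theta,
            delta_psi=dpsi, current=current, period=period, anchor=anchor,
            mu=mu, omega=omega, lambda_floq=float(sigma.eigenvalue.real),
            delta_omega=delta_omega, seed=seed)


@dataclass
class PhaseReductionResult:
    """Fitted phase reduction of a planar stochastic oscillator."""

    oscillator: StochasticOscillator
    model: LangevinModel
    grid: RectGrid
    backward: object
    forward: object
    q_mode: SpectralMode
    sigma_mode: SpectralMode
    p0: SpectralMode
    psi: PhaseField
    theta: PhaseField | None
    delta_psi: DeltaPsiSolution | None
    current: CurrentField
    period: MeanPeriodResult
    anchor: tuple
    mu: float
    omega: float
    lambda_floq: float
    delta_omega: float
    seed: int
    _interp_cache: dict = field(default_factory=dict, repr=False)

    # -- derived quantities -------------------------------------------------
    @property
    def lambda1(self) -> complex:
        return complex(self.mu, self.omega)

    @property
    def T_bar(self) -> float:
        return self.period.T_bar

    @property
    def T_omega(self) -> float:
        """Oscillation period 2*pi/omega of the slowest complex mode."""
        return 2 * math.pi / self.omega

    @property
    def quality_factor(self) -> float:
        return abs(self.omega / self.mu)

    @property
    def phaseless(self) -> tuple:
        return self.psi.phaseless

    def phase_map(self, which="theta"):
        """Continuous (spline) interpolant of psi or Theta."""
        if which not in self._interp_cache:
            fld = self._field(which)
            self._interp_cache[which] = phase_interpolant(self.grid, fld)
        return self._interp_cache[which]

    def _field(self, which) -> PhaseField:
        if which == "psi":
            return self.psi
        if which == "theta":
            if self.theta is None:
                raise ValueError("Theta was not computed (compute_delta_psi=False)")
            return self.theta
        raise ValueError(f"unknown phase field {which!r}")

    # -- Monte-Carlo checks ---------------------------------------------------
    def mrt_check(self, which="theta", isochron_level=0.0, k_points=3,
                  n=10_000, dt=1e-3, seed=None, tolerance=0.01, r_min=None,
                  horizon=None):
        """Monte-Carlo MRT-property check along one isochron of psi or Theta.

        ``r_min`` controls the start-point placement (minimum distance from
        the phaseless point; defaults to the Delta-psi exclusion radius)."""
        fld = self._field(which)
        if r_min is None:
            r_min = self.delta_psi.r_min if self.delta_psi is not None else 0.0
        return mrt_uniformity(
            self.phase_map(which), isochron_level, k_points, self.model,
            n=n, dt=dt, seed=self.seed if seed is None else seed,
            T_bar=self.T_bar, horizon=horizon, phase=fld, r_min=r_min,
            tolerance=tolerance, label=f"{self.model.name}:{which}")

    # -- reporting ------------------------------------------------------------
    def to_manifest(self) -> dict:
        man = {
            "software": {"package": "stochphase", "version": __version__},
            "model": {"name": self.model.name,
                      "boundary_flavor": self.model.boundary_flavor,
                      "params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                                 for k, v in self.model.params.items()}},
            "grid": self.grid.to_json_dict(),
            "seed": self.seed,
            "eigenvalues": {
                "lambda1": [self.mu, self.omega],
                "lambda_floq": self.lambda_floq,
                "quality_factor": self.quality_factor,
                "gap_ok": bool(self.q_mode.info["gap_ok"]),
            },
            "periods": {"T_bar": self.T_bar, "two_pi_over_omega": self.T_omega,
                        "delta_omega": self.delta_omega,
                        "orientation": self.period.orientation},
            "phaseless_point": list(map(float, self.phaseless)),
            "anchor": list(map(float, self.anchor)),
        }
        if self.delta_psi is not None:
            man["delta_psi"] = {"r_min": self.delta_psi.r_min,
                                "residual_max": self.delta_psi.residual_max,
                                "residual_rms": self.delta_psi.residual_rms,
                                "converged": self.delta_psi.converged,
                                "method": self.delta_psi.info["method"]}
        return man

    def summary(self) -> str:
        """Human-readable summary of the fitted phase reduction."""
        lines = [
            "Stochastic oscillator phase reduction",
            "=" * 53,
            f"model: {self.model.name:<24s} grid: {self.grid.N} x {self.grid.M}",
            f"domain: [{self.grid.bounds[0]:.4g}, {self.grid.bounds[1]:.4g}] x "
            f"[{self.grid.bounds[2]:.4g}, {self.grid.bounds[3]:.4g}]"
            f"   boundary: {self.model.boundary_flavor}",
            "-" * 53,
            f"lambda_1 (mu + i omega)   {self.mu:+.4f} {self.omega:+.4f}i",
            f"lambda_Floq               {self.lambda_floq:+.4f}",
            f"quality factor |omega/mu| {self.quality_factor:8.3f}"
            f"   spectral gap ok: {self.q_mode.info['gap_ok']}",
            "-" * 53,
            f"mean period T_bar         {self.T_bar:8.4f}",
            f"2*pi/omega                {self.T_omega:8.4f}",
            f"Delta_omega               {self.delta_omega:+8.5f}",
            f"rotation orientation      {'+1 (ccw)' if self.period.orientation > 0 else '-1 (cw)'}",
            f"phaseless point           ({self.phaseless[0]:+.4f}, {self.phaseless[1]:+.4f})",
            f"zero-phase anchor         ({self.anchor[0]:+.4f}, {self.anchor[1]:+.4f})",
        ]
        if self.delta_psi is not None:
            lines += [
                "-" * 53,
                f"Delta-psi r_min           {self.delta_psi.r_min:8.4f}",
                f"Delta-psi max residual    {self.delta_psi.residual_max:8.2e}",
                f"Delta-psi rms residual    {self.delta_psi.residual_rms:8.2e}",
            ]
        return "\n".join(lines)

    def save(self, outdir, grids=True):
        """Write the run manifest (JSON) and the field grids (delimited text)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.to_manifest(), fh, indent=2)
        if grids:
            np.savetxt(outdir / "psi.txt", self.psi.values)
            np.savetxt(outdir / "u.txt", self.psi.amplitude)
            np.savetxt(outdir / "P0.txt", self.p0.values)
            np.savetxt(outdir / "sigma.txt", self.sigma_mode.values)
            if self.theta is not None:
                np.savetxt(outdir / "theta.txt", self.theta.values)
                np.savetxt(outdir / "delta_psi.txt", self.delta_psi.values)
        return outdir / "manifest.json"
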