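# Methods

This note records the model, the numerical choices and their rationale, at
the level of detail a maintainer or a careful user needs.  Nothing here is
an empirical claim beyond what the test suite and `scripts/acceptance.py`
compute.

## Model and assumptions

The object of study is the planar Itô diffusion dX/dt = f(X) + g(X)ξ(t)
with diffusion matrix G = ½ggᵀ, assumed *robustly oscillatory*: the
nontrivial eigenvalue of the generator L⁺ with least negative real part,
λ₁ = μ + iω, is complex and simple, every other nontrivial eigenvalue λ′
satisfies Re λ′ < 2μ, and the quality factor |ω/μ| is large.  G must be
nondegenerate on the domain (all packaged models use constant, additive
noise; the API accepts state-dependent g in the Itô convention, but the
Monte-Carlo kernels and some analytics then need a user-supplied noise
factor).

Two phase functions are computed on one scaffold:

* ψ(x) = arg Q*₁(x), with amplitude u = |Q*₁|; phaseless set where u = 0;
* Θ(x) = ψ + Δψ with L⁺Δψ = Ω + Δω, Ω = 2ΣG_ij ∂ᵢln u ∂ⱼψ,
  Δω = 2π/T̄ − ω, so that L⁺Θ = 2π/T̄ (the mean–return-time property).

The theory behind the MRT phase is formulated on an annulus with
reflecting outer/inner boundaries; following the observation that a full
simply-connected rectangle yields numerically indistinguishable isochrons
while the phaseless point localizes itself to within a grid spacing, the
implementation always uses the full rectangle.

## Discretization

* Grid: N×M nodes spanning the rectangle inclusive of both endpoints,
  spacing Δx = (x₊−x₋)/(N−1); production resolution 120×120.  Quadrature is
  trapezoidal (matches the second-order interior stencils).
* Backward operator, `one_sided` flavour (unbounded systems truncated to a
  box): centred second-order differences in the interior; at the border,
  second-order one-sided first derivatives and first-order one-sided second
  derivatives, which keeps constants an *exact* null vector.  The cross
  term uses the 4-corner centred stencil, degrading to one-sided corners at
  the border.
* Forward operator: always a conservative finite-volume scheme — fluxes
  f P − ∇·(G P) on cell faces, zero flux through boundary faces — so the
  quadrature-weighted column sums vanish to rounding and probability is
  conserved exactly.  The stationary current uses the node-based convention
  J_i = f_i P₀ − Σⱼ∂ⱼ(G_ij P₀), i.e. no ½ in front of the diffusive term;
  this is the convention under which the linear-model closed forms and the
  discrete operator agree.
* Backward operator, `reflecting_adjoint` flavour (heteroclinic square):
  the exact transpose of the conservative forward operator in the
  quadrature inner product, which guarantees discrete duality and the
  constant kernel simultaneously.
* Eigenpairs: shift-invert Arnoldi (ARPACK) with a single factorization at
  a shift just above zero captures the whole low-lying window (stationary
  mode, λ₁ pair, the slowest real mode λ_Floq) in one k≈20 solve.  The
  start vector is seeded for reproducibility.  The stationary eigenvector
  of the non-monotone second-order forward scheme can undershoot zero at
  the ~1e-6..1e-4-of-max level along steep density ridges (high cell
  Peclet number, e.g. the Van der Pol crater rim); undershoots are clipped
  after a tolerance check (default 1e-3 of max) and the achieved value is
  recorded.

## Linear-model closed forms

For the canonical spiral sink (A = [[μ,−ω],[ω,μ]],
G = ε[[1+β_D, β_c],[β_c, 1−β_D]]) the package provides the stationary
covariance εΠ, its determinant, the stationary current, the drag term
Ω(x), the phase difference Δψ(x), and the mean period

T̄ = (2π/ω)·√((ω² + μ²(1−β_c²−β_D²)) / (μ² + ω²)).

Two remarks a user comparing against the literature should know:

* Π is the solution of the Lyapunov equation A(εΠ) + (εΠ)Aᵀ + 2G = 0; the
  off-diagonal entry is Π₁₂ = (β_Dω − β_cμ)/(μ²+ω²).  Printed variants of
  this covariance with the opposite off-diagonal sign do not solve the
  Lyapunov equation.
* The T̄ above follows from 1/T̄ = ω/(2π|μ|√det Π) (the ray-flux integral of
  the stationary Gaussian current, verified symbolically); a widely quoted
  variant without the square root differs by ≈0.5% at the packaged
  parameters and is inconsistent with the flux integral.
* The closed-form Δψ(x, y) = ε(γ(x²−y²) + 2αxy)/((ω²+μ²)r⁴) solves
  L⁺Δψ = Ω with an O(ε²/r⁴) residual (shown symbolically); it is the
  quadrupolar part of the solution and the solver's initial seed.  The full
  bounded-domain solution adds a shallow, nearly axisymmetric radial
  component ≈ (Δω/μ)·ln r driven by the constant Δω forcing; comparisons
  with the closed form are therefore made on angular profiles.

## The canonicalization convention

`oup_canonicalize` uses the eigenvector of A for μ + iω scaled to first
component 1.  Only μ, ω, β_c²+β_D² and T̄ are invariant under admissible
eigenvector normalizations; the individual (ε, β_D, β_c) are
convention-dependent, so alternative printed triples with the same
invariants describe the same oscillator.

## Packaged models

| model | drift | noise | domain | boundary |
|---|---|---|---|---|
| spiral_sink | A x (canonical: μ=−0.0796, ω=0.564, ε=0.0046, β_D=−0.74, β_c=0.11; or any A, B) | additive | [−1.5,1.5]² | one_sided |
| wilson_cowan | −E+Sₑ(c₁E−c₂I+P), −I+Sᵢ(c₃E−c₄I+Q); logistic S | diag(0.1, 0.05) | [−0.3,1]×[−0.1,0.9] | one_sided |
| van_der_pol | −y+x−x³, x | √(2·0.1)·diag(1, 0.1) | [−2.5,2.5]² | one_sided |
| heteroclinic | cos x sin y + α sin 2x, −sin x cos y + α sin 2y; α=0.1 | √(2D)·I, D∈{0.01125, 0.1} | [−π/2,π/2]² | reflecting_adjoint |

Wilson–Cowan parameters are (c₁..c₄, aₑ, aᵢ, θₑ, θᵢ, P, Q) =
(13, 12, 6, **3**, 1.3, 2, 4, 1.5, 2.5, 0).  The value c₄ = 3 is the one
that defines the reported oscillator: it reproduces the deterministic
period 5.26, the leading eigenvalue −0.435 + 1.049i, the mean period ≈5.75
and the quotient |μ/ω| ≈ 0.415 simultaneously, whereas c₄ = 4 (which
appears in some listings of this parameter set) yields a different
oscillator (period 5.17, ω = 0.974) inconsistent with all of those
quantities.  c₄ remains a user-settable parameter.

## Mean period

T̄ is the reciprocal ray flux of the stationary current: trapezoidal
integration of J₀,y along the grid row nearest the phaseless point, from
the (sub-grid refined) phaseless abscissa to x₊, with the partial first
segment handled by linear interpolation.  The four axis-aligned rays agree
to <1% for every packaged model (divergence-free current), and the flux
sign gives the rotation orientation.  The phaseless point itself is the
argmin of u refined by a quadratic fit of u² on a 5×5 patch.

## Zero-phase anchor

Both phases are pinned to zero at the maximal-x point of the zero level
set of the slowest real eigenmode Σ (the "stochastic limit cycle"), found
by sign-change scanning of grid edges with linear interpolation.  Using
one anchor for ψ and Θ makes the two fields directly comparable.

## The Δψ solve

Rows of the discrete L⁺ at nodes outside an exclusion disc of radius
r_min around the phaseless point, plus one unit gauge row pinning the
anchor node (constants span the kernel), plus — when r_min > 0 —
low-weight discrete-Laplace rows over the excluded nodes that determine
the disc interior by smooth (harmonic) extrapolation without competing
with the physical rows.  The system is solved by LSQR (when the analytic
seed is available: linear models, r_min = 0) or by the sparse normal
equations, with an automatic direct polish if the iterative residual
misses the 1e-2 contract; residual statistics are reported over the nodes
whose stencils do not touch the extrapolated disc.

The forcing Ω is available in two forms: the gradient form
2ΣG_ij Re(∂ᵢQ/Q)·Im(∂ⱼQ/Q) (branch-cut free, matches the closed form for
the linear model to ~2% on the annulus), and the operator-consistent form
Ω = ω − L⁺[ψ] evaluated by a row-local unwrapped application of the
assembled operator.  The pipeline uses the operator form for the nonlinear
models — the resulting Θ then satisfies the *discrete* MRT equation
L⁺Θ = 2π/T̄ on the retained rows essentially exactly — and the gradient
form with the analytic seed for the canonical linear model.  The two forms
agree to O(h²) away from the phaseless set (property-tested).

Defaults: r_min = 0 for the canonical linear model; 10 grid cells
otherwise, because the finite-difference drag term is unreliable in a ring
around the phaseless point, not merely at its centre (with a 5-cell disc
the Wilson–Cowan Δψ range inflates visibly and the Monte-Carlo return
times shift by several percent).

## Monte-Carlo MRT verification

Euler–Heun integration (Heun on the drift, plain Gaussian increment —
identical to Euler–Maruyama for additive noise), dt = 1e-3, horizon
3T̄, reflecting walls for the heteroclinic square; numba-compiled kernels
with bilinear interpolation of cos Θ, sin Θ (an O(h²) difference from the
bicubic public interpolant, far below Monte-Carlo error).  The phase along
a path is unwrapped incrementally assuming per-step increments below π
(monitored; violations are counted).  Default ensemble n = 10⁴ per start
point; the study-scale n = 10⁵ is a parameter away.

Start points for a uniformity check are taken on the isochron at
quantiles 0.1–0.9 of the distance from the phaseless point, keeping a
margin from the border.  The verdict is pairwise:
|mᵢ − mⱼ| ≤ 1%·grand-mean + 3√(SEᵢ²+SEⱼ²); consistency of the grand mean
with T̄ allows the same 1% (the operator estimate itself carries ~1% grid
dependence) plus 3 SE.  Return-time distributions of the less coherent
oscillators genuinely place 0.1–0.5% of their mass beyond 3T̄ (verified by
extending the horizon on an exactly solvable isotropic control at matched
quality factor), so up to 1% non-returning paths are tolerated, reported,
and bounded in effect (censoring bias < frac·2T̄).  At low noise the
heteroclinic oscillator's inner region has heavy-tailed, slow first
rotations; its consistency check samples at distance ≥0.5 from the
centre.

## What the tests do and do not show

The packaged models *are* the study conditions; the suite reproduces the
printed spectra, periods and MRT-property outcomes at the printed grid
and parameters (scaled-down Monte Carlo, n = 10⁴).  Passing tests show
the operator pipeline and the pathwise simulations agree at the 1–2%
level for these four planar, additive-noise systems; they do not exercise
state-dependent noise, dimensions above two, or systems whose low-lying
spectrum is not discrete and well separated.  One table value is knowingly
not reproduced: the Wilson–Cowan λ_Floq converges to −0.883 under grid
refinement (with μ, ω from the very same solve matching the table
exactly); the package reports its converged value.

## Known limitations

* Second-order non-monotone schemes undershoot on steep density ridges;
  P₀ is clipped (tolerance-checked) rather than computed with a positivity-
  preserving scheme.
* Θ within ~r_min of the phaseless point comes from smooth extrapolation,
  not from the PDE; isochrons there are only trustworthy to the grid
  spacing, mirroring the self-localization of the phaseless point.
* The mean-return-time measurement is a first-passage statistic; at low
  quality factor its distribution is broad, so horizon and censoring
  handling matter (see above) and SEs should always be read together with
  the non-return fractions.
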