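# Methods

## Transport model

The forward model is the 1D unsteady advection-diffusion equation on
`0 < x < d` with Dirichlet boundaries: `∂C/∂t = D ∂²C/∂x² − u ∂C/∂x`,
`C(0,t) = Cs(t)`, `C(d,t) = Cb(t)`, `C(x,t₀) = C₀(x)`. Assumptions: the
solute is conserved (no binding, uptake or degradation over the imaging
window), D and u are uniform across the gel, transverse variation is
negligible (the channel is much longer than it is wide), and fluorescence
intensity is proportional to concentration, so all intensities are in
arbitrary units.

### Discretization

* Uniform grid of `n_nodes` (default 101) on `[0, d]`; central second
  differences for the diffusive term.
* Second-order upwind differences for the advective term. The first
  interior node downstream of the inflow boundary lacks a second upstream
  node; there the scheme falls back to first-order upwinding. A local
  first-order truncation at a single node leaves the global error second
  order, which the convergence tests confirm (observed spatial order ≈ 2.0
  against the closed-form steady state `C = c₀ + (c_d − c₀)(e^{ux/D} − 1)/
  (e^{ud/D} − 1)`).
* Advection is normally non-negative (source → buffer); for `u < 0` the
  stencil mirrors, with the fallback at the opposite boundary.
* Implicit Euler time stepping (first order, unconditionally stable;
  observed temporal order ≈ 1.0 against the sinusoidal modal-decay
  solution). Default time step: the observation interval divided by 60
  substeps.
* Each step solves a pentadiagonal system. Within one observation window
  the matrix is constant, so it is LU-factored once with partial pivoting
  (LAPACK `dgbtrf`) and reused for every substep (`dgbtrs`) — the MCMC hot
  path evaluates one forward solve per proposal, ~0.4 ms at default
  resolution. Factorization failure raises; it is never converted into a
  silent likelihood value.

Default resolution rationale: at the targeted parameter scales
(D ~ 5·10⁻⁵ mm²/s, windows of 30–120 s) the implicit-Euler rate bias is
~0.1% and the spatial error far below the ~1% measurement noise, verified
by the convergence tests. Both knobs are configurable.

## Measured initial and boundary conditions

The first measured profile becomes `C₀(x)` by piecewise linear
interpolation (exact at every anchor; extrapolation outside the measured
span is an error). The boundary-adjacent intensity time series become
`Cs(t)`, `Cb(t)` by ordinary least-squares polynomial fits. Fits are
computed in normalized time (`numpy.polynomial.Polynomial.fit`, domain
mapped to [−1, 1]) because a degree-7 Vandermonde system over thousands of
seconds is severely ill-conditioned in raw time; both normalized and
re-expanded raw coefficients are reported.

Degree selection: an explicit degree per side can be pinned in the
configuration. The default `auto` rule picks the smallest degree whose RMS
residual relative to the series' value range falls below `bc_rel_tol`
(default 0.02), or at which raising the degree improves that relative RMS
by less than the same tolerance (a plateau), capped at `bc_max_degree`
(default 10). The rule is a deterministic stand-in for a qualitative
"lowest adequate degree" judgement; determinism matters more here than
the exact threshold, since the sequential results must be reproducible.

If a dataset carries no recorded boundary series, the first/last profile
columns are used as a fallback, with a warning.

## Noise model and likelihood

Observed profiles are `C̄(xᵢ, t) = C(xᵢ, t) + εᵢ`, `εᵢ ~ N(0, σ²)` i.i.d.
across positions and times, giving the Gaussian log-likelihood
`−N/2·log(2πσ²) − Σᵢ rᵢ²/(2σ²)`. Intensities are normalized to a
dataset-wide maximum of 1 before inference so that σ is commensurate with
its HalfNormal(1) prior; the scale is recorded and σ is convertible back
to raw units by multiplication.

## Priors and sequential updating

* Step 1: `D ~ U(0,1)` mm²/s, `u ~ U(0,1)` mm/s, `σ ~ HalfNormal(1)`.
  The uniform bounds are wide: physical values are ~10⁻⁵–10⁻⁴.
* Step n ≥ 2: `D ~ Γ(α, β)` moment-matched to step n−1's diffusivity
  posterior (`α = m²/v`, `β = m/v` from the posterior sample mean and
  variance); `u ~ U(0,1)` again; `σ ~ HalfNormal(1)` again (imaging noise
  treated as independent per frame).
* `dextranI` variant: for steps `2 ≤ n ≤ u_propagation_last_step`
  (default 6), `u` is also gamma-propagated from the previous posterior;
  from step 7 on it reverts to `U(0,1)`. The flag exists because a single
  early window may not separate D from u; temporarily carrying the
  advection posterior forward stabilizes both.
* If a posterior variance is numerically degenerate (below
  `(10⁻³·mean)²`), the propagated gamma's variance is floored there, with
  a warning, to avoid a Dirac-like prior.

Initial conditions propagate through the model rather than the data: step
n ≥ 2 starts from `C(x, t_{n−1})` computed at step n−1's posterior
*medians* (medians, not means, to be robust to skewed posteriors). Each
step's likelihood uses only the profile at its own observation time, with
the forward model integrated over `[t_{n−1}, t_n]`.

## MCMC

Random-walk Metropolis–Hastings, one joint 3-D Gaussian proposal per
iteration with independent per-parameter scales. Defaults: 20,000
iterations, 5,000 burn-in, no thinning (all configurable; the scaled-down
test runs use 10,000/2,500). During burn-in only, the proposal adapts in
the diagonal adaptive-Metropolis style: every 50 iterations the global
scale factor steps up/down by 1.7× when the block acceptance leaves
[0.2, 0.5], and the per-parameter relative scales are refreshed from the
recent chain's standard deviations with the classic `2.4/√dim` prefactor.
Adaptation is frozen after burn-in, so the retained draws come from a
valid time-homogeneous chain. Chains are bit-reproducible for a fixed
seed; per-step seeds derive from the run seed via `numpy.random.
SeedSequence`.

Chain initialization: the posterior in D is severely multiscale — every
diffusivity large enough to equilibrate the window (`D ≫ d²/Δt`) produces
the same near-steady profile, so the likelihood is flat over most of
`U(0,1)` and a chain started there can stall with σ inflated to absorb the
misfit. Step 1 therefore starts from a deterministic coarse scan: a
25-point log-spaced D grid crossed with 9 advection magnitudes, σ set to
the residual RMS (its conditional maximum-likelihood value), best
log-posterior wins. Later steps start at the previous posterior medians
with proposal scales set from the previous posterior standard deviations.

Summaries: mean, median, sd, and the 95% HPD interval computed by the
sorted-window search (shortest contiguous window containing ⌈0.95·n⌉
sorted draws; ties break toward the lower start) — exact for unimodal
samples and never wider than the equal-tailed interval. Diagnostics per
parameter: effective sample size from the autocorrelation sum truncated at
the first non-positive consecutive pair (capped at n; a constant chain is
flagged degenerate and reported at n), lag-k autocorrelations, and the
first-half/second-half mean discrepancy in units of the chain sd.

The sampler was validated two ways: against known closed-form targets
(standard normal, Γ(4,2)), and against brute-force 3-D grid quadrature of
the identical unnormalized posterior on a fixed 21-node single-window
instance, where the two routes' posterior medians for (D, u, σ) agree to
well within 5% (observed ≲ 0.3%).

## Synthetic data generator

Emulates the measurement, not the optics: a source intensity rising as
`A(1 − e^{−t/τ})` (A = 100 a.u., τ = 300 s — fluorescence starts at zero
and saturates as the supply equilibrates), a low buffer with slow linear
drift (2 a.u. + 5·10⁻⁴/s), profiles sampled at 100 positions, boundary
series sampled 8× denser than the profile interval, and i.i.d. Gaussian
noise with σ = 1% of the source plateau added to profiles and boundary
series. Three named scenarios mirror the experimental designs
(`dextranI-like`: 0.91 mm, t₀ = 120 s, every 120 s to 2640 s, D = 5·10⁻⁵;
`dextranII-like`: same channel to 1440 s; `ccl19-like`: 0.496 mm,
t₀ = 0, every 30 s to 120 s, D = 1.3·10⁻⁵; advection 1–2·10⁻⁴ mm/s).

To keep recovery tests non-circular at the discretization level, the
generator integrates on a 4× finer grid and 4× smaller time step than the
inference default, starting from a fluorescence-free state at t = 0.
What the generator does *not* emulate — photobleaching, point-spread blur,
gel heterogeneity, pressure-transient advection fluctuations — bounds what
passing recovery tests can say about real data: they demonstrate the
estimator is correct and well calibrated when the transport model holds,
not that the model captures every imaging artifact.

Test problem sizes were chosen to keep the full suite at desk scale: the
sequential-recovery study uses the dextranI-like scenario truncated to 10
observation steps with 10,000 MCMC iterations per step over 5 independent
seeds, and the quadrature cross-check uses a 21-node grid with a
100×100×60 parameter grid.

## Numerical details and edge cases

* Output times in `simulate` snap to the nearest internal step (within
  dt/2); times outside the window, or outside a boundary function's
  validity interval, raise with the offending time named.
* `σ = 0` is rejected in the likelihood (degenerate); points outside the
  prior support get log-posterior −∞ without invoking the solver; solver
  failures propagate as exceptions, never as −∞.
* Boundary rows of the implicit system are identity rows, so the solver
  honours the prescribed boundary values to machine precision at every
  step, and a spatially constant state with equal boundaries is invariant
  for any (D, u, dt).
* Waveform values below zero are clipped at zero with a warning
  (fluorescence is non-negative); additive noise is not clipped, matching
  the Gaussian error model.
* The Péclet number `u·d/D` summarizes the transport regime; at the
  parameters the device is designed for it is below 1 (diffusion
  dominated).

## Known limitations

* Single-chain inference; no multi-chain R-hat.
* The advection prior's upper bound (1 mm/s) and the intensity
  normalization convention are package choices where conventions were
  open; both are configurable.
* The gamma moment-match preserves only two moments of the propagated
  posterior; heavy skew beyond gamma shape is lost between steps.
* No spline boundary fitting; a poor polynomial boundary fit degrades the
  step likelihoods it feeds (visible as inflated σ estimates at the
  affected steps).
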