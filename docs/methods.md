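# Methods

## Model and assumptions

The labelled-cell density ρ(x, t) along the proximo-distal (PD) axis is
treated as a continuum (cell diameters are ~10⁻³ of the limb length)
and evolves by

    ∂ρ/∂t = r ρ + D ∂²ρ/∂x² − ∂(v_a ρ)/∂x + ∂(v_p ρ)/∂x,   v_a = a·x,

on x ∈ [0, L(t)], L(t) = L₀ e^{at}, with zero-flux boundaries. The
assumptions this encodes:

- proliferation is first-order (area under the profile grows as e^{rt});
- spreading is Fickian with a constant, condition-specific D;
- host-tissue expansion is spatially uniform exponential growth, giving
  the linear advection field v_a = a·x;
- proximalisation acts as a *constant* drift v_p toward x = 0. This is
  a deliberate minimal choice: v_p may in reality vary with stage,
  position and cell, and the estimate is then an average over all
  three. Constant v_p is equivalent to a linear proximalisation
  potential (constant force at constant mobility) or to chemotaxis with
  a spatially uniform attractant gradient (`rda.interpret_velocity`
  makes these conversions explicit).

Observations are modelled as the density plus additive i.i.d. Normal
noise of scale σ. Measured densities are normalized pixel counts and
cannot be negative, so the synthetic generator clips noisy values at 0
by default; the unclipped variant (`clip_noise=False`) is the pure
additive model, under which the Gaussian likelihood used in inference
is exactly specified. The calibration experiments use the unclipped
variant for that reason.

## Numerics

The PDE is solved in transformed coordinates δ = x/(L₀e^{aθ}) ∈ [0, 1],
θ = t, where it becomes ∂ρ/∂θ = D̃(θ) ∂²ρ/∂δ² + (r − a)ρ + ṽ(θ) ∂ρ/∂δ
with D̃ = D/(L₀e^{aθ})², ṽ = v_p/(L₀e^{aθ}). A conservative upwind
scheme advances cell-centred node values: the total flux is written as
ρ·G with G = −D̃/ρ·∂ρ/∂δ − ṽ, interface G is the mean of the adjacent
node values, and the upwind side is chosen by its sign; the reaction
term (r − a)ρ is added as an explicit source within the same step
(tested against Lie operator splitting: < 0.5 % difference over a day
at the default step). Zero interface flux at δ = 0, 1 implements the
Neumann boundaries and makes transformed-frame mass conservation exact
in the absence of sources.

Numerical choices worth knowing:

- **Density floor.** G divides by ρ; nodes are floored at 10⁻¹²·max(ρ)
  for the G evaluation only. The floor is *relative*, so the scheme is
  exactly linear in the initial condition (a property the tests assert
  at 10⁻¹² relative tolerance).
- **Time step.** The nominal step is Δθ = Δδ²/(3 D̃₀) with D̃₀ the
  transformed diffusivity at θ = 0 (the largest over time, since the
  domain only grows), further bounded by 0.9·Δδ/(2ṽ₀) and 0.1/|r − a|.
  At every step the CFL number 2·max|G|·Δθ/Δδ is evaluated on
  flux-carrying interfaces (upwind density > 0) and the step is
  shortened to keep it below 1 with a 0.9 safety factor. This
  adaptivity matters for measured or noisy initial conditions, where
  clipped zeros adjacent to signal make |G| transiently large; the
  step recovers within a short transient as diffusion smooths the
  cliff. A step collapse below 10⁻¹³ days aborts with a diagnostic.
- **Positivity.** Under the CFL bound the update may still produce
  negative values at round-off scale; values in (−10⁻⁹·max, 0) are
  clipped to 0 and anything more negative aborts.
- **Batched solver.** Grid inference, ABC and Sobol analysis evaluate
  thousands of forward runs from one shared initial condition; these go
  through a numba-jitted per-run loop (`_kernel.batch_evolve`) with
  numerics identical to the reference path (asserted to 10⁻¹⁰ in the
  tests).
- **IC interpolation.** Lab-frame initial profiles are linearly
  interpolated onto the δ-grid and rescaled to preserve their integral.

Defaults: n₀ = 200 nodes (Δδ = 1/n₀). Grid convergence: halving Δδ
changes the 24-day profile by < 2 % in L¹ at the reference parameter
sets.

## Inference

The posterior over (ṽ, D̃, σ) — transformed units ṽ = v_p/L₀,
D̃ = D/L₀², both day⁻¹ — is discretized on an N³ grid (default
N = 100) with independent uniform priors, default bounds
ṽ ∈ (5·10⁻⁴, 5·10⁻²), D̃ ∈ (5·10⁻⁵, 5·10⁻³), σ ∈ (10⁻⁴, 10⁻²). The
measured profile at the first timepoint is the forward model's initial
condition; each later timepoint multiplies the current posterior by the
Gaussian likelihood and renormalizes via log-sum-exp (batch and
sequential processing coincide exactly in log space). Since the
forward model depends only on (ṽ, D̃), the N³ grid costs N²
simulations, cached once. Marginals are sums over the other two axes;
reported summaries are the marginal mean ± 2 sd. Spline smoothing, if
used, is cosmetic (plots only) and never feeds reported numbers.
Lab-unit conversion (μm/day, μm²/day) multiplies by L₀ and L₀²
respectively and is explicit in `ProximalisationResults`.

Replicates are averaged per timepoint on the δ coordinate before
fitting (condition-mean fitting); per-replicate fitting is possible by
constructing one model per replicate.

**Calibration harness.** `validate_recovery` draws ground truths,
generates noisy series, and checks (i) that the posterior mode lands
within one grid cell of the truth for noiseless data, and (ii) that the
truth falls in mean ± 2 sd for noisy data. Two deliberate design
choices: noisy-case truths are drawn *on* interior grid nodes, so
coverage measures the calibration of the noise model rather than the
grid discretization bias (posterior widths at the lower end of the σ
range are below a cell, so off-grid truths would make the check a
measure of the grid instead); and the first-timepoint profile is left
noiseless, because the inference conditions on it as exact — a noisy IC
propagates extra variance into the residuals and biases σ̂ upward by
~20 %. Mode recovery is checked with continuous (off-grid) truths.

**ABC-SMC.** The likelihood-free route uses the distance
Σ_t Σ_i (y_i − f(x_i))²/σ², uniform priors on (ṽ, D̃), population 100,
at most 20 populations, acceptance threshold floor 0.1. The ε schedule
is the median of the previous population's accepted distances (a
standard choice; the source material does not state one); perturbation
is a component-wise Gaussian kernel with twice the weighted population
variance, and importance weights follow the standard prior/kernel-
mixture ratio computed in log space. With noisy data the distance floor
is ~n (the number of residuals), so runs typically stop at the
population cap rather than at ε ≤ 0.1; the posterior then concentrates
near the distance minimiser, and the check against the grid route is
concordance of means within a fraction of the prior range, not interval
coverage.

## Sensitivity analysis

Sobol first-order (S1) and total-order (ST) indices of the model-data
distance with respect to (D, v_p, r, a), per timepoint at 7, 12, 18,
24 dpe. Sampling is Saltelli's scheme on a scrambled Sobol' sequence
(N(d + 2) runs, N a power of two, default 1024); estimators are
Saltelli-2010 for S1 and Jansen for ST; confidence intervals come from
a bootstrap over sample rows (default 100 resamples). The reference
data are synthetic series generated from the published per-condition
parameter estimates with each condition's own noise scale, and the
default parameter box spans the spread of those estimates across
conditions. Zero-variance outputs are reported as degenerate rather
than invented.

## Synthetic data

`make_profile_series` emulates the study conditions: a distal Gaussian
initial condition at the first timepoint (centre 0.9·L₀, sd 0.05·L₀ —
the electroporated distal blastema compartment; amplitude normalized to
peak 1 like a measured profile), evolved under known parameters, with
additive Normal noise per timepoint. Noise streams are spawned from the
master seed by timepoint index, so extending the series never perturbs
earlier timepoints. Timepoints default to 1, 6, 12, 18, 24 dpe for
inference work and 7, 12, 18, 24 dpe for the sensitivity reference
(matching the respective analyses they emulate).

`make_limb_scene` renders a limb-like image: a quadratic-Bézier PD axis
(interpolating for three control points), a band-shaped ROI of given
half-width, and cells as uniform-intensity disks whose arc positions
are sampled from a supplied density, offset orthogonally within the
band. It returns the exact sampled arc-position histogram as ground
truth. What it does **not** emulate: real tissue texture and
autofluorescence, intensity variation between cells, out-of-focus
light, limb curvature changing over time, or segmentation error in the
ROI — so passing collapse tests demonstrate geometric correctness of
the axis collapse, not robustness to real imaging artefacts.

## Image collapse

At each point of the (1 px arc-length resampled) axis the local tangent
is a central difference over ±2 points (one-sided at the ends); the
orthogonal line is marched in 0.5 px steps both ways until it leaves
the ROI, with a hard cap of twice the ROI-derived half-width estimate
against mask leaks. Pixels are deduplicated within one orthogonal
line; pixels counted by orthogonals of *different* axis points in
concave regions are accepted (the resolution of overlapping orthogonals
is genuinely open; this choice is documented rather than hidden).
"Above threshold" is strictly greater by default (configurable to ≥).
Profiles are normalized to their maximum; x = 0 is the proximal end of
the traced axis, and re-referencing to the amputation-plane landmark is
an explicit, logged operation.

## Problem sizes

Full-size defaults follow the study (n₀ = 200 solver nodes, N = 100
posterior axes, 1024 Sobol base samples). The test suite and the
acceptance script run the package's desk-scale sizes — n₀ = 100,
N = 25–40, 20 recovery cases, 256 Sobol base samples — chosen so the
statistical checks retain power while a full run of every stage
completes in about a minute; all sizes are parameters and scale up
without code changes.

## Known limitations

- v_p is constant in space, time and across cells; systematic
  stage-dependence would be absorbed into the average.
- The upwind scheme is first-order: it adds numerical diffusion of
  order Δδ·|∂ρ/∂δ|·D̃/ρ in steep tails, visible as the ~2 % variance
  excess in the pure-diffusion check at n₀ = 200.
- The grid posterior's resolution floor is one cell; uncertainties
  smaller than a cell are reported as such and should be read as
  "at most one cell".
- Replicate averaging discards between-replicate variability; the
  Student-t intervals for a and r capture it only for the growth rates.
- The anterior-posterior axis is not modelled; profiles are strictly
  one-dimensional along the PD axis.
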