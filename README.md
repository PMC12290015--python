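# proximo

Quantitative analysis of **proximalisation** in regenerating axolotl
limbs: when distal blastema cells overexpress proximal-identity factors
(Prod1, Tig1), they and their progeny drift toward the shoulder instead
of staying in the hand-forming region. `proximo` turns fluorescence
image series of such experiments into cell-density profiles along the
curved proximo-distal (PD) axis, and fits a mechanistic model that
reads the drift off as a single number — the proximalisation velocity.

The package is aimed at quantitative biologists analysing displacement
assays in regenerating tissue, and at modellers who want a tested
reference implementation of inference for advection–diffusion dynamics
on a growing domain.

## The model

The density ρ(x, t) of labelled cells along the PD axis (x = 0
proximal) obeys a reaction–diffusion–advection equation on a domain
growing as L(t) = L₀·e^{at}:

    ∂ρ/∂t = r ρ + D ∂²ρ/∂x² − ∂(v_a ρ)/∂x + ∂(v_p ρ)/∂x,   v_a = a·x

with zero-flux boundaries at x = 0 and x = L(t). Here r is the net
proliferation rate (T_c = ln 2 / r is the mean cell-cycle length), D a
cell diffusion coefficient, v_a the advection due to host-tissue
expansion, and v_p ≥ 0 a constant proximal drift — the proximalisation
velocity. Equivalently, v_p is the velocity induced by a linear
proximalisation potential (constant proximal force at constant
mobility), or by chemotaxis up an attractant gradient that decreases
distally.

The pipeline estimates `a` from limb-length kinetics and `r` from the
growth of the area under the density profiles (exponential fits with
Student-t confidence intervals), then infers (v_p, D, σ) from the
profile time series by sequential Bayesian inference on an N³ parameter
grid — the posterior after each timepoint becomes the prior for the
next — with an additive Gaussian observation model of scale σ.
Numerically, the PDE is mapped to the fixed domain δ = x/L(t) and
solved with a conservative upwind scheme under the CFL condition; the
N³ grid needs only N² simulations, evaluated in a jitted batch.
Likelihood-free ABC sequential Monte Carlo provides an independent
estimate of (v_p, D), and Saltelli/Sobol sensitivity analysis ranks the
four parameters by their contribution to the model-data distance.

## Worked example

Generate a synthetic profile series with known ground truth
(v_p = 12 μm/day, D = 1500 μm²/day, σ = 0.005) and fit it:

```python
from proximo import ProximalisationModel
from proximo.rda import ModelParams, SimGrid
from proximo.synthetic import GroundTruth, make_profile_series

truth = ModelParams(r=0.08, D=1500.0, a=0.092, vp=12.0, L0=1000.0)
gt = GroundTruth(truth, noise_sigma=0.005, seed=1, clip_noise=False)
series = make_profile_series(gt, SimGrid(n0=100), noise_on_ic=False)
res = ProximalisationModel(series, r=0.08, a=0.092, n_grid=40,
                           sim_grid=SimGrid(n0=100)).fit()
print(res.summary())
```

```
         Proximalisation model results
==========================================================
Condition: synthetic        Method: grid
Timepoints (dpe): 1, 6, 12, 18, 24
L0 = 1000.0 μm    n_nodes = 100    N_grid = 40
a = 0.092 day⁻¹    r = 0.08 day⁻¹  (supplied)
----------------------------------------------------------
param           mean          sd   [mean − 2sd mean + 2sd]
v_p            11.92    9.71e-14         11.92       11.92  μm/day
D               1446     0.00146          1446        1446  μm²/day
sigma       0.005204    0.000185      0.004835    0.005573  density
----------------------------------------------------------
```

The posterior mean recovers the true v_p and D to within one grid cell
(the 40-point axes have cells of ≈ 1.3 μm/day and ≈ 127 μm²/day), and
the noise scale σ to within its 2-sd interval. `res.conf_int()`,
`res.simulate()`, `res.plot_fit()` and `res.plot_posterior()` give the
intervals, the posterior-mean forward simulation and diagnostic plots;
`method="abc"` fits the same series by ABC-SMC.

The same stages are exposed on the command line (`proximo synth`,
`collapse`, `fit-growth`, `simulate`, `infer-grid`, `infer-abc`,
`sobol`, `validate`), each reading a JSON/YAML config and writing its
outputs with a JSON run manifest.

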