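# chemograd

Bayesian estimation of solute transport parameters — effective diffusivity
*D*, advection velocity *u*, and measurement noise σ — from time-lapse
fluorescence concentration profiles recorded across the hydrogel channel of
a microfluidic gradient chamber.

Chemokine gradients steer leukocyte migration, and quantifying how a
chemokine (or a fluorescent surrogate such as 10 kDa Dextran) moves through
an interstitial-like collagen gel is a prerequisite for predictive models
of gradient formation. In the measurement setup this package targets, a
fluorescent solute is supplied in a *source* channel, washed away in a
*buffer* (sink) channel, and imaged as it crosses the gel of width *d*
between them. `chemograd` turns those image-derived intensity profiles into
posterior distributions over the transport parameters, with credible
intervals, at every observation time.

## Model

Concentration `C(x, t)` across the channel obeys the 1D unsteady
advection-diffusion equation

    ∂C/∂t = D ∂²C/∂x² − u ∂C/∂x,   0 < x < d,

with a measured initial profile `C(x, t₀) = C₀(x)` and measured
time-varying Dirichlet boundaries `C(0, t) = Cs(t)`, `C(d, t) = Cb(t)`.
Observed profiles are the model solution plus additive i.i.d. Gaussian
noise of standard deviation σ. The equation is solved by finite
differences: central differences for diffusion, second-order upwinding for
advection, implicit Euler in time, one banded LU factorization per
parameter set.

Inference is sequential. At the first observation time the priors are
vague: `D ~ U(0,1)`, `u ~ U(0,1)` (mm²/s, mm/s) and `σ ~ HalfNormal(1)` in
normalized intensity units. At each later time step the diffusivity prior
is the gamma distribution `Γ(α, β)` moment-matched to the previous
diffusivity posterior (`E = α/β`, `Var = α/β²`) — diffusivity is a material
property, so information accrues and its estimate plateaus — while the
advection prior is reset to `U(0,1)` (the velocity drifts with pressure
transients) and the noise prior is reset each frame. A `dextranI` variant
additionally propagates the advection posterior for steps 2–6 to overcome
a transient identifiability problem. Initial conditions for step *n* ≥ 2
are model-based: the forward solution over the previous window at the
previous posterior medians. Posteriors are sampled with an adaptive
random-walk Metropolis–Hastings chain and summarized by mean, median,
standard deviation and 95% highest-posterior-density (HPD) intervals.

A synthetic-data generator reproduces the targeted experimental conditions (channel widths
0.91 / 0.496 mm, sampling every 120 / 30 s, saturating source rise, ~1%
noise) on a 4× finer discretization than the inference default, so the
whole pipeline is testable with known ground truth and no raw imaging
data.

## Worked example

Generate a chemokine-like synthetic experiment (0.496 mm channel, profiles
every 30 s up to 120 s, true D = 1.3·10⁻⁵ mm²/s, u = 10⁻⁴ mm/s, noise 1%
of the source plateau), then run the sequential inference:

```sh
chemograd generate --scenario ccl19-like --seed 7 --out data
printf 'n_iter: 8000\nburn_in: 2000\nseed: 1\n' > config.yaml
chemograd infer --dataset data/dataset.csv --config config.yaml --out results
chemograd summarize --results results --out summary.csv
```

`results/medians.csv` then contains the per-step posterior medians:

```
 time_s        D        u    sigma
   30.0 0.000018 0.000121 0.027009
   60.0 0.000015 0.000088 0.030893
   90.0 0.000014 0.000073 0.028520
  120.0 0.000014 0.000111 0.030713
```

The diffusivity estimate tightens toward the generating value
1.3·10⁻⁵ mm²/s as information accrues — the 95% HPD interval for *D*
narrows from (1.0, 2.8)·10⁻⁵ at 30 s to (1.1, 1.7)·10⁻⁵ at 120 s
(`summary.csv`) — the advection medians scatter around the true
10⁻⁴ mm/s, and σ ≈ 0.03 in normalized units equals the generator's
absolute noise (1.0 intensity unit) divided by the dataset maximum
(~33 units; the normalization scale is recorded in
`results/manifest.yaml`). Per-step posterior draws, gamma moment fits and
MCMC diagnostics (effective sample size, split-half discrepancy,
acceptance rate) are written alongside.

The same machinery is available as a library:

```python
from chemograd import PipelineConfig, run_pipeline
from chemograd.cli_io import normalize_intensities, read_dataset

dataset, scale = normalize_intensities(read_dataset("data/dataset.csv"))
result = run_pipeline(dataset, PipelineConfig(n_iter=8000, burn_in=2000, seed=1))
print(result.median_frame())
```

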