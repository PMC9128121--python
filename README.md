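# bearmove

Hierarchical Bayesian movement and step-selection analysis for irregular,
error-prone satellite telemetry — built around the study design used for
spring polar bears tracked by Argos tags, where adult females (AF), adult
males (AM), and sub-adults (SA) carry different tag types with different
duty cycles, error ellipses, and failure rates.

The package answers two questions at the scale of 4-day steps:

1. **Movement** — do classes differ in step length and directional
   persistence?  Step lengths are Weibull, `l ~ Weib(k_i, g_i)`; bearings
   follow a wrapped Cauchy centred on the previous bearing,
   `θ_t ~ wCauchy(θ_{t-1}, r_i)`, whose concentration `r_i` is the
   directional persistence.  Individual parameters are tied to class-level
   parameters by method-of-moments hyper-distributions, e.g.
   `g_i | c ~ Gamma(γ_c²/σ_γ², γ_c/σ_γ²)`, so class means and
   inter-individual SDs are explicit parameters.  The derived class mean
   step length is `μ_c = γ_c Γ(1 + 1/κ_c)`.
2. **Step selection** — which sea-ice conditions do bears choose?  Each used
   location is compared with 25 *available* locations generated from the
   animal's own fitted movement kernel; the choice probability is a softmax
   of linear scores over eight covariates (depth, ice concentration and its
   square, local concentration SD, distance to land and its square, distance
   to the 10% ice-concentration contour and its square), with individual
   coefficients `α_i ~ Normal(β_c, σ_β)` shrunk toward class coefficients.

Because Argos fixes are irregular and noisy, the chain starts with
deterministic filtering (≥ 5 days post-capture, a 1 March – 30 June window,
one fix per duty cycle by smallest error ellipse, exclusion below 3 fixes),
then fits a continuous-time correlated random walk (CTCRW, an integrated
Ornstein–Uhlenbeck velocity model observed through the error ellipses) per
animal, and draws 25 path realizations on an exact 4-day grid.  Every model
is fit once per imputed dataset and the posteriors are pooled; classes are
compared by 95% credible-interval overlap.  Predictive skill is measured by
case–control cross-validation: 20% of clusters held out, rows ranked by
predicted choice probability, and the used-location rank histogram
correlated with rank order (Spearman ρ).

All samplers are adaptive Metropolis-within-Gibbs written in numpy; a
synthetic-data module generates tracks, Argos-like fixes, and daily
sea-ice/depth rasters with the statistical structure the analysis assumes,
so the whole chain is testable end to end without any external data.

## Worked example

```python
import numpy as np
from bearmove import (
    MCMCConfig, default_class_params, mean_step_length, pool_and_summarize,
    run_movement_mcmc, sample_individual_params, simulate_crw, steps_and_angles,
)

# published class posterior medians -> derived mean step length (meters)
print(round(mean_step_length(1.79, 67_288.0), 1))   # 59854.8 (AF)
print(round(mean_step_length(1.76, 79_025.0), 1))   # 70358.3 (AM)

# simulate 15 animals per class at realistic scales and refit the hierarchy
rng = np.random.default_rng(7)
series = []
for label, cp in default_class_params().items():
    for ind in sample_individual_params(cp, 15, rng):
        series.append(steps_and_angles(simulate_crw(ind, 20, rng=rng)))
cfg = MCMCConfig(adapt=1000, burnin=2000, iters=3000, thin=3)
samples = run_movement_mcmc(series, cfg, np.random.default_rng(11))
summary = pool_and_summarize(samples)
print(summary[summary["class"] == "AF"].round(3).to_string(index=False))
```

which prints (medians and equal-tailed 95% CIs):

```
  parameter class    median     ci_lo     ci_hi
      kappa    AF     1.927     1.751     2.115
      gamma    AF 68068.395 62432.304 72963.534
        phi    AF     0.294     0.221     0.367
step_length    AF 60365.895 55553.199 64715.333
```

The AF truth here was κ = 1.79, γ = 67,288 m, φ = 0.248: the medians land
within a few percent and every interval covers its generating value.
`mean_step_length(1.79, 67288) = 59854.8` m is the model's derived 4-day
displacement for an adult female — about 15 km/day.

The full pipeline is also available as a CLI:

```sh
bearmove --seed 1 --out-dir run1 run-all          # simulate ... validate
bearmove --seed 1 --out-dir run1 fit-ssf --force  # re-run one stage
```

Each stage writes a manifest with input hashes; reruns skip stages whose
inputs are unchanged, and rerunning with the same seed reproduces every
output bit for bit.

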