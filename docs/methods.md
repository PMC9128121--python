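# Methods

This note documents the models, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Movement model

Step lengths at 4-day resolution are modelled as `l_{i,t} ~ Weibull(k_i, g_i)`
and bearings as `θ_{i,t} ~ wrappedCauchy(θ_{i,t-1}, r_i)`.  The wrapped-Cauchy
concentration r is the directional persistence: r = 0 is uniform turning and
r → 1 is straight-line travel.  Individual parameters are tied to class-level
parameters (classes: adult female AF, adult male AM, sub-adult SA) through
method-of-moments hyper-distributions:

    g_i | c ~ Gamma(γ_c²/σ_γ², γ_c/σ_γ²)      mean γ_c, variance σ_γ²
    k_i | c ~ Gamma(κ_c²/σ_κ², κ_c/σ_κ²)
    r_i | c ~ Beta(a, b),  a, b chosen so the mean is φ_c and variance σ_φ²

The Beta parameterization requires σ_φ² < φ_c(1 − φ_c); the constructor
raises outside that bound, and the sampler treats it as a support constraint
(jointly truncating φ_c and σ_φ).  Priors are uniform:
γ_c ~ U(0, 5·10⁵), κ_c ~ U(0, 10), φ_c ~ U(0, 1), σ_γ ~ U(0, 5·10⁴),
σ_κ ~ U(0, 5), σ_φ ~ U(0, 0.5).  Each animal's first angle θ_{i,1} ~ U(−π, π)
is a free parameter on which the first observed bearing is conditioned.  The
initial step s_{i,1} ~ U(0, 10⁵) is carried in the state for fidelity to the
model specification but contributes no likelihood under the Weibull model as
written; it is resampled directly from its prior each sweep.

The derived class mean step length is `μ_c = γ_c Γ(1 + 1/κ_c)` with the
ordinary gamma function.  (A log-gamma reading would make μ_c negative at the
relevant κ values, so Γ is the only reading consistent with positive
step-length summaries.)

**Angle convention.**  "Directional persistence" is read the standard CRW
way: the deviation between consecutive *bearings* is wrapped-Cauchy centred
at zero, equivalently the current bearing is centred on the previous bearing.
A literal autoregression on turn angles (each turn centred on the previous
*turn*) is an unusual but possible reading; it is implemented behind
`angle_mode="turn_autoregressive"` in both the generators and the
likelihoods, with the bearing reading as the default everywhere.

## Location preprocessing and multiple imputation

Deterministic filters per animal: drop fixes < 5 days post-capture, keep the
1 March – 30 June window, keep one fix per duty cycle (smallest ellipse area
π·smaj·smin; calendar-day grouping is the fallback when duty-cycle ids are
missing), and exclude animals with fewer than 3 remaining fixes.  Filtering
is idempotent.

The CTCRW is an integrated Ornstein–Uhlenbeck velocity process with
parameters shared across the two planar axes: velocity autocorrelation β
(1/day) and diffusion σ².  Observations are the fixes with per-fix 2×2 error
covariance implied by the ellipse (semi-axes are treated as 1-SD lengths).
The likelihood is evaluated by Kalman filter; maximum likelihood uses
L-BFGS-B on (log β, log σ) from two starts.  The initial state is proper but
weak: position centred on the first fix with SD 100 km, velocity at its
stationary distribution.  Path realizations on the exact 4-day grid
(anchored at each animal's first retained fix) are drawn by conditional
simulation via mean correction: simulate an unconditional state path and
pseudo-observations, smooth both, and combine.  Realizations are assembled
into m datasets with exactly one realization per animal and no reuse.

Steps with either endpoint on a land cell are flagged invalid (analysis is
restricted to sea ice); the movement likelihood consumes validity masks, and
an angle term is dropped when either adjacent step is dropped.

## Samplers

Both models use single-block adaptive random-walk Metropolis within Gibbs,
vectorized across conditionally independent blocks (individuals, classes,
covariates).  Proposals are Gaussian on the natural scale for bounded
uniform-prior parameters (rejecting outside the bounds), log scale for
positive parameters, logit scale for (0,1) parameters, and circular for
angles.  Proposal scales adapt in batches of 50 toward ~35% acceptance
during a dedicated adaptation phase and are frozen afterwards; acceptance
rates and single-chain split-R̂ (plus effective sample size) are recorded in
the sample metadata, with a warning (never an error) when R̂ > 1.1.  One
chain is run per imputed dataset; draws are pooled across datasets with
provenance, and summaries are medians with equal-tailed 95% CIs.  The
initial-angle block accepts at a high rate regardless of proposal scale
because its conditional posterior is nearly flat on the circle at realistic
persistence values; this is a property of the target, not a tuning failure.

The step-selection hierarchy α_ij ~ Normal(β_cj, σ_j) with
σ_j ~ Gamma(0.01, 0.01) (shape–rate on the SD, shared across classes)
produces a funnel at σ → 0 under which centred samplers collapse.  The SSF
sampler therefore uses the non-centred parameterization
α_ij = β_cj + σ_j z_ij with z_ij ~ N(0,1): z and β are vectorized Metropolis
blocks (a β move shifts all of its class's α), and σ_j is a log-scale
Metropolis block whose move rescales the individual offsets.  The
Normal(0, 100) prior on β_c is read as standard deviation 100; both prior
readings (SD vs precision, Gamma on SD vs on precision) are switchable in
`SSFPriors`.

Default schedules mirror the reference implementation at full scale
(movement: 5,000 adaptation / 100,000 burn-in / 100,000 iterations thinned
by 100; SSF: 5,000 / 10,000 / 5,000 thinned by 5; 25 datasets pooled to
25,000 draws).  A desk profile (hundreds to thousands of iterations, 3–5
datasets) runs the full pipeline in minutes and is used by the tests; the
problem sizes used by each test are stated in its docstring or fixture.

## Step-selection design

Available locations: one (k, g, r) triple is drawn from the individual's
movement posterior per cluster, then A = 25 lengths ~ Weibull(k, g) and
bearings ~ wrappedCauchy(θ_prev, r) displace the previous used location.
Clusters start at the third path location (two predecessors are needed for
θ_prev).  Covariates (fixed order): depth, ice concentration, its square,
SD of concentration within 100 km, distance to land, its square, unsigned
distance to the 10% concentration contour, its square.  Quadratics are
formed on the raw scale and each of the 8 columns is centred/scaled
independently by its pooled mean/SD per imputed dataset; the scaling is
stored (`DesignInfo`) and reused at prediction time.  Available points on
land are kept and given covariates (distance to land ≈ 0); points beyond
the grid are clamped to the grid edge.  The unsigned contour distance
carries no side information; sidedness is recoverable from the concentration
value itself.

Covariate extraction conventions: depth and distance-to-land are bilinear
interpolations (the latter of a Euclidean distance transform to land-cell
centres); concentration, its local SD, and the contour distance are
nearest-cell lookups, with the contour distance defined as distance to the
nearest opposite-side cell centre minus half a cell, floored at zero.  Daily
layers are matched to the calendar day of each location.

## Cross-validation

Per imputed dataset: a random 20% of clusters (rounding half away from zero)
are withheld; the model is refit on the training clusters with the design
scaling fit on training data only; each held-out cluster's 26 rows are
ranked by linear predictor (a strictly monotone transform of the choice
probability, so ranks coincide), ties broken by a seeded permutation; the
used row's rank is histogrammed and the Spearman correlation of counts
against bin index 1..26 reported.  Held-out clusters are scored with the
class-level β medians — the only option for fully held-out animals, applied
uniformly; scoring with α_i is available behind a config switch.  A
zero-variance histogram raises rather than silently returning 0.  The
per-dataset ρ values are pooled by median and empirical 2.5/97.5 percentiles.

## Synthetic world

The generator emulates the study design: three classes with class-specific
movement parameters centred on realistic spring values (κ ≈ 1.8,
γ ≈ 67–79 km per 4 days, φ ≈ 0.16–0.25, moderate inter-individual spread);
1–4-day duty cycles with occasional double fixes (so deduplication is
exercised); random error ellipses with ~6 km mean semi-major axis; and
class-dependent tag failure giving AM/SA series roughly five fewer 4-day
steps than AF.  Rasters live on a planar 56×56 grid of 25-km cells (~1,400
km, comparable to the real study area): depth is a smooth negative field,
land a contiguous block along the eastern edge, and daily ice concentration
a south–north ramp plus AR(1)-in-time anomaly fields with ~40-km spatial
correlation and 35% SD, clipped to [0, 100], with forced open water on the
southern edge and pack ice on the northern edge so a 10% contour exists
every day.  The anomaly roughness matters scientifically: spring pack ice
varies strongly at scales below a 4-day step, and without that within-step
contrast no step-selection signal of realistic magnitude is recoverable.

Covariate-biased tracks select one of n candidate endpoints with probability
∝ exp(β·x), with covariates standardized by stack-wide means/SDs so β acts
on approximately unit scales.  Because the SSF assumes choice against the
continuous kernel, generation uses large candidate pools (100 by default in
the pipeline, 400 in recovery tests); small pools (e.g. 25) visibly
attenuate recovered coefficients — a finite-choice-set effect of the
generator, not of the estimator.  Recovery tests map generating coefficients
into the fitted scale exactly via β_fit = β_gen · sd_pool/sd_stack
(conditional-logit likelihoods are invariant to the additive part of the
affine scaling).

What the synthetic world does **not** emulate: geodesy (coordinates are
planar meters), real sea-ice physics or NSIDC grids, Argos location-class
structure, behavioural states, or prey fields.  Passing recovery tests
therefore demonstrate correctness of the estimators under the assumed model,
not robustness to real-data violations of it.

## Numerical details and edge cases

- Weibull log-density at l = 0: −∞ for k > 1, −log g at k = 1, +∞ for k < 1;
  step lengths are floored at 10⁻⁸ m in the padded likelihood arrays.
- Wrapped-Cauchy sampling wraps a linear Cauchy with scale −log r (exact);
  r = 0 falls back to circular uniform.
- Angles are wrapped to (−π, π] throughout.
- The local concentration SD is computed from globally centred fields so the
  uniform-field case returns exactly zero.
- Kalman covariances are symmetrized each update; process-noise Cholesky
  draws add 10⁻⁹ jitter.
- CI overlap width is min(upper) − max(lower): positive is the overlap
  length, negative the gap.
- Every generator and sampler is a pure function of (inputs, rng); the
  pipeline derives per-stage seeds from one master seed and writes manifests
  with input hashes, so identical configurations reproduce outputs bit for
  bit and unchanged stages are skipped on rerun.

## Known limitations

- Movement coefficients are not corrected for selection (the two-step
  design): movement parameters are fit ignoring habitat selection, which can
  bias the availability kernel where selection is strong.
- Split-R̂ is computed on a single chain per dataset (halves compared);
  multi-chain diagnostics require running the sampler with different seeds.
- σ_j (inter-individual SD of selection coefficients) is weakly identified
  with few animals; its posterior is prior-dominated and wide.
- The CTCRW assumes a single movement regime per animal; no behavioural
  switching.
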