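# Methods

This note documents the models implemented in `tradmod`, the parameter
choices that matter, and what the synthetic data can and cannot show.

## Synthetic survey generator

**Population.**  Nine constructs on a 1-5 Likert metric: cultural identity
(CI), medicine-food separation cognition (MFSC), attitude (ATT), perceived
price (PP), purchase intention (PI), purchase behaviour (PB), food
neophobia (FN), health literacy (HL), and a packaging-preference marker
(MK).  Item counts (3 each, 2 for PB), target AVEs, the inter-construct
correlation matrix, demographic proportions (54.6% urban; age shares
21.8/45.1/24.9/8.2%) and the standardized urban→MFSC effect (0.26) are the
published summary statistics of the reference survey.  Only the PI mean/SD
(3.73/1.07) are anchored by that survey; the remaining construct means
(CI 3.8, MFSC 3.0, ATT 3.7, PP 3.2, PB 3.1, FN 2.9, HL 3.5, SD 1.0) are
plausible conventions, exposed in the config, and nothing downstream
asserts them.  All MFSC items and FN1 are generated in reversed orientation
and un-reversed at scoring time.

**Item model.**  An item is a threshold-discretized propensity
`shift + λ·z + sqrt(1−λ²)·noise`, cut at the standard-normal quintile
points (symmetric, parameter-free).  The per-construct `shift` is solved
exactly so the expected item score equals the construct mean; this is what
puts the PI composite mean at 3.73.  The composite SD that emerges from
quintile cuts is ≈1.2 rather than 1.07; only the mean is calibrated, and
the ABM takes its anchors from configurable constants, not from the
generated items.

**Attenuation-aware calibration.**  Five-point categorisation shrinks
product-moment correlations nonlinearly (the linear Hermite term carries
≈89% of the variance at these cuts), so naive generation misses every
observed-scale target: composite correlations come out ~0.03-0.04 low and
ML-SEM path estimates 0.02-0.04 low.  The generator therefore solves the
exact discretized-moment maps (bivariate-normal rectangle probabilities):

- generation loadings are chosen so *observed* within-construct item
  correlations equal the target AVEs;
- in `corr-matched` mode, latent correlations are chosen so *observed
  composite* correlations reproduce the target matrix (the printed matrix
  is treated as composite-level - the source does not say which, and the
  composite reading keeps the Fornell-Larcker comparison internally
  consistent);
- in `model-generated` mode, latent correlations are chosen so that the
  correlations *recovered by a factor analysis* of the items equal the
  correlations implied by the structural coefficients; the urban dummy uses
  the continuous-variable version of the same map.  Drawing latents from
  this implied covariance is distributionally identical to iterating the
  structural equations with Gaussian disturbances, so the printed
  coefficients are the ground truth that a correctly specified ML fit
  recovers without bias (verified to ±0.01 at n = 1,076 over 200
  replicates; mean χ² ≈ 1.06·df under Likert data, χ² ≈ df under the
  continuous mode where the fitted model is exactly true).

If a requested matrix is not positive definite, eigenvalues are clipped at
1e-8 and the matrix rescaled to unit diagonal; the maximum entry change is
reported on the spec.  The two regimes exist because the published
correlation matrix and path coefficients cannot both hold (the implied
Σβr for PI exceeds the printed R²); no single generator can match both.

**What the generator does not emulate:** response styles (acquiescence,
straight-lining), missing data, item-specific loadings within a construct,
non-normal latent distributions, or any real sampling design.  Passing
tests therefore demonstrate correctness of the estimators on data that
satisfy their assumptions, not robustness on real survey data.

## Measurement diagnostics

Cronbach's α uses raw covariances (a standardized option exists); CR and
AVE follow the standard composite formulas from standardized loadings;
loadings are estimated by deterministic principal-axis factoring (sqrt of
the inter-item correlation for 2-item constructs).  Harman's single-factor
share is the first eigenvalue of the pooled item correlation matrix over
the number of items - the most common, rotation-free operationalisation.
The Fornell-Larcker report replaces the diagonal with √AVE and flags each
pair; it is computed on composite correlations and labelled as such.

## The SEM engine

RAM parameterisation: `v = A v + u`, `Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ`, with an
optional mean structure `μ = F(I−A)⁻¹m`.  Models are written in a small
lavaan-style DSL; the first loading of each latent is fixed to 1 for
identification (latent-variance scaling is available by fixing explicitly);
a dummy-coded observed regressor may enter regressions directly (zero
measurement error by construction).  Estimation: L-BFGS on an internal
parameterisation with log-transformed variances (positivity by
construction), analytic F_ML gradient, convergence at gradient norms
~1e-5-1e-6, up to 5 random restarts on failure.  Standard errors come from
the numeric Hessian of (n−1)/2·F_ML in the natural parameter space;
near-zero variance estimates are flagged as Heywood-like.  The baseline for
CFI/TLI is the independence model with free variances (closed form
−ln|R|); RMSEA uses the (n−1) convention; SRMR averages squared
standardized residuals over the lower triangle including the diagonal.

Multi-group fits minimise Σ_g (n_g−1) F_g with equality constraints
expressed through shared parameter labels per category (loadings,
intercepts, ...).  The invariance sequence runs configural → metric →
scalar with a mean structure at every level (saturated means below scalar,
so the χ²s are nested), freeing latent means in non-reference groups at the
scalar level, and applies the |ΔCFI| ≤ 0.01 rule.  Note that a *uniform*
rescaling of one group's loadings is not detectable under reference-item
identification - it is absorbed into the latent variance; metric
non-invariance means unequal loading *patterns*.

The common-latent-factor check adds one orthogonal method factor with
equal loadings on all indicators and reports the largest standardized
structural-path change against the base model.

t-values are reported but not treated as reproduction targets: the
published t/CI pairs are mutually inconsistent, so no implementation can
match both.

## LMG importance

Exact subset-weight enumeration (≤12 predictors), equivalent to averaging
incremental R² over all orderings; R²(S) = r_yS' R_SS⁻¹ r_yS with a 1e-10
ridge fallback (warned) for singular blocks.  Inputs may be raw composites
(the default: unit-weighted means of un-reversed items) or a correlation
matrix.  Shares computed from the printed latent correlations legitimately
differ from the published shares (42.8/28.1/16.5/12.6), which were computed
on the unavailable raw data; the pipeline report prints both side by side
without asserting equality.

## Agent-based model

1,000 agents, Barabási–Albert network (m = 3), 100 synchronous steps.
Each step: intention `PI_z = 0.34 z(CI) − 0.29 z(MFSC) + 0.44 z(ATT)
− 0.27 z(PP) + ε`, destandardized as `3.73 + 1.07·PI_z` and clipped to
[1,5]; purchase when PI exceeds a per-agent-step threshold ~N(3.4, 0.5²);
CI diffusion toward strictly higher-CI neighbours at rate τ.  z-scores use
the frozen population means/SDs, so absolute CI gains translate into
intention gains.  ε is redrawn per agent-step.

**Diffusion aggregation.**  The default divides the summed positive
neighbour gaps by the agent's degree (`mean` mode).  The literal `sum`
mode is retained for fidelity experiments but saturates hub-rich networks
at the scale ceiling within ~50 steps at τ ≥ 0.05, because a hub's summed
gaps exceed the neighbour maximum once degree ≳ 1/τ.

**Calibration.**  τ is calibrated by pattern-oriented modelling on the
grid 0.01-0.10 against the survey pattern (PI mean 3.73, SD 1.07), scored
on the final-20-step window.  The intention-noise SD - nowhere specified -
was calibrated once against the same pattern at τ = 0.05, giving σ = 1.0
z-units as the default: positive-gap diffusion steadily homogenises CI, so
with small σ the stationary PI dispersion collapses far below the observed
1.07 while diffusion alone pushes the mean upward.  With the calibrated
defaults the baseline settles at mean PI ≈ 3.85 and SD ≈ 1.08 (30 seeds).
The purchase-threshold parameters affect only the purchase-rate series.

**Interventions.**  A one-shot ΔCI (default 0.1) applied at t = 0 to the
26-55 age bands (both brackets of the published "core" demographic).
Paired seeds make treated and control runs share network, initial states
and noise.  Two uplift readings are reported and kept distinct:

- *vs control* - treated vs seed-matched control end states; isolates the
  marginal effect (exactly 0 for ΔCI = 0, monotone in ΔCI).  Under
  positive-gap ratchet dynamics this quantity *decreases* with τ: the
  control population converges to the same neighbourhood maxima, absorbing
  the bump.
- *vs baseline* - treated end state vs the pre-dynamics intention level;
  this is what a before/after market scenario tabulates, it equals the
  direct effect at τ = 0 and grows strictly with τ (≈3% → ≈10% over
  τ = 0.01-0.15 at ΔCI = 0.1).  The sensitivity table and the τ-ordering
  property use this reading.

Published uplift magnitudes (12.4-28.9%, and the 19.7% headline) are not
reproduction targets: they depend on the unspecified noise and threshold
parameters, and the published baseline intention (3.20) is inconsistent
with the published calibration anchor (3.73) - possibly a different
("repurchase") quantity.  The simulator reports its own baseline alongside.
Only orderings (uplift increasing in τ and in ΔCI; tail compression) are
contracts, and they are checked across independent topologies.

## Problem sizes and numerical conventions

Recovery experiments use 200 replicates at the study size n = 1,076;
simulator summaries use 30 seeds × 1,000 agents × 100 steps; composite
-moment recovery is checked at n = 100,000.  Matrix repairs clip
eigenvalues at 1e-8; LMG identities are asserted to 1e-12; optimizer
restarts are seeded and deterministic.  All randomness flows from explicit
integer seeds through `numpy.random.SeedSequence`, so every table in the
report bundle is bit-reproducible given (config, seed).

## Known limitations

- Likert items are treated as continuous in the ML fit (no polychoric /
  WLSMV path); the generator compensates at the moment level, real ordinal
  data would not.
- No bootstrap or robust (Satorra-Bentler) corrections; SEs assume
  multivariate normality.
- The ABM's ratchet diffusion has no forgetting mechanism, so CI drifts
  toward the ceiling on long horizons; the 100-step window is part of the
  model definition.
- MFSC item wording is reverse-keyed while the construct is scored as
  "higher = stronger separation belief"; the generator follows that scoring
  convention throughout.
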