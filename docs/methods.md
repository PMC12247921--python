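# Methods

## The problem

When two consumer items are valued as a bundle, reported willingness-to-pay
(WTP) is sub-additive: v_ij < v_i + v_j, with the discount growing in the
item values. The same question has a neural side: do brain value regions
encode item and bundle values on one absolute scale (a context-invariant
"common currency"), or does the code re-scale per context, attenuating its
responsiveness on bundle trials? `bundleval` implements the behavioral
models, the normalization theory, and the multivariate analyses needed to
ask both questions, together with synthetic-data generators that carry the
statistical structure the analyses assume.

## Synthetic data generator

The generator emulates a three-day study design:

- **Stimuli.** 40 items, categories split evenly between food and trinkets;
  20 items per day (10 shared across all days, 10 fresh per day); all
  C(20,2)=190 within-day pairs plus the 20 self-pairs give 210 bundles per
  day.
- **Latent values.** Item values are exponential with mean $3.30, truncated
  to the $0–$20 budget — a right-skewed distribution matching typical bid
  histograms. Bundle value distributions end up shifted right of item
  values, which is what makes absolute and per-condition-normalized codes
  distinguishable.
- **Bids.** Item bids are the latent value plus Gaussian noise (sd 0.5 by
  default); bundle bids apply one of the four families to the latent member
  values, plus subject random effects on the intercept and the leading
  scale coefficient (sd 0.3 and 0.05 by default) and Gaussian noise (sd
  1.0). Bids are censored to [$0, $20] (`censor_bids=False` disables this
  for estimator-validation studies; see "Recovery studies" below).
- **Choice task.** Per day, 5 runs of 62 trials: each of the 20 items once
  per run, the 210 bundles partitioned evenly at random across runs (42
  per run), item and bundle trials shuffled together, side assignment
  balanced within run. The reference money amount is the subject's same-day
  per-category median bid. Choices are logistic in
  (bid − reference − money_bias·[item]) / temperature; the money bias on
  item trials defaults to 0 and is configurable (its empirical magnitude is
  not pinned down). Reaction times are log-normal plumbing.
- **BDM auction.** A bid is compared to a Uniform($0,$20) price; purchase
  at the drawn price iff bid ≥ price. Expected surplus is available in
  closed form, and the test suite verifies it peaks at the true value
  (truthfulness).
- **Multivoxel patterns.** pattern(t) = w_value(type)·coded(t)·u +
  w_tt·[bundle]·c + w_side·[right]·s + ε with u, c, s fixed unit-norm
  Gaussian directions drawn once per dataset and ε i.i.d. Gaussian. The
  coded value follows the scheme: raw bid, bid minus condition mean,
  condition z-score, compressive v/(σ+v), or none. `w_bundle < w_item`
  realizes an attenuated bundle code; `separate_directions=True`
  orthogonalizes the item and bundle encoding axes (a condition-specific
  code). These patterns stand in for trial-wise GLM beta maps; there is no
  BOLD time-series, HRF, or spatial noise structure, so passing tests show
  that the *analyses* behave as intended, not that real fMRI data would be
  this clean.

All generators are bit-reproducible under a fixed seed.

## Behavioral model fitting

Three estimation routes, sharing analytic Jacobians per family:

1. **Pooled fixed effects** — multi-start (default 5, seeded) bounded
   nonlinear least squares with a linear-least-squares warm start; for the
   linear family this equals the closed-form solution to 1e-8.
2. **Per-subject fixed effects** — each participant fitted independently;
   the reported comparison metric is the **sum of per-participant BICs**
   (with per-subject Gaussian profile likelihoods). This is the headline
   model-comparison aggregation.
3. **Mixed effects** — subject random effects on the intercept and the
   leading scale coefficient. The linear family uses the exact marginal
   likelihood (statsmodels `MixedLM`, ML, random intercept + slope on
   v_i+v_j). Nonlinear families use an in-package Laplace-approximate
   nonlinear mixed model: a joint penalized least-squares fit of fixed and
   subject effects (inner loop, analytic Jacobian) nested in a Nelder–Mead
   search over log variance components, with the marginal likelihood
   approximated at the joint mode. Single-subject data falls back to fixed
   effects with a warning.

Numerical choices: σ is bounded below by 1e-6 (divnorm), power exponents
and log offsets are box-constrained to (0, 5] and (0, ∞); censored bids
enter fitting as-is (a documented limitation — no Tobit-style correction).
BIC counts all fitted parameters including variance components. Bundle-type
stratified fits use the linear family; same-item bundles have v_i = v_j, so
that stratum is fitted as b0 + c·(v_i+v_j) with fixed effects only and both
slopes reported as c. Fitted curves are evaluated on the equal-member
diagonal v_i = v_j ∈ [0, 10] in 0.01 steps (1001 points), with the summed
value (twice the common value) as the x-axis.

## Normalization theory

Closed forms for z = v/(σ+Σv): bundle value v̄/(σ+v̄), responsiveness
∂(z₁+z₂)/∂v₂ = σ/(σ+v₁+v₂)², second derivative −2σ/(σ+v̄)³. Implemented
for any number of items. Properties under test: concavity, saturation in
[0,1), order preservation, invariance under joint scaling of values and σ,
and strict attenuation of responsiveness for any companion value > 0 —
the core neural prediction. The design (like the study it emulates) cannot
distinguish divisive from range normalization; only the shared attenuation
prediction is modeled, via the coding scheme's attenuation ratio.

## Cross-condition decoding

Values are z-scored within trial type (population sd). For each held-out
run, a ridge regression (α = 10³, sklearn's closed-form solver, voxels not
standardized) is trained on the training condition's trials from all other
runs and scored on the held-out run separately per test condition by
Pearson correlation; per-split accuracy is the plain mean of r across the
15 folds (no Fisher z). Group inference: two-sided one-sample Wilcoxon
signed-rank tests versus r = 0 per ROI and split, BH-FDR across ROIs at
q = 0.05; condition differences use paired signed-rank tests on
per-subject split differences (samples are paired within subject). Folds
with fewer than two test trials of a condition are skipped with a warning;
all-zero samples get p = 1. A simplified ROI-level regressor comparison
(`voxelwise_value_regression`) contrasts absolute, condition-z-scored and
value-minus-reference regressors by summed log-likelihood across voxels.

## RSA

Neural DSMs are condensed pairwise Euclidean distances between trial
patterns; every same-day pair is masked out (the stricter reading of
removing within-session confounds). Model DSMs are pairwise absolute
differences of per-trial model values; ButtonPress and TrialType nuisance
DSMs are binary disagreement matrices. The predicted DSM is
a0 + a1·ButtonPressDSM + a2·TrialTypeDSM + ValueDSM with the value DSM
entering at unit coefficient (scale carried by b1, b2). The full
normalization value is (b1·V + b2·V·T)/(σ + w_avg·Avg + w1·T + w_v·V); the
joint rescaling degeneracy of numerator and denominator is removed by
fixing σ = 1 during optimization, so all other parameters are relative to
it. Subtractive/z-score models normalize within trial type by default
(within stimulus category is exposed as an option). Fits minimize squared
error over valid pairs with lmfit (least-squares backend); the
full-normalization family is multi-started (5 jittered starts, seeded)
with |b| ≤ 10 and denominator weights ≥ 0, which with σ = 1 guarantees a
positive denominator. BIC uses the Gaussian profile likelihood over valid
pairs with all free parameters (plus the residual variance) counted. The
attenuation test is a paired t-test of bundle (b1+b2) versus item (b1)
coefficients across subject cells, p = 1 by convention when all
differences are exactly zero.

## Recovery studies (what the tests simulate and why)

- Recovery suites simulate with `item_noise_sd = 0` (regressors equal the
  generative inputs; avoids errors-in-variables attenuation) and — for
  model-*selection* recovery — with censoring disabled: clipping at the
  budget makes linearly generated data genuinely concave, so concave
  families would legitimately win. These suites validate the estimators
  under their own assumptions; the study-condition defaults keep both
  effects on.
- A linear generator with exactly equal slopes is observationally
  equivalent to large-σ divisive normalization (equal parameter count), so
  BIC selection on such data is a boundary case; the selection-recovery
  study uses slightly asymmetric slopes (0.74/0.77, the stratified
  food-bundle values), which the divnorm family cannot mimic.
- Null (type-I) simulations generate at interior values of all bounded
  parameters; generating exactly on the non-negativity bounds of the RSA
  denominator weights biases the compensating value coefficients.
- Problem sizes: coefficient recovery uses the full 14-subject design;
  model-selection recovery uses 5-subject cohorts (630 bundle bids each),
  decoding type-I control 8-subject cohorts, RSA cohorts 14 subjects at
  75 trials (25 per day) — sizes chosen so the whole suite runs quickly
  while keeping each test well-powered. The end-to-end pipeline default
  subsamples 120 trials per subject for the DSM fits, since the pairwise
  problem grows quadratically in trials.

## Known limitations

- Censored bids are fitted as-is; estimates near the budget bounds are
  biased (visible as a slightly inflated intercept under the default
  generator).
- The Laplace approximation for nonlinear mixed models can understate
  variance-component uncertainty; BIC comparisons across families use the
  same approximation and are therefore on an equal footing.
- The pattern generator's noise is i.i.d. Gaussian; no spatial or temporal
  autocorrelation, so decoding/RSA effect sizes are optimistic relative to
  real data.
- σ and β₁ of the divnorm family trade off when the value range is narrow
  relative to σ; curve-level recovery is well-identified even when the
  individual parameters are not.
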