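# Methods

## Severity grading

Each of the five health-status parameters is graded 1 (controlled), 2 (mild
activity, further evaluation), or 3 (significant activity, clinical action).
The grading rules are fixed instrument definitions, not fitted quantities.
Boundary conventions, where the printed inequalities leave room, are:

- **IGF-I**: level 1 on the closed interval [LLN, ULN]; a value exactly at
  1.2×ULN is level 2 (level 3 requires strictly more than 1.2×ULN); any
  value below LLN is level 2 (abnormal but not "significantly elevated").
- **Tumor**: level 2 requires a strict *increase* in size of at most 20 %;
  no change, shrinkage, an invisible tumor, or an undocumented change (no
  prior MRI) are level 1. Increase > 20 %, increased invasiveness, or
  worsening vision are each sufficient for level 3.
- **Comorbidities**: a precedence rule. Any of {uncontrolled diabetes,
  moderate/severe sleep apnea, uncontrolled cardiac disease} forces level 3;
  level 1 requires no diabetes, no sleep-apnea complaints, and cardiac
  disease absent or controlled; everything else is level 2. The original
  level-3 wording is grammatically ambiguous about moderate/severe apnea
  without diabetes; the precedence reading keeps every condition explicitly
  named at level 3 there, and grades isolated *mild* apnea level 2.
- **Symptoms (SSS)**: the level-3 test (mean item score > 4 or any item
  > 6) is applied first, then the level-1 test (all items ≤ 2), else
  level 2. The explicit ordering resolves profiles such as all-items-3,
  which match neither verbal description cleanly.
- **Quality of life (AcroQoL)**: the raw 22–110 total is standardized
  linearly to 0–100, `100·(raw − 22)/88`, with 100 the best possible QoL;
  the 40/60 thresholds apply to this percentage, with both boundaries
  resolving to the milder level (60 → level 1, 40 → level 2).

Missing items or components are errors; a clinical scorer must not impute.

## Scenario space and survey design

The 243 scenarios are the 3⁵ level combinations in fixed parameter order
(IGF-I, tumor, comorbidity, symptoms, QoL). Ids use the mixed-radix map
`id = 1 + Σₖ (levelₖ − 1)·3^(5−k)` (QoL digit fastest); this convention is
not stated anywhere explicitly but is the unique natural rule reproducing
all ten published (id, bracket-code) pairs, verified exhaustively in tests.

`required_design_size` implements the events-per-variable rule: with 10
events per model variable, 10 indicator variables, an event rate of 1/3 and
a doubling for within-rater dependence, 600 observations, i.e. 29 scenarios
per rater for 21 raters. `build_survey_design` gives every rater the common
core plus a without-replacement fill; *stratified* fill (default) always
draws from the currently least-assigned scenarios with random tie-breaks,
which keeps per-scenario coverage counts within one of each other; *simple*
fill is plain uniform sampling. Both are deterministic under the seed.

## Agreement statistics

For a balanced block (every scenario rated by the same n raters) with count
rows n_ij:

- Pr_i = Σⱼ n_ij(n_ij − 1) / [n(n − 1)], the fraction of agreeing rater
  pairs;
- Pc_j = Σᵢ n_ij / (N·n);
- Fleiss' κ = (P̄ − P̄ₑ)/(1 − P̄ₑ), P̄ the mean Pr, P̄ₑ = Σⱼ Pc_j².

κ is implemented here (it is the quantity being reproduced) and is
cross-checked in the test suite against the independent statsmodels
implementation to 10⁻¹⁰. Comparisons against printed three-decimal values
use half-even rounding at three decimals.

The packaged ten-common-scenario fixture stores, for each row, the unique
composition of 21 that is consistent with the published digit string *and*
reproduces the printed Pr — e.g. the row printed `1 9 11` (Pr 0.433) rather
than `19 1 1` (which would give 0.814). A partition-search oracle in the
test suite verifies uniqueness for every ambiguous row. The fixture
self-checks on load. The published outlier-removed sensitivity value of κ
cannot be reproduced because per-rater ratings were never published;
`leave_one_rater_out` implements the analysis and is exercised on simulated
data only.

## The activity algorithm

**Gate.** IGF-I level 3 or tumor level 3 classifies the patient S-DA
immediately; the 135 such vectors (81 + 81 − 27) bypass the probability
model entirely and report score 1.0 by convention (the score formula is
defined on probability triples, which gate rows never receive).

**Two-stage logistic model.** On the 108 compensatory vectors, the ordinal
outcome is decomposed into two binary choices: Model 1 predicts S vs
not-S on all retained ratings; Model 2 predicts S-DA vs M-DA on the
non-stable ratings only. Covariates are indicator-coded severity levels
with level 1 as reference — by default comorbidities, symptoms, and QoL
(6 columns), optionally all five parameters (10 columns, adding the IGF-I
and tumor level-2 effects, which also behave compensatorily below the
gate). Gate rows are excluded before either fit.

Stages are fit by penalized maximum likelihood (lbfgs) with an L2 penalty
of strength `ridge` on the coefficients, default 10⁻⁶ — effectively
unpenalized but finite under the quasi-complete separation typical of
small vignette datasets. `ridge=0` requests the unpenalized fit and raises
a non-convergence error, advising a positive ridge, if the optimizer hits
the iteration cap (default 100). A stage whose outcome is one-sided
degenerates to an intercept-only fit at the smoothed base rate; an empty
non-stable subset is an error.

**Probability combination.** Two modes:

- *literal* (default): P_S from Model 1, P_S-DA from Model 2, P_M-DA as
  the remainder. Because Model 2 is fit on the non-stable subset, its
  prediction is an estimate of P(S-DA | not S), so using it marginally can
  drive the remainder negative; the literal mode then clamps P_M-DA to 0,
  renormalizes, and emits a `CoherenceWarning` (counted on the estimator).
  Literal is the default because it is the combination rule as stated for
  the original algorithm.
- *conditional*: P_S-DA = (1 − P_S)·Model 2, P_M-DA = (1 − P_S)·(1 −
  Model 2). Always coherent, and the statistically consistent reading;
  recovery analyses use it.

**Score and classification.** score = ([1·P_S + 2·P_M-DA + 3·P_S-DA] −
1)/2, linear on the simplex with vertex values 0, ½, 1. Below the gate the
class is M-DA if P_M-DA > P_S and S if P_S > P_M-DA; an exact tie resolves
to M-DA, the direction that prompts further evaluation.

**CART.** `GiniCartClassifier` grows a greedy binary Gini tree over the
five ordinal parameters (scikit-learn backend). Because each parameter is
an ordered 3-level factor, every threshold split is exactly one of the
ordered subset splits {1} | {2,3} or {1,2} | {3}; the tree is re-exposed in
those terms. `min_leaf` defaults to 20; no pruning or cross-validated
tuning (the tree's role is structural: exhibiting the gate splits).

## Rater simulator

Scenario severity is summarized by a latent index
μ(v) = Σₖ wₖ·(levelₖ − 1) with non-negative weights, rater heterogeneity
by an additive bias bᵣ ~ N(0, rater_bias_sd²), and two cutpoints divide
the latent scale into S / M-DA / S-DA. Two generative families:

- **gaussian** (default): latent u = μ + bᵣ + ε with Gaussian ε; marginal
  class probabilities are exact Gaussian orthant probabilities with
  combined sd √(bias² + noise²).
- **sequential**: a continuation-ratio logistic — S with probability
  expit((cut₁ − μ − bᵣ)/s), otherwise S-DA with probability
  expit((μ + bᵣ − cut₂)/s). This family *is* a gated two-stage logistic
  model, so the fitted estimator is correctly specified under it; with
  rater bias the marginal truth is computed by 64-point Gauss–Hermite
  quadrature, otherwise in closed form.

`gate_in_truth` optionally forces S-DA for every IGF-I/tumor level-3
scenario in both the draws and the truth.

**Defaults.** 21 raters × 52 scenarios with the ten published common
scenarios; weights (1.0, 0.9, 0.45, 0.40, 0.35) making IGF-I and tumor
dominant, as observed of real raters; cutpoints (1.1, 2.6) spanning the
latent range 0–6.2; rater_bias_sd 0.3 and noise_sd 0.5. `gate_in_truth`
defaults to false: the published common-scenario counts show real
physicians were *not* unanimous on gated scenarios, so the default
emulates a soft gate through large IGF-I/tumor weights. The noise scales
were calibrated once so the simulated common-scenario Fleiss' κ lands in
the observed moderate band (about 0.4–0.65; the defaults give ≈ 0.57–0.64
across seeds). The simulator emulates the survey's *structure and
marginal behavior* only: it has no country or experience covariates, no
item-level questionnaire responses, no learning or ordering effects —
passing tests show the statistical machinery is correct, not that real
physicians behave like the generator.

**Recovery experiment.** The end-to-end recovery tests (and the matching
acceptance check) use a design chosen to measure pure estimation error at
n ≈ 20,000: the sequential family (correct specification), zero rater
bias, IGF-I/tumor weights zero (those parameters act only through the
gate, mirroring the fitted model's structure), cutpoints (0.45, 1.55) and
scale 0.583 over the compensatory range, and 185 raters each rating all
108 compensatory scenarios — ratings on gated scenarios would be discarded
by the fit. Under this design the maximum absolute error of the fitted
probabilities over the full grid is ≈ 0.02–0.03 at n = 19,980 (it is a
fixed-seed stochastic check); a smaller companion test verifies the fitted
stage coefficients against the generator's known values (−w/s and −2w/s
per indicator) within three observed-information standard errors.

## Numerical choices and degenerate inputs

- Logistic stages: lbfgs, tol 10⁻⁸, max 100 iterations, ridge 10⁻⁶.
- Probability triples are validated to sum to 1 within 10⁻⁶ before
  scoring; clamped literal combinations renormalize exactly.
- Fleiss' κ requires ≥ 2 scenarios, ≥ 2 raters, and ≥ 2 categories used;
  an all-one-category table is a degenerate-κ error, not NaN.
- Zero-noise simulator configurations are valid and produce point-mass
  truth and unanimous ratings (a latent exactly at a cutpoint rates into
  the higher interval, matching the draw rule).
- All randomness flows from a single config seed through
  `numpy.random.default_rng`; identical configs give byte-identical
  rating tables.
- Reports print floats at 6 significant digits with a version/config-hash
  header, so repeated runs are byte-identical.

## Known limitations

- The original fitted coefficients and CART tree are not reproducible:
  the 1091-observation physician dataset was never published. Property
  tests on simulated data stand in for them.
- The literal combination mode can require clamping; the coherent
  conditional mode changes the S-DA probabilities (it multiplies Model 2
  by 1 − P_S), so scores differ between modes for the same fit.
- The severity classifiers implement one defensible reading of the
  comorbidity and boundary wording (documented above); alternative
  readings would shift level-2/3 assignments for edge profiles.
- Agreement machinery assumes balanced blocks; unbalanced designs must be
  restricted to commonly rated scenarios first.
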