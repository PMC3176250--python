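# Methods

`miscore` implements a complete workflow for developing and internally
validating a short additive screening score for adolescent psychosocial
maladjustment when most records are incomplete. The workflow is:
simulate (or load) a cohort, impose missingness, multiply impute,
select questionnaire items by stepwise logistic regression in every
training imputation, retain items by selection frequency, average
coefficients into an additive score, and validate the score on held-out
imputations with Rubin-pooled metrics. This note records the models,
the defaults and their rationale, and the known limitations.

## The synthetic cohort model

Real questionnaire cohorts of this kind are rarely public, so the
package ships a generator that reproduces the statistical structure the
analysis relies on rather than any particular dataset.

Each student carries a single latent risk factor `u ~ N(0, 1)`, shifted
by `nonlocal_risk_shift` (default +0.4 SD) for non-local/migrant
students so that residence status is an outcome-relevant, fully
observed covariate. Everything informative is driven by `u`:

- **Items.** A categorical item with levels `l` and configured marginal
  probabilities `p_l` is drawn from a multinomial logit
  `P(l | u) ∝ exp(a_l + e_l u)`, where `e_l` is the level's risk
  loading and the intercepts `a_l` are calibrated by Gauss–Hermite
  quadrature so the *marginal* level probabilities equal the configured
  `p_l` (the exponential tilting would otherwise distort them).
  Non-informative items have all `e_l = 0`.
- **Scale totals.** Each of the three behavioural-scale totals
  (CBCL/YSR/MHI analogues) is
  `mean + sd · (ρ u + sqrt(1 − ρ²) ε + gender_shift · male)`, with
  loading `ρ = 0.7` per scale by default and `ε` a standardized
  lognormal (shape 0.6), giving the right-skew typical of symptom
  checklists. Pairwise scale correlations (~ρ² ≈ 0.5) are a package
  default, not an empirical claim; they are configurable.
- **Outcome.** A student is a case when any one scale exceeds its
  gender-specific percentile threshold. Thresholds are empirical
  percentiles of the generated complete data. When a target prevalence
  is configured (default 18.4%), the common percentile is found by
  bisection so the overall case rate matches it. This mirrors
  thresholds that come from external reference norms: with thresholds
  taken from the sample itself at the 95th percentile, the any-of-three
  rule cannot exceed a 1 − 0.95³ ≈ 14.3% case rate, so a higher
  prevalence is only reachable with calibrated (norm-like) thresholds.
- **The scored gender item** is generated as its own latent-loaded
  binary item, deliberately decoupled from the demographic gender
  column used for thresholds. With within-sample gender-specific
  thresholds, demographic gender has no marginal association with the
  outcome by construction; an external-norm setting is where gender
  carries signal, and the decoupled item stands in for that.

The missing-data mechanism is configured per variable. Under MAR the
missingness indicator follows a logistic model in fully observed
covariates (level indicators or standardized numeric values), with the
intercept solved by root-finding so the realized marginal rate matches
the configured rate. MCAR drops the covariates; MNAR additionally
allows dependence on the variable's own value. The default full-scale
configuration reproduces the observed study conditions: item rates
spread over 1.3–11.9% with median ≈ 1.8%, scale totals at
59.3/27.1/27.7%, the first scale structurally missing in two flagged
non-participating schools, and missingness loaded on residence status
and gender. After degradation the outcome is re-derived under the
missing-aware case rule (one observed scale above threshold is a
definite case; a definite non-case needs all three observed and below),
which leaves ≈ 70% of rows without a case definition. Item-level
nonresponse is independent across items given the demographics; real
nonresponse clusters within students more strongly, so the generator
yields somewhat fewer fully complete rows than a comparable real cohort
would have.

## Chained-equation imputation

`impute` is a from-scratch chained-equations engine. Each of the M
imputations initializes missing cells by draws from the variable's
observed margin, then performs `n_cycles` sweeps over the incomplete
variables in order of increasing missingness. Conditional models are
refitted each visit on an approximate-Bayesian-bootstrap resample of
the observed rows, which propagates parameter uncertainty without full
posterior machinery:

- continuous variables: predictive-mean matching with k = 5 donors
  (default; a parametric normal draw is available), robust to the
  skewed scale totals;
- two-level categoricals: the package's own ridge-stabilized IRLS
  logistic (penalty 10⁻³ so separation cannot abort a chain);
- multi-level categoricals: multinomial logistic regression
  (scikit-learn, light L2), falling back to observed-margin draws when
  any observed category has fewer than 10 rows (at that size donor
  strata would be empty, so the fallback is unstratified);
- the binary outcome is *passively* re-derived from the imputed scale
  totals through the case rule — it is a deterministic function of
  them, and passive imputation keeps every completed dataset internally
  consistent. `direct_outcome=True` switches to imputing the outcome as
  an ordinary binary variable.

Defaults follow the study design: M = 15 split 10 training /
5 validation, with the split deterministic by copy index. `n_cycles`
defaults to 10, the conventional chained-equations choice; the
reduced-scale profile uses 4 cycles, which the chain-mean diagnostics
(per-variable means by cycle, exposed on the result) show to be ample
for these simple conditional structures.

## Logistic core and stepwise selection

`fit_logistic` is plain maximum likelihood via IRLS: convergence at
max |Δβ| < 10⁻⁸ or 100 iterations, covariance from the inverse observed
information, separation flagged when any coefficient passes 15 during
iteration (with an optional fixed-ridge refit). `stepwise_select`
performs forward entry with backward elimination at p = 0.05 both ways,
using likelihood-ratio tests throughout: a multi-level item enters or
leaves as one block on k − 1 degrees of freedom, which is the natural
test when the published score table carries every non-reference level
of each retained item. Ties in p-values break lexicographically by item
name, so selection is fully deterministic.

## Instrument construction

Items selected in at least 70% of the training imputations are
retained. One logistic model containing exactly the retained items is
then refitted on *every* training imputation and each level's weight is
the across-refit mean coefficient. Averaging over refits on a common
covariate set (rather than over whichever stepwise models happened to
contain the item) keeps every averaged coefficient adjusted for the
same covariates; both readings of the construction are defensible and
the refit mode is the default. Weights are stored sign-flipped,
protective-positive (higher score = lower modeled risk), reference
levels exactly 0, and rounded to 2 decimals in the published-table
artifact while full-precision weights are kept for evaluation, so
rounding loss cannot leak into AUC or calibration estimates.

## Validation

Per validation imputation: AUC as the Mann–Whitney probability (ties
half-weighted) with DeLong placement-value standard errors, and the
calibration slope as the coefficient from regressing the outcome on the
risk-oriented linear predictor (the negated full-precision score), so
the ideal slope is +1 regardless of the protective orientation.
Estimates are pooled by Rubin's rules, T = W + (1 + 1/M)B with
(M − 1)(1 + W/((1 + 1/M)B))² degrees of freedom and t-based intervals.

Dichotomized diagnostics follow the published convention exactly: a
score *above* the cutoff is a *negative* test. Sensitivity/specificity
come from the 2×2 table on the pooled validation rows (rounded scores,
as a user of the printed table would compute); PPV/NPV from the table
or from a supplied prevalence via Bayes; LR⁺, LR⁻ and the diagnostic
odds ratio by their identities, exact at full precision. Confidence
intervals are logit-scale Wald for proportions and log-scale Wald for
ratios — the original report does not state its constructions, so these
are package choices. The Youden-optimal cutoff maximizes J over
midpoints of adjacent distinct scores (ties to the smaller cutoff) and
is always included in the diagnostics battery. Score-band likelihood
ratios use the published seven-band edges when they intersect the
instrument's score range and fall back to score quartiles otherwise;
empty-denominator bands report +inf alongside a +0.5-per-cell
continuity-corrected version.

The listwise-deletion arm drops every row with any missing analysis
variable (refusing to fit below 50 rows), runs the same stepwise /
score-construction path on the remainder, and is additionally evaluated
on the MI validation imputations so its calibration slope is directly
comparable with the MI arm's.

## Profiles and problem sizes

- `paper`: n = 2919, ~80 items (ten informative), M = 15 (10/5),
  10 cycles — the full-scale study conditions.
- `ci`: n = 1000, 3 informative + 5 noise items, M = 6 (4/2), 4 cycles.
  The informative effects (1.5–1.7 on common levels) are scaled up by
  ≈ √(2919/1000) relative to the strongest full-scale items so that
  per-replicate selection power at the smaller n matches the full-scale
  design; this profile is what the replicate-level property tests run.
- `contrast`: n = 2000, 3 informative + 15 noise items, 8% item
  missingness and 55/30/30% scale missingness loaded on residence
  status — a small, biased complete-case sample on which stepwise
  selection overfits, demonstrating the slope attenuation of listwise
  deletion.

Passing the reduced-scale suites shows the machinery is correct and
well calibrated under the generator's assumptions (single latent
factor, logistic item loadings, MAR); it does not certify performance
on real questionnaire data, where multidimensional risk, MNAR
nonresponse, and clustered school effects are all plausible.

## Numerical choices

Seeds: every stage derives its own seed from the master seed via a
fixed SeedSequence counter scheme recorded in the run manifest; equal
configurations give byte-identical artifacts. Missingness intercepts
and the outcome-percentile calibration use scalar root-finding
(`brentq`) on deterministic functions. Missing cells serialize as empty
CSV fields, and cohort CSVs are read back with round-trip float
parsing so re-serialization is byte-identical.
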