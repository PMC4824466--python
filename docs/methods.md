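# Methods

## Outcome model and standardization

The performance indicator is a binary patient outcome (death or
ADL-dependence at 3 months after stroke). Case-mix adjustment uses a
fixed-effects multiple logistic regression: patient covariates (age, sex,
consciousness level at admission, stroke subtype, smoking status, atrial
fibrillation, diabetes) plus one indicator effect ψ_h per hospital, with no
hospital–covariate interactions — hospital effects are assumed constant
across the case-mix. Reference levels are female / alert / hemorrhagic /
non-smoker / no AF / no diabetes; the reference hospital is the
lexicographically smallest id (the choice is arbitrary and cancels out of
every reported quantity). Effects (sum-to-zero) coding is also supported;
fitted risks, standardized risks and delta-method SEs are invariant to the
coding, and the exponentiated effects-coding hospital effects are the
hospital-versus-average odds ratios.

Direct standardization evaluates every hospital on the full study
population: R_h is the average counterfactual risk expit(β₀ + x_i'β + ψ_h)
over *all* n included patients. The population risk used in the benchmark
is deliberately the *crude observed* event proportion, not a model-based
quantity, and is recomputed per simulated data set.

## Fitting, separation, and the Firth fallback

Maximum likelihood is computed by Newton iterations with step-halving;
convergence requires the score's largest component below 1e-8 × max|X| (at
most 100 iterations). The covariance is the inverse observed Fisher
information at the optimum. A small hospital can separate (e.g. zero events
in a bootstrap resample); detection is via Newton failure, nonconvergence,
or any |ψ̂_h| > 10. The fallback is Firth's bias-reduced penalized
likelihood (score adjusted by hat-value leverages), which keeps all
hospitals in the analysis with finite estimates rather than dropping them;
the simulation engine counts penalized refits as a first-class output so
the behaviour is auditable. Wald CIs use z = 1.96 exactly; multi-level
factors additionally get one likelihood-ratio p-value per factor.

## Variance of R_h

The delta method over the MLE covariance: the gradient of R_h in θ is
(1/n) Σ_i p_ih(1−p_ih) x_i(h), with the hospital block of x_i(h) set to
hospital h's coding pattern. The derivation conditions on the observed
covariate sample (X treated as fixed); the extra variability from treating
the standardization population as random is not included. The resulting SEs
are validated in the test suite against a 500-resample parametric bootstrap
(15% relative tolerance on a 5-hospital fixture) and against the closed
binomial form √(p(1−p)/n) in the intercept-only case. One-sided lower
bounds R − Φ⁻¹(k)·SE may be negative for tiny hospitals and are not
clipped, only compared to the benchmark.

## Decision rule and diagnostics

Outlying ⇔ lower bound strictly exceeds B = (1+δ) × population risk; a
hospital exactly at B is acceptable (both in the rule and in the
gold-standard labels, which compare the original fit's point estimates to
the original benchmark). Diagnostics pool all hospital × replicate pairs
into one 2×2 table; because truth is fixed per hospital this equals
averaging per-replicate rates. Metrics with empty denominators are reported
as a distinguished undefined marker (`None` in the API, `undefined` in
exports), never NaN.

## Simulation study

A conditional parametric bootstrap: covariates and hospital assignments are
fixed; outcomes are redrawn as independent Bernoulli at the fitted risks;
each replicate is analyzed exactly like the original data, including its
own crude population risk and benchmark, with warm-started refits.
Replicate seeds are spawned from the plan seed by counter, so extending S
preserves earlier replicates.

## Synthetic registry: what it emulates and what it does not

The generator's defaults encode the published registry summaries:

- 76 hospitals; log-normal sizes with median 194 clipped to [27, 798]
  (`size_log_sd = 0.72` chosen so the clipped range is actually visited);
- age ~ normal(67.6, 9.5) truncated to [18, 80] — the SD is *derived* from
  the printed standard error (0.07 × √18309 ≈ 9.5), not itself a published
  value, and truncation pulls the realized mean to ≈ 65.8;
- categorical marginals from the followed-up cohort (male 58.9%, drowsy
  8.3%, unconscious 3.9%, ischemic 84.9%, unspecified 2.0%, smoking yes
  20.0% / unknown 7.4%, AF 18.2%, diabetes 19.6%), renormalized to sum to 1;
- outcome-model coefficients at the published point estimates;
- hospital effects ψ_h ~ normal(0, 0.25): a calibration choice putting most
  hospital odds ratios in 0.8–1.2 with tails near 0.3/1.8. It is a config
  field, never hard-coded downstream;
- optional completely-at-random loss to follow-up (13% when enabled; off by
  default) — informative dropout is out of scope.

Covariates are drawn independently of each other and identically across
hospitals (the source data showed similar case-mix across hospitals); the
generator therefore does not reproduce covariate correlations, hospital-level
case-mix extremes, or dropout informativeness. A green end-to-end test shows
the pipeline's internal consistency under this stated world, not agreement
with any confidential cohort: the published headline diagnostic table is not
reproducible without the original data, and only its qualitative pattern is
asserted.

Generated pooled event rates land near 20% (the observed rate of the
source cohort was 22.0%; the gap comes from generating covariates
independently at the published marginals and coefficients, which loses the
positive covariance between high-risk covariates present in real patients).

## Numerical and design choices

- Per-hospital generation streams are spawned from the root seed, so
  changing m leaves other hospitals' draws untouched.
- Inclusion filtering order is fixed: age window [18, 80] (defines
  n_eligible), then missing outcome, then missing non-smoking covariates;
  missing smoking becomes the `unknown` level.
- Missing tokens in text I/O: empty string and `NA`.
- The coverage/recovery analyses target the identified parameters: under
  reference coding the intercept estimates β₀ + ψ_ref and hospital
  coefficients estimate ψ_h − ψ_ref.
- The theoretical ROC planner's flag probability Φ((R−B)/SE − z_k) treats
  the benchmark as fixed; the empirical study re-estimates the benchmark
  per replicate, which introduces a small extra (partly cancelling)
  variance component. The planner's population risk defaults to the
  unweighted mean of supplied R values only when no crude risk is given.

## Known limitations

- Pooled specificity need not be monotone in δ: raising the margin moves
  borderline hospitals into the acceptable class, and those are the most
  likely to be wrongly flagged. On synthetic registries this produces small
  (≲0.01) systematic dips between adjacent δ values even though specificity
  at δ = 0.2 is far above δ = 0. The test suite asserts the strict property
  and therefore records this behaviour rather than hiding it.
- No random-effects or hierarchical hospital modelling, no indirect
  standardization, no multiple imputation, no three-way (better /
  acceptable / worse) classification.
- Exact (non-normal) confidence intervals for R_h are not provided.
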