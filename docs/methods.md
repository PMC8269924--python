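# Methods

## The estimand and the model

The analysis tracks entrants to the first core training level (CT1) and asks,
for each of the five annual transitions (CT1→CT2, CT2→CT3, CT3→ST4, ST4→ST5,
ST5→ST6), what fraction of those still "on schedule" fails to progress to the
next level in the next calendar year. "Fails to progress" deliberately
conflates slower progression, breaks, less-than-full-time working and
drop-out: anyone not at the expected level in the expected year has the
event. Cumulative survival S_t is therefore the probability of being on the
minimum-time track through transition t, and S_5 is the six-year completion
probability.

Because events can only happen at the five annual boundaries, the hazard is
modelled in discrete time: a Bernoulli likelihood on the person–period
dataset with a logit link,

    logit h_t(x) = β_t + x'γ.

The five period dummies are the intercepts (no global constant — a
configuration with a global intercept plus four dummies is refused rather
than silently reparameterised, so β_t always reads directly as the period-t
baseline log-odds). Covariates are person-constant, so each γ shifts every
period by the same amount: the proportional-odds property is structural, not
an assumption to verify. Event coding is 1 = "did not progress", so a
positive γ means a higher risk of stalling; completion-odds ratios are the
reciprocals exp(−γ).

Censoring is administrative and happens at period boundaries: a person
contributes every period they complete before the horizon year and is then
withdrawn. A consequence worth stating is that the Kaplan–Meier product-limit
estimator computed on the same person–period data multiplies exactly the same
factors 1 − d_t/n_t as the intercepts-only model baseline (whose MLE hazards
are d_t/n_t), so the two curves are identical by algebra. The test suite
asserts this at 1e-10; in practice it holds at machine epsilon. The actuarial
life table differs only through the half-withdrawal convention (withdrawals
counted with half an interval's exposure, effective denominator n_t − c_t/2).
That convention for boundary-censored persons is a documented choice of this
package, made to match the standard actuarial treatment in legacy statistical
software.

## Cohort construction rules

- **Entry**: a person's entry year is their *first* appearance at CT1. Only
  first appearances inside the entry window (default 2012–2017) qualify; a
  first appearance before the window disqualifies the person entirely
  (first-attempt rule), and stayer duplicates never create a second entry.
- **Person–period expansion**: for t = 1..5 the expected position is the
  (t+1)-th level in year entry + t. Present there → at-risk row, event 0;
  absent or anywhere lower/same → terminal event row; year past the horizon →
  no row (censored). A record *above* the expected level cannot occur in
  valid data (levels cannot be skipped) and raises a validation error rather
  than being guessed at.
- **Left truncation**: persons first seen at CT1 in the first data year may
  in truth have started earlier; they are kept, as the data cannot
  distinguish them. This slightly overstates on-time completion.
- The 2012–2013 entry subcohort has complete five-period follow-up by
  construction; the builder's tests assert it yields zero censored persons.
- Subcohort restrictions (e.g. UK graduates only) are applied at selection
  time, before person–period expansion, so a subcohort run equals a
  standalone run on the restricted records.

## The synthetic registry

The generator emulates the registry structure the analysis assumes: entry
years drawn from configurable weights (default uniform 2012–2017), horizon
2018, per-transition baseline hazards on the logit scale shifted by binary
person-level covariates, non-progressors either vanishing or lingering
("stayers") at their level for one or two further years, and per-covariate
completely-at-random missingness applied person-wise. One master seed is
split into independent substreams (entry, covariates, transitions, stayers,
missingness), so adding a covariate to a configuration never perturbs the
transition draws — a property the tests pin down.

The bundled scenario preset (`published_cohort_scenario`) encodes the study
conditions this pipeline is designed around: 2820 trainees; women 59.6% with
non-progression log-odds ln 1.49; non-UK graduates 32.4% with ln 2.16; BME
ethnicity, disability, free school meals, area deprivation and the smaller
socioeconomic effects at ln 1.295, ln 2.766, ln 1.936, ln 1.48 and ~ln 1.1
respectively, with realistic prevalences where no published figure exists;
a positive association between childhood free school meals and area
deprivation; stayer probability 0.10; and per-covariate missingness rates
that compound to roughly a 25% complete-case loss on the socioeconomic
covariates. The reference-pattern baseline hazards (0.107, 0.107, 0.394,
0.107, 0.107) were calibrated once, by simulation at n = 150 000, so that the
*marginal* univariate analysis of a generated cohort reproduces the headline
conditions — six-year completion ≈ 17.2%, a core→specialty bottleneck hazard
≈ 57.1%, highest hazard at t = 3 — given the configured covariate mix; they
are frozen in the preset.

What the generator does *not* emulate: entry-year (cohort) effects, so the
2012–2013 subcohort has the same expected curves as the main cohort here,
whereas real cohorts can drift; informative missingness; extended (> 3-year)
specialty programmes; correlations among covariates beyond the single
configurable pairwise-association knob; and any trainee-level time-varying
covariates. Passing tests on this generator therefore demonstrate
correctness of the estimators and pipeline mechanics, not robustness to
those real-data features.

## Numerical choices

- **Optimiser**: damped Newton (IRLS) on the exact Bernoulli log-likelihood,
  starting from zero, step-halving on any −2LL increase. Convergence when
  the largest score component drops below 1e-8; a relative −2LL stagnation
  guard (1e-14) stops runs that can no longer improve in double precision,
  and flags them unconverged unless the score is already below 1e-6.
  Iteration cap 100. The gradient-based criterion is what makes the
  saturated-model oracle (fitted hazards = d_t/n_t to 1e-8) and the
  KM/baseline identity hold to the asserted tolerances.
- **Covariance**: inverse observed information at the optimum (equal to the
  expected information under the canonical logit link). Wald 95% CIs use the
  1.96 normal quantile; CIs are log-symmetric around the OR by construction.
- **Degenerate designs**: constant columns and collinear column sets are
  detected by inspection and SVD before fitting and raised as named
  rank-deficiency errors; a missing period (no rows at some t) is likewise a
  named error, because the five-dummy parameterisation requires all periods.
  Coefficients exceeding 15 in absolute value trigger a
  separation warning and mark the fit suspect instead of failing silently.
- **Complete cases**: rows missing any *requested* covariate are dropped per
  model, and the dropped row/person counts are carried on the fit object, so
  different model specifications legitimately use different denominators.
- **Pseudo-R²**: both Cox–Snell, 1 − exp((D_full − D_null)/n), and
  Nagelkerke (Cox–Snell divided by its maximum), computed against the
  time-dummies-only null on the same rows. Both are reported because the
  unlabelled R² convention differs between software packages.
- **Interaction rule**: a term enters the final model when its Wald p < 0.05
  *or* the −2LL improvement is ≥ 4; the threshold is inclusive, and the
  significance arm uses the Wald test by default (a likelihood-ratio test is
  available through `lr_test`).

## Disclosure control

Published counts pass through the rounding rules (0, 1, 2 → 0; otherwise
nearest multiple of 5 — unique for integer counts, and non-integer inputs
are rejected); percentages are suppressed when the unrounded base is below
22.5 persons, averages when based on seven or fewer. Suppression thresholds
are evaluated on unrounded bases, since a threshold of 22.5 is meaningless
after rounding to multiples of 5. Disclosure is applied only at the
reporting boundary; all internal computation uses raw values.

## Problem sizes used by the test and acceptance runs

Generator closed-form checks use n = 20 000 (Monte-Carlo error ±0.009 on a
completion probability of 0.25); the saturated-model oracle and KM identity
use n = 5000; parameter recovery uses the full scenario at n = 20 000 with a
3-standard-error band; frequentist calibration uses 200 replicates at
n = 5000, asserting pooled 95% CI coverage in [0.90, 0.98] and a null-covariate
likelihood-ratio rejection rate in [0.03, 0.07] at α = 0.05. The acceptance
script runs the pipeline at the published cohort size, n = 2820.

## Known limitations

- The event definition cannot separate drop-out from slower progression;
  estimated "survival" is on-time progression, not retention.
- Wald inference can be anti-conservative in small strata (the observed
  replicate coverage sits near 0.93); profile-likelihood intervals are not
  implemented.
- The life-table c/2 convention is one of several defensible treatments of
  boundary censoring; alternatives would change its (small) deviation from
  the product-limit curve.
- Missingness is handled by complete-case deletion only, matching the target
  analysis; no imputation machinery is provided.
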