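# trainsurv

Discrete-time survival analysis of multi-stage postgraduate training
progression.

Medical training programmes in the UK move trainees through ordered annual
levels — three core psychiatry years (CT1–CT3) followed by three specialty
years (ST4–ST6). A national registry observes each trainee once a year, so
the natural question "what fraction of entrants completes training in the
minimum six years, and where do they stall?" is a *discrete-time* survival
problem: the event ("did not progress to the next level on time") can occur
only at the five annual transitions, follow-up is administratively cut at the
study horizon (right censoring), and covariates such as gender, region of
primary medical qualification (PMQ), ethnicity or childhood deprivation may
shift the per-transition risk.

`trainsurv` implements that analysis end to end, for workforce researchers
and medical-education analysts who have (or want to emulate) person-year
registry extracts:

- **synthetic registry generator** — annual observation records with
  configurable entry years, per-transition hazards, covariate effects on the
  hazard logit, "stayer" duplicates, administrative censoring and
  missingness, so the whole pipeline is testable without restricted data;
- **cohort builder** — first-attempt entry selection, stayer de-duplication,
  person–period expansion, risk tables;
- **discrete-time hazard model** — logistic regression of the person–period
  event indicator on five time dummies (entered as the intercepts; no global
  constant) plus covariates, giving hazards h_t, survival
  S_t = ∏_{j≤t}(1 − h_j), odds ratios with Wald 95% CIs, likelihood-ratio
  tests, Cox–Snell/Nagelkerke pseudo-R², and the interaction-inclusion rule
  (keep a term when significant or when −2LL improves by ≥ 4);
- **sensitivity estimators** — Kaplan–Meier (identical to the model baseline
  by construction with annual boundary censoring) and the actuarial life
  table with the half-withdrawal convention;
- **disclosure control** — HESA-style rounding (0/1/2 → 0, else nearest
  multiple of 5) and suppression of percentages (base < 22.5) and averages
  (base ≤ 7) at the reporting boundary.

## The model

With person–period rows (one per person per year at risk) and event
indicator y = 1 for "did not progress on time",

    logit P(y = 1 | t, x) = β_t + x'γ,   t = 1..5,

where β_t are the five period intercepts and γ the covariate log-odds,
constant over periods (proportional odds by construction). The baseline
hazard is h_t = expit(β_t), a covariate pattern's curve is
h_t(x) = expit(β_t + x'γ), and cumulative survival — the probability of
still progressing on schedule — is the product of (1 − h_j). Fitting the
intercepts-only model reproduces the empirical event proportions d_t/n_t
exactly (saturated-model MLE), which doubles as an internal correctness
oracle.

## Worked example

```python
import numpy as np
import trainsurv as ts

cfg = ts.published_cohort_scenario(n_trainees=2820, seed=0)
records = ts.generate_cohort(cfg)
spec = ts.CohortSpec()                      # CT1 entrants 2012-2017, horizon 2018
cohort = ts.select_entry_cohort(records, spec)
pp = ts.build_person_period(records, cohort, spec)

base = ts.baseline_hazards(ts.fit(pp))      # univariate: time dummies only
print("per-period hazard of not progressing:", base.hazards.round(3))
print("cumulative survival (on-time progression):", base.survival.round(3))
print(f"six-year completion: {100*base.survival[-1]:.1f}%")

m = ts.fit(pp, covariates=["gender", "pmq_region"])
for e in ts.effect_estimates(m):
    print(f"{e.name} ({e.contrast}): completion OR = {1/e.odds_ratio:.3f}, "
          f"95% CI {1/e.ci_high:.3f}-{1/e.ci_low:.3f}, p = {e.p_value:.2g}")

km = ts.km_estimate(pp, max_time=5)
print("max |KM - model survival|:", float(np.max(np.abs(km.survival - base.survival))))
```

prints

```
per-period hazard of not progressing: [0.252 0.215 0.542 0.175 0.221]
cumulative survival (on-time progression): [0.748 0.587 0.269 0.222 0.173]
six-year completion: 17.3%
gender (female vs male): completion OR = 0.678, 95% CI 0.602-0.764, p = 1.7e-10
pmq_region (non-UK vs UK): completion OR = 0.497, 95% CI 0.439-0.562, p = 8.1e-29
max |KM - model survival|: 5.551115123125783e-16
```

Reading: about a quarter of entrants stall at each core transition, more
than half stall at the core→specialty bottleneck (h₃ = 0.542), and only
17.3% of this simulated cohort completes in six years. The fitted effects
are on the event (non-progression) scale; their reciprocals, printed above,
are completion-odds ratios — women and non-UK graduates have lower odds of
completing on time, by construction of the scenario. The Kaplan–Meier curve
agrees with the model baseline to machine precision, as it must with annual
boundary censoring.

The same stages are available as a CLI:

```
trainsurv simulate --seed 0 --out records.csv
trainsurv build --records records.csv --entry-window 2012 2017 --out build/
trainsurv fit --person-periods build/person_periods.csv \
              --covariates gender,pmq_region --out fit.json
trainsurv sensitivity --person-periods build/person_periods.csv --out sens/
trainsurv report --seed 0 --out run/        # full pipeline + manifest
```

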