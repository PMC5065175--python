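# disabsurvey

Multi-instrument disability measurement for population-based cluster
surveys.

## The problem

Population surveys measure disability in two largely disjoint ways:
**self-reported functional limitation** (graded difficulty — none / some /
a lot / cannot do — across core domains such as seeing, hearing, walking,
self-care, remembering), and **clinical impairment screening** (visual
acuity, pure-tone audiometry, musculoskeletal examination, seizure history,
depression symptoms). The two identify overlapping but different people: a
person with a moderate hearing loss may report no difficulty at all (the
"hierarchy of disability" — impairments felt as less critical to daily
participation go unreported), while another may report severe limitations
with no screenable impairment.

This package implements the full measurement pipeline of an all-age
two-country survey (North-West Cameroon 2013, Telangana State India 2014;
51 clusters × 80 people per country) built around exactly that comparison,
for epidemiologists and survey methodologists who want to reuse, stress-test
or extend the approach:

* **instrument scoring** (`instruments`) — graded severity from raw screen
  results: Snellen acuity cut-offs 6/18, 6/60, 3/60 (better eye,
  presenting); better-ear audiometry at 35 (children) / 41 (adults), 61 and
  81 dBA; physiotherapist-graded musculoskeletal impairment; ≥3 generalised
  tonic-clonic seizures in 12 months; PHQ-9 bands; Washington-Group style
  domain scoring; summed participation-restriction scores.
* **composite case definitions** (`case_classification`) — a *case* either
  reports "a lot of difficulty"/"cannot do" in ≥1 core domain
  (self-reported) or screens positive for a moderate-or-worse impairment or
  a severe disabling health condition (clinical). Cases decompose into
  Category A (self-report only), B (both), C (clinical only), and a
  two-stage strategy — self-report screen, clinical work-up of everyone
  reporting at least "some" difficulty — is evaluated against the composite
  case set.
* **survey statistics** (`survey_stats`) — sample-size calculation
  (n = z²p(1−p)/(εp)² × deff/(1−loss)), systematic PPS cluster selection,
  compact-segment sampling, and cluster-robust prevalence estimation with
  Taylor-linearised variance
  var(p̂) = k/(k−1)·Σᵢ(yᵢ−p̂mᵢ)²/(Σmᵢ)², logit-scale t(k−1) confidence
  intervals, and design-effect reporting.
* **synthetic cohorts** (`synthetic_cohort`) — a generative model of the
  survey (age-graded latent impairment, severity ladders, measurement
  noise, an ordered-logit reporting model with sensory under-reporting,
  cluster and frailty random effects, non-response) plus closed-form
  analytic expectations used as a parameter-recovery oracle.
* **agreement analyses** (`agreement_analysis`) — severity-by-report
  cross-tabulations, logistic regression for predictors of concordance,
  participation-score comparisons (pooled t-tests), and case-definition
  sweeps.
* **I/O and CLI** (`cli_io`) — a validated CSV data dictionary, a YAML
  pipeline driver, and the `disabsurvey` command with subcommands
  `simulate`, `classify`, `estimate`, `agree`, `report` and `paper-checks`.

## Worked example

```bash
disabsurvey report --config examples/config.yaml
```

simulates one Cameroon-like cohort at the design scale and runs the whole
analysis. The generated `demo_run/report.md` reads:

```
Country: cameroon; seed 1; n = 3569; clusters = 51

## Cases
- total cases: 348 (A 65 / B 124 / C 159)
- self-reported: 189; clinical: 283

## Prevalence (cluster-robust 95% CI)
- overall: 9.8% (8.5-11.2), deff 1.75
- self_reported: 5.3% (4.4-6.3), deff 1.50
- clinical: 7.9% (6.8-9.2), deff 1.64

## Two-stage strategy (screen at 'some difficulty')
- identifies 331 of 348 cases (sensitivity 95.1%), clinical screens needed: 940
```

Reading this: 9.8% of the simulated population are disability cases under
the composite definition; clinical screening finds more people (283) than
self-report (189), and fewer than half of all cases (124 of 348) are found
by both routes. Asking everyone first about difficulty and clinically
screening the 940 people (26%) who report at least "some" captures 95% of
all cases — the central methodological result the pipeline is designed to
quantify. The same analyses are available as library calls
(`generate_cohort`, `grade_cohort`, `classify_cohort`,
`estimate_prevalence`, `evaluate_two_stage_strategy`, ...) on any
participant CSV that follows the data dictionary.

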