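# Methods

## Measurement model

A participant's disability status is assessed on two routes that the
package keeps strictly separate until the final decomposition.

**Self-report.** Graded difficulty (none < some < a lot < cannot do) is
recorded per functional domain. Core domains are age-specific: children
(2–17) — seeing, hearing, walking, self-care, understanding, being
understood, learning, remembering; adults (18+) — seeing, hearing,
walking/climbing, understanding, being understood, remembering,
concentrating, self-care, upper body strength, fine motor dexterity.
Non-core domains (pain, fatigue, anxiety, depression) are recorded but
never enter any case definition. The primary self-report case definition
is "a lot of difficulty" or "cannot do" in at least one core domain; the
threshold level and the minimum number of qualifying domains are exposed
so that expanded definitions ("some in any domain", "some in any two")
are the same code path. Ages 0–1 have no instrument and are never
self-report cases.

**Clinical screening.** Each screen maps raw measurements to an ordered
severity grade (none < mild < moderate < severe < profound):

| screen | measurement | grade cut-offs |
|---|---|---|
| vision (5+) | presenting Snellen acuity, better eye | <6/18 moderate, <6/60 severe, <3/60 profound (lower bounds inclusive) |
| vision (<2, 2–4) | fix-and-follow / finger counting | fail → impaired-unclassified |
| hearing (4+) | better-ear pure-tone average after bilateral OAE failure | children <35 dBA none, 35–60 moderate, 61–80 severe, >80 profound; adults none <41 dBA |
| hearing (0–3) | OAE only | bilateral fail → impaired-unclassified |
| musculoskeletal | physiotherapist examination after positive report screen | none/mild/moderate/severe (no profound level) |
| epilepsy | reported generalised tonic-clonic seizures, 12 months | ≥3 → case |
| depression (18+) | PHQ-9 composite 0–27 | 0–4 / 5–9 / 10–14 / 15–19 / 20–27 |

A clinical case has any impairment grade ≥ moderate (impaired-unclassified
counts, since the infant screens are designed to fire at that level), or
epilepsy, or depression at or above a configurable band. The PHQ-9 band at
which depression counts as a "severe disabling health condition" is not
fixed by the source material; the default is moderately-severe (composite
≥ 15), set by `ClassificationConfig.depression_case_band`. The child/adult
boundary for audiometric thresholds is the 18th birthday, independent of
the country-specific consent ages used for the self-report respondent
rules (caregiver 2–7; child self-report to 17 in India, 20 in Cameroon).

Cases split into Category A (self-report only), B (both), C (clinical
only); A+B+C = cases holds by construction and is property-tested. A
record missing one clinical screen remains classifiable on the others and
carries a `partial_screening` flag; severity-specific analyses exclude
unclassified or missing severity and report the excluded count.

## Survey statistics

The design is self-weighted two-stage cluster sampling: systematic
probability-proportionate-to-size selection of clusters from a census
frame (units larger than the sampling interval can be selected more than
once), then one compact segment per cluster, with the segment count equal
to round-half-up(population / 80), minimum 1. The sample-size formula is
n = z²p(1−p)/(εp)²·deff/(1−nonresponse) with z the exact standard-normal
quantile and ε interpreted as *relative* precision. At the survey's
planning inputs (p = 4%, ε = 20%, 95% confidence, deff 1.4, 20%
non-response) this gives 4,034; the survey's own planning figure was
4,056, a ~0.5% difference whose rounding path is not recoverable from the
published description.

Prevalence uses the plain sample proportion (the design is self-weighted;
the point estimate is provably independent of the clustering). The
variance is the between-cluster Taylor-linearised estimator
var(p̂) = k/(k−1)·Σ(yᵢ−p̂mᵢ)²/(Σmᵢ)² with k clusters, and the default 95%
CI is a logit-scale Wald interval with a t(k−1) quantile, matching the
default behaviour of standard survey software; a plain Wald interval is
available by flag. Degenerate inputs: a single cluster yields a flagged
estimate with undefined CI; p̂ ∈ {0, 1} reports the point with a
degenerate CI and a design effect of 1 by convention. This estimator is
implemented here directly (no installed Python package provides
design-based survey estimation); it is validated against hand-computed
worked examples, a 500-replicate coverage study (93–97% nominal band) and
a null-clustering design-effect check.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested; its defaults are fixed and are not per-analysis knobs.

* **Design**: 51 clusters × 80 enumerated per country; response rate 0.87
  (Cameroon) / 0.88 (India); clusters drawn by PPS from a synthetic
  lognormal census frame, one compact segment each.
* **Demographics**: ten-year age-band probabilities shaped like the two
  samples (Cameroon young — 35% under 10; India older), uniform age within
  band; female fraction 0.59 / 0.52.
* **Latent impairment**: per domain d ∈ {vision, hearing, musculoskeletal},
  P(any impairment) = expit(αd + β·age + f + u) with shared age slope
  β = 0.07 per year, domain intercepts α = −7.3 / −7.0 / −6.2, person
  frailty f ~ N(0, 0.5²) (comorbidity: one parameter governing the
  multiple-impairment rate) and cluster effect u ~ N(0, 0.5²). Conditional
  severity ladders: vision 0.70/0.13/0.17 over moderate/severe/profound
  (the acuity chart has no mild band), hearing 0.72/0.18/0.10,
  musculoskeletal 0.45/0.45/0.10 over mild/moderate/severe. The intercepts
  were chosen once so the age-marginalised expectations give all-age
  prevalences of the magnitude the survey reported (clinical ≈ 8–10%,
  overall ≈ 9–11%) with the steep age gradient both countries showed; the
  same impairment model serves both countries, whose realised differences
  then arise from demography alone — the direction the survey observed
  (older population, higher prevalence).
* **Measurements from latent grades** are invertible transforms plus
  in-band noise: decimal acuity uniform within the grade's Snellen
  interval, PTA uniform within the grade's decibel band, infant screens
  failing iff the latent grade is ≥ moderate, examination grades passed
  through. Classifying the generated measurements therefore recovers the
  latent grade wherever the screen determines severity, which is asserted
  as a test.
* **Reporting**: for domains with a matched screen, an ordered-logit draw
  with P(report ≥ level j) = expit(2.8·grade + 0.02·(age−50) − cⱼ − offset),
  cutpoints (2.5, 7.0, 9.2) and a sensory under-reporting offset of 1.2
  log-odds on seeing/hearing. Under these defaults a moderate sensory
  impairment most often yields "some difficulty" rather than "a lot" —
  the reporting hierarchy that produces a large clinical-only Category C —
  while moderate physical impairment is reported more readily. Unmatched
  core domains use background cutpoints (3.4, 5.2, 7.5) with age slope
  0.03; epilepsy adds 2.5 log-odds and each PHQ-9 band unit 0.8 log-odds
  to background reporting, so health conditions surface as limitations in
  domains no screen matches (one source of Category A, alongside mild
  impairments). No quantitative reporting-behaviour parameters exist to
  copy; these values reproduce the qualitative overlap structure, not its
  exact percentages, and the two-stage/“a lot”-only sensitivity contrast.
* **Cluster effect SD 0.5** was calibrated so the realised design effect of
  the composite case indicator averages ≈ 1.4 at the design's cluster
  size — the value the survey's own sample-size calculation assumed.
* **Participation** (cases only): item scores 1 + Binomial(3, expit(r))
  per item, 15 items under 17 years / 21 items from 17, with
  r = −2.0 + 0.30·max grade + 0.55·self-reported + N(0, 0.4²), so
  restriction rises with both severity and reporting and Category B is the
  most restricted adult group.
* **Single question** ("do you consider yourself to have a disability") is
  generated for India only: P(yes) = expit(−5 + 3.0·self-reported +
  2.2·clinical), emulating heavy under-identification.
* **Analytic expectations** marginalise the model over the age grid
  (1-year midpoints) and frailty (31-node Gauss–Hermite), with cluster
  effects at their mean: exact when the cluster SD is zero, first-order
  otherwise. They are the oracle for parameter recovery (clinical
  prevalence within 2 Monte-Carlo SEs over 200 replicate cohorts).

What the generator does **not** emulate: household structure and
geography; cause-of-impairment; measurement error in the screens beyond
in-band noise (no false OAE positives from ambient noise, no refraction
effects); country-specific reporting culture (one shared reporting model);
item-level participation content. Passing tests therefore show the
pipeline's internal consistency and its behaviour under a plausible data
generating process, not field validity of the instruments.

## Agreement analyses

The severity-by-report cross-tabulation takes, per person aged 5+, the
most severe classified grade across the three screened domains (columns
none/mild/moderate/severe-profound) against the maximum reported level in
the matched domains (rows none/some/a lot-cannot); matched domains are
seeing, hearing, plus walking (children) or walking-climbing, upper body
strength and fine motor (adults) — children's modules carry no upper-body
or fine-motor items, so their physical match is walking only (a
documented choice, configurable in the matching tables). Records with any
missing or unclassified severity are excluded and counted.

Concordance regression fits, among clinical cases, a maximum-likelihood
logistic model (statsmodels, Newton) of also being a self-reported case on
age band (2–17, 18–33, 34–49 ref, 50–65, 66+), sex, severity
(moderate ref / severe / profound, missing-severity records excluded) and
impairment type (vision ref / musculoskeletal / hearing / epilepsy /
multiple, ties broken vision < hearing < musculoskeletal and "multiple" =
≥2 at case level taking precedence). Depression-only cases are excluded
by default (sparse, and they carry no impairment severity or type). Empty
dummy levels are dropped so the Hessian stays regular; separation
(|coefficient| > 15 or non-finite SE) flags the term instead of printing a
meaningless CI. On any saturated 2×2 the fitted OR equals the
cross-product ratio to 1e-6, which is the oracle test.

Participation comparisons use pooled-variance (Student) t-tests — the
analysis the survey named — for Category A vs B and B vs C, children
(5–16) and adults (17+) separately; Welch is available via
`scipy.stats.ttest_ind(equal_var=False)` on the same score frame. Groups
with fewer than two observations yield NaN rather than a test.

## Published-count arithmetic

The survey deposited no microdata, so exact reproduction is limited to
arithmetic on printed counts (`disabsurvey paper-checks`): overall
prevalence (373/3567 → 10.5%, 437/3574 → 12.2%), ages 50+ (214/636,
256/668), the A/B/C decomposition by inclusion–exclusion (B = self +
clinical − cases), cross-tab row percentages, and the severe-vs-moderate
crude odds ratio (19·136)/(9·73) = 3.93. Two printed figures are not
arithmetic consequences of the printed counts and are asserted at their
computed values instead: the Cameroon Category B share (118/373 = 31.6%
→ 32, printed 33 — the decomposition B = 118 itself matches the published
regression table) and one Cameroon cross-tab cell (3/1643 = 0.2% → 0,
printed 1, apparently a display floor). Printed sub-prevalences such as
5.9%/8.4% (Cameroon) are not ratios of any printed numerator/denominator
pair and are not asserted. Percentages round half-up, matching the tables.

## Numerical choices and problem sizes

Ordered-categorical draws use a single uniform against the cumulative
probabilities; all generation flows from one master `SeedSequence` with
independent substreams for census, segments and persons, so a (config,
seed) pair is byte-reproducible. Tests run at reduced scales chosen for a
quick default suite: parameter recovery uses 200 replicates of 12×40
cohorts; design-effect checks average 20 full-scale cohorts; the CI
coverage study uses 500 replicates of 51×70 beta-binomial cohorts; the PPS
frequency test uses 5×10⁴ replicates with a χ² goodness-of-fit at α=0.01.
The acceptance script averages 12 full-scale cohorts per country for its
stochastic quantities (the realised design effect has a replicate SD of
about 0.3).

## Known limitations

* The concordance ORs from the original survey are not reproducible
  without its microdata; the package reproduces the crude 2×2 arithmetic
  and the qualitative severity/type gradients only.
* The analytic expectations ignore the cluster effect's higher moments;
  with the default cluster SD they are a close but not exact expectation
  (the recovery test therefore runs with cluster effects off).
* India's realised Category B share under the shared reporting model sits
  below its Cameroon counterpart, whereas the survey found the opposite
  ordering between countries; matching that would require country-specific
  reporting parameters the source does not provide.
* The single-question model is a two-parameter logistic chosen to emulate
  under-identification; it has no validated behavioural basis.
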