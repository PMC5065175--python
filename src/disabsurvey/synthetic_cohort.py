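"""Synthetic survey cohorts with the statistical structure the analysis assumes.

The study's microdata are not public, so every pipeline stage is exercised
on generated cohorts that emulate the survey's design and the qualitative
behaviour of its population:

* two-stage sampling — PPS selection of clusters from a synthetic census
  frame, one compact segment per cluster, a fixed number enumerated per
  segment, and Bernoulli non-response;
* demographics — age drawn from piecewise age-band probabilities shaped
  like the two survey samples (one young, one older), with a configurable
  female fraction;
* latent impairment — per-domain (vision / hearing / musculoskeletal)
  impairment indicators with logistic age gradients, a shared person-level
  frailty (comorbidity) and a shared cluster effect (intra-cluster
  correlation), plus a conditional severity ladder per domain;
* measurements — deterministic-plus-noise transforms of the latent grade
  (acuity uniform within the grade's Snellen interval, PTA uniform within
  the grade's decibel band, infant screens failing iff latent >= moderate);
* reporting — an ordered-categorical model whose cumulative log-odds shift
  with latent grade, domain and age.  Sensory domains carry an
  under-reporting offset (the "hierarchy of disability"): by default a
  moderate sensory impairment most often yields "some difficulty", not
  "a lot", so a large clinical-only category arises;
* participation — item-level restriction responses whose propensity rises
  with both clinical severity and reporting, collected for cases only.

``analytic_expectations`` returns closed-form (age- and frailty-
marginalised) expected prevalences per instrument and per case definition,
exact when the cluster effect is zero; it is the oracle for parameter
recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from . import case_classification as cc
from .instruments import SeverityGrade
from .survey_stats import compact_segment_sample, pps_select_clusters

__all__ = [
    "DomainModel",
    "ReportingModel",
    "CohortConfig",
    "ExpectedPrevalences",
    "default_config",
    "generate_cohort",
    "analytic_expectations",
]


def _expit(x):
    return special.expit(x)


@dataclass(frozen=True)
class DomainModel:
    """Latent impairment model for one clinical domain.

    P(any impairment | age, frailty f, cluster effect u) =
    expit(base_logodds + age_slope * age + f + u); conditional on
    impairment, severity follows ``ladder`` (probabilities summing to 1).
    """

    base_logodds: float
    age_slope: float
    ladder: tuple[tuple[SeverityGrade, float], ...]

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.ladder)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("severity ladder probabilities must sum to 1")
        if any(p < 0 for _, p in self.ladder):
            raise ValueError("severity ladder probabilities must be non-negative")

    @property
    def case_fraction(self) -> float:
        """P(grade >= moderate | impaired)."""
        return sum(p for g, p in self.ladder if g >= SeverityGrade.MODERATE)


@dataclass(frozen=True)
class ReportingModel:
    """Ordered-categorical reporting of difficulty given latent grade.

    P(report >= level_j | grade g, age) = expit(grade_coef * g
    + age_coef * (age - age_ref) - cutpoints[j] - offset), where ``offset``
    is the sensory under-reporting penalty for seeing/hearing reports.
    """

    cutpoints: tuple[float, float, float] = (2.5, 7.0, 9.2)
    grade_coef: float = 2.8
    age_coef: float = 0.02
    age_ref: float = 50.0

    def __post_init__(self) -> None:
        if not (self.cutpoints[0] < self.cutpoints[1] < self.cutpoints[2]):
            raise ValueError("cutpoints must be strictly increasing")

    def prob_at_or_above(self, grade: float, age, offset: float = 0.0) -> np.ndarray:
        """P(report >= level) for levels (SOME, A_LOT, CANNOT_DO); vectorised over age."""
        eta = self.grade_coef * grade + self.age_coef * (np.asarray(age) - self.age_ref) - offset
        return _expit(eta[..., None] - np.asarray(self.cutpoints))


# Latent severity ladders.  Vision has no graded "mild" band (the acuity
# chart grades start at moderate); hearing likewise; the musculoskeletal
# examination grades mild impairment, which feeds the self-report-only
# category.
_VISION_LADDER = (
    (SeverityGrade.MODERATE, 0.70),
    (SeverityGrade.SEVERE, 0.13),
    (SeverityGrade.PROFOUND, 0.17),
)
_HEARING_LADDER = (
    (SeverityGrade.MODERATE, 0.72),
    (SeverityGrade.SEVERE, 0.18),
    (SeverityGrade.PROFOUND, 0.10),
)
_MSI_LADDER = (
    (SeverityGrade.MILD, 0.45),
    (SeverityGrade.MODERATE, 0.45),
    (SeverityGrade.SEVERE, 0.10),
)

# Age-band probabilities shaped like the two survey samples (bands of ten
# years, 0-9 ... 80+).
_AGE_EDGES = (0, 10, 20, 30, 40, 50, 60, 70, 80, 91)
_AGE_PROBS = {
    "cameroon": (0.35, 0.23, 0.11, 0.07, 0.06, 0.06, 0.05, 0.04, 0.03),
    "india": (0.19, 0.19, 0.18, 0.14, 0.11, 0.09, 0.07, 0.02, 0.01),
}


@dataclass(frozen=True)
class CohortConfig:
    """All generative parameters for one synthetic survey cohort."""

    country: str = "cameroon"
    n_clusters: int = 51
    cluster_size: int = 80
    response_rate: float = 0.87

    age_band_edges: tuple[int, ...] = _AGE_EDGES
    age_band_probs: tuple[float, ...] = _AGE_PROBS["cameroon"]
    female_frac: float = 0.59

    vision: DomainModel = field(
        default_factory=lambda: DomainModel(-7.3, 0.07, _VISION_LADDER)
    )
    hearing: DomainModel = field(
        default_factory=lambda: DomainModel(-7.0, 0.07, _HEARING_LADDER)
    )
    msi: DomainModel = field(default_factory=lambda: DomainModel(-6.2, 0.07, _MSI_LADDER))

    epilepsy_prev: float = 0.007
    #: Adult PHQ-9 band probabilities (none, mild, moderate, moderately_severe, severe).
    depression_band_probs: tuple[float, ...] = (0.90, 0.06, 0.03, 0.007, 0.003)

    reporting: ReportingModel = field(default_factory=ReportingModel)
    #: Extra log-odds penalty on reporting difficulty in seeing/hearing
    #: (the "hierarchy of disability" under-reporting of sensory loss).
    sensory_underreport: float = 1.2
    #: Cutpoints for core domains with no matched clinical screen
    #: (understanding, remembering, ...) and for the non-core domains.
    background_cutpoints: tuple[float, float, float] = (3.4, 5.2, 7.5)
    background_age_coef: float = 0.03
    noncore_cutpoints: tuple[float, float, float] = (1.8, 4.5, 6.5)
    #: Log-odds boost to background-domain reporting (understanding,
    #: remembering, ...) for people with epilepsy, and per PHQ-9 band unit
    #: for depression: disabling health conditions surface as reported
    #: limitations in domains with no matched clinical screen.
    epilepsy_report_boost: float = 2.5
    depression_report_boost: float = 0.8

    frailty_sd: float = 0.5
    cluster_sd: float = 0.5

    part_base: float = -2.0
    part_sev_coef: float = 0.30
    part_rep_coef: float = 0.55
    part_noise_sd: float = 0.40

    collect_single_question: bool = False
    sq_base: float = -5.0
    sq_self_coef: float = 3.0
    sq_clin_coef: float = 2.2

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cluster_size < 1:
            raise ValueError("n_clusters and cluster_size must be positive")
        if not 0 < self.response_rate <= 1:
            raise ValueError("response_rate must be in (0, 1]")
        if len(self.age_band_probs) != len(self.age_band_edges) - 1:
            raise ValueError("age_band_probs must have one entry per band")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        if any(p < 0 for p in self.age_band_probs):
            raise ValueError("age_band_probs must be non-negative")
        if not 0 <= self.female_frac <= 1:
            raise ValueError("female_frac must be in [0, 1]")
        if not 0 <= self.epilepsy_prev < 1:
            raise ValueError("epilepsy_prev must be in [0, 1)")
        if len(self.depression_band_probs) != 5 or abs(sum(self.depression_band_probs) - 1) > 1e-9:
            raise ValueError("depression_band_probs must be 5 probabilities summing to 1")
        if self.frailty_sd < 0 or self.cluster_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")


def default_config(country: str = "cameroon", seed: int = 0) -> CohortConfig:
    """Study-condition defaults for one of the two countries.

    The impairment model is shared; the countries differ in demographics
    (age structure, sex ratio), response rate, epilepsy/depression rates and
    whether the direct single disability question was asked (India only).
    """
    country = country.lower()
    if country == "cameroon":
        return CohortConfig(country="cameroon", seed=seed)
    if country == "india":
        return CohortConfig(
            country="india",
            response_rate=0.88,
            age_band_probs=_AGE_PROBS["india"],
            female_frac=0.52,
            epilepsy_prev=0.018,
            depression_band_probs=(0.88, 0.07, 0.030, 0.013, 0.007),
            collect_single_question=True,
            seed=seed,
        )
    raise ValueError(f"unknown country: {country!r}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_PHQ_BAND_RANGES = ((0, 4), (5, 9), (10, 14), (15, 19), (20, 27))
#: Decimal-acuity sampling intervals per latent vision grade.
_ACUITY_RANGES = {
    int(SeverityGrade.NONE): (6 / 18, 1.2),
    int(SeverityGrade.MODERATE): (6 / 60, 6 / 18),
    int(SeverityGrade.SEVERE): (3 / 60, 6 / 60),
    int(SeverityGrade.PROFOUND): (0.008, 3 / 60),
}


def _draw_ordered(rng, eta, cutpoints) -> np.ndarray:
    """Single-uniform draw from the cumulative-logit model."""
    u = rng.random(np.shape(eta))
    lvl = np.zeros(np.shape(eta), dtype=int)
    for c in cutpoints:
        lvl += u < _expit(eta - c)
    return lvl


def _draw_grades(rng, n, p_any, ladder) -> np.ndarray:
    """Latent grades: Bernoulli(any impairment) then the severity ladder."""
    grades = np.zeros(n, dtype=int)
    impaired = rng.random(n) < p_any
    if impaired.any():
        probs = np.array([p for _, p in ladder])
        values = np.array([int(g) for g, _ in ladder])
        picks = rng.choice(len(values), size=int(impaired.sum()), p=probs)
        grades[impaired] = values[picks]
    return grades


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one survey cohort.

    Returns ``(records, truth)``: the participant frame (data dictionary in
    :mod:`disabsurvey.cli_io`) and the per-person latent truth.  The output
    is deterministic under the config (which includes the master seed):
    cluster selection, segment choice and person-level generation use
    independent substreams derived from it.
    """
    master = np.random.SeedSequence(config.seed)
    ss_census, ss_segments, ss_persons = master.spawn(3)
    rng_census = np.random.default_rng(ss_census)
    rng_segments = np.random.default_rng(ss_segments)
    rng = np.random.default_rng(ss_persons)

    # Synthetic census frame and two-stage selection.
    n_units = max(4 * config.n_clusters, 20)
    unit_pops = np.maximum(
        120, np.round(np.exp(rng_census.normal(6.6, 0.6, size=n_units))).astype(int)
    )
    units = [(f"u{i:03d}", int(p)) for i, p in enumerate(unit_pops)]
    selected = pps_select_clusters(units, config.n_clusters, rng_census)
    pops = dict(units)
    cluster_ids = []
    seen: dict[str, int] = {}
    for name in selected:
        seg = compact_segment_sample(pops[name], config.cluster_size, rng_segments)
        j = seen.get(name, 0)
        seen[name] = j + 1
        cluster_ids.append(f"{name}.s{seg}" + (f".{j}" if j else ""))

    n = config.n_clusters * config.cluster_size
    cluster_index = np.repeat(np.arange(config.n_clusters), config.cluster_size)
    cluster_label = np.array(cluster_ids, dtype=object)[cluster_index]
    cluster_eff = rng.normal(0.0, config.cluster_sd, size=config.n_clusters)[cluster_index]

    # Demographics.
    edges = np.asarray(config.age_band_edges, dtype=float)
    band = rng.choice(len(config.age_band_probs), size=n, p=config.age_band_probs)
    age = edges[band] + rng.random(n) * (edges[band + 1] - edges[band])
    female = rng.random(n) < config.female_frac
    sex = np.where(female, "f", "m")

    # Latent impairment.
    frailty = rng.normal(0.0, config.frailty_sd, size=n)
    true = {}
    for name, model in (("vision", config.vision), ("hearing", config.hearing), ("msi", config.msi)):
        p_any = _expit(model.base_logodds + model.age_slope * age + frailty + cluster_eff)
        true[name] = _draw_grades(rng, n, p_any, model.ladder)
    epilepsy_true = rng.random(n) < config.epilepsy_prev
    adult = age >= 18
    dep_band = np.zeros(n, dtype=int)
    dep_band[adult] = rng.choice(5, size=int(adult.sum()), p=config.depression_band_probs)

    # --- Measurements from latent grades -----------------------------------
    # Vision
    va_denominator = np.full(n, np.nan)
    va_fix_and_follow = np.full(n, np.nan)
    va_counts_fingers = np.full(n, np.nan)
    acuity_lo = np.array([_ACUITY_RANGES.get(g, (np.nan, np.nan))[0] for g in range(5)])
    acuity_hi = np.array([_ACUITY_RANGES.get(g, (np.nan, np.nan))[1] for g in range(5)])
    vg = true["vision"]
    decimal = acuity_lo[vg] + rng.random(n) * (acuity_hi[vg] - acuity_lo[vg])
    over5 = age >= 5
    va_denominator[over5] = 6.0 / decimal[over5]
    under2 = age < 2
    mid = (age >= 2) & (age < 5)
    va_fix_and_follow[under2] = (vg[under2] < int(SeverityGrade.MODERATE)).astype(float)
    va_counts_fingers[mid] = (vg[mid] < int(SeverityGrade.MODERATE)).astype(float)

    # Hearing
    hg = true["hearing"]
    fail_both = hg >= int(SeverityGrade.MODERATE)
    oae_pass_left = (~fail_both).astype(float)
    oae_pass_right = (~fail_both).astype(float)
    pta = np.full(n, np.nan)
    need_pta = fail_both & (age >= 4)
    child_pta = age < 18
    pta_lo = np.where(child_pta, 35.0, 41.0)
    band_lo = np.select(
        [hg == int(SeverityGrade.MODERATE), hg == int(SeverityGrade.SEVERE)], [pta_lo, 61.0], 81.0
    )
    band_hi = np.select(
        [hg == int(SeverityGrade.MODERATE), hg == int(SeverityGrade.SEVERE)], [60.9, 80.9], 100.0
    )
    pta[need_pta] = band_lo[need_pta] + rng.random(int(need_pta.sum())) * (
        band_hi[need_pta] - band_lo[need_pta]
    )

    # Musculoskeletal
    mg = true["msi"]
    msi_screen_positive = (mg >= int(SeverityGrade.MILD)).astype(float)
    msi_exam_grade = np.where(msi_screen_positive > 0, mg.astype(float), np.nan)

    # Epilepsy: cases report >= 3 tonic-clonic seizures; a small fraction of
    # non-cases report sub-threshold counts.
    seizures = np.zeros(n, dtype=int)
    seizures[epilepsy_true] = 3 + rng.poisson(2.0, size=int(epilepsy_true.sum()))
    subthresh = (~epilepsy_true) & (rng.random(n) < 0.02)
    seizures[subthresh] = rng.integers(1, 3, size=int(subthresh.sum()))

    # Depression (adults): composite uniform within the band, spread over the
    # nine items front-to-back (so any positive composite triggers the full
    # administration rule).
    phq_items = np.full((n, 9), np.nan)
    phq_full = np.full(n, np.nan)
    if adult.any():
        lo = np.array([r[0] for r in _PHQ_BAND_RANGES])
        hi = np.array([r[1] for r in _PHQ_BAND_RANGES])
        comp = rng.integers(lo[dep_band[adult]], hi[dep_band[adult]] + 1)
        spread = np.clip(comp[:, None] - 3 * np.arange(9)[None, :], 0, 3)
        phq_items[adult] = spread
        phq_full[adult] = (comp > 0).astype(float)

    # --- Reported functioning ----------------------------------------------
    rep = config.reporting
    wg: dict[str, np.ndarray] = {d: np.full(n, np.nan) for d in _ALL_WG_DOMAINS}
    child = (age >= 2) & (age < 18)
    eta_age = rep.age_coef * (age - rep.age_ref)

    def matched(domain: str, grade: np.ndarray, mask: np.ndarray, sensory: bool) -> None:
        off = config.sensory_underreport if sensory else 0.0
        eta = rep.grade_coef * grade + eta_age - off
        wg[domain][mask] = _draw_ordered(rng, eta[mask], rep.cutpoints)

    matched("seeing", vg, child | adult, sensory=True)
    matched("hearing", hg, child | adult, sensory=True)
    matched("walking", mg, child, sensory=False)
    matched("walking_climbing", mg, adult, sensory=False)
    matched("upper_body", mg, adult, sensory=False)
    matched("fine_motor", mg, adult, sensory=False)

    bg_eta = (
        config.background_age_coef * (age - rep.age_ref)
        + config.epilepsy_report_boost * epilepsy_true
        + config.depression_report_boost * dep_band
    )
    for domain in _BACKGROUND_CORE:
        mask = child | adult
        if domain in ("learning",):
            mask = child
        if domain == "concentrating":
            mask = adult
        wg[domain][mask] = _draw_ordered(rng, bg_eta[mask], config.background_cutpoints)
    for domain in ("pain", "fatigue", "anxiety", "depression"):
        mask = child | adult
        wg[domain][mask] = _draw_ordered(rng, bg_eta[mask], config.noncore_cutpoints)

    # --- Assemble, classify, add case-only content -------------------------
    respondent = np.select(
        [age < 2, age < 8, age < (21 if config.country == "cameroon" else 18)],
        ["none", "caregiver", "child_self"],
        default="self",
    )
    records = pd.DataFrame(
        {
            "pid": [f"p{i:05d}" for i in range(n)],
            "cluster_id": cluster_label,
            "country": config.country,
            "age": np.round(age, 2),
            "sex": sex,
            "respondent_type": respondent,
            **{f"wg_{d}": wg[d] for d in _ALL_WG_DOMAINS},
            "va_denominator": np.round(va_denominator, 3),
            "va_fix_and_follow": va_fix_and_follow,
            "va_counts_fingers": va_counts_fingers,
            "oae_pass_left": oae_pass_left,
            "oae_pass_right": oae_pass_right,
            "pta_better_ear": np.round(pta, 1),
            "msi_screen_positive": msi_screen_positive,
            "msi_exam_grade": msi_exam_grade,
            "gtc_seizures_12m": seizures,
            **{f"phq9_{j + 1}": phq_items[:, j] for j in range(9)},
            "phq9_full": phq_full,
        }
    )

    graded = cc.grade_cohort(records)
    self_flags = cc.self_reported_flags(graded)
    clin_flags = cc.clinical_flags(graded)
    is_case = self_flags | clin_flags

    # Participation (cases only): child form (15 items) below 17, adult form
    # (21 items) from 17 up, matching the analysis age split.
    max_grade = np.zeros(n)
    for col in ("vision_grade", "hearing_grade", "msi_grade"):
        g = pd.to_numeric(graded[col], errors="coerce").to_numpy(dtype=float)
        g = np.where(g == int(SeverityGrade.IMPAIRED_UNCLASSIFIED), int(SeverityGrade.MODERATE), g)
        max_grade = np.maximum(max_grade, np.nan_to_num(g))
    propensity = (
        config.part_base
        + config.part_sev_coef * max_grade
        + config.part_rep_coef * self_flags
        + rng.normal(0.0, config.part_noise_sd, size=n)
    )
    part = np.full((n, 21), np.nan)
    p_item = _expit(propensity)
    n_items = np.where(age < 17, 15, 21)
    draws = 1 + rng.binomial(3, np.repeat(p_item, 21).reshape(n, 21))
    for i in np.flatnonzero(is_case):
        part[i, : n_items[i]] = draws[i, : n_items[i]]
    for j in range(21):
        records[f"part_{j + 1}"] = part[:, j]

    if config.collect_single_question:
        p_yes = _expit(
            config.sq_base + config.sq_self_coef * self_flags + config.sq_clin_coef * clin_flags
        )
        records["single_question_disability"] = (rng.random(n) < p_yes).astype(float)
    else:
        records["single_question_disability"] = np.nan

    truth = pd.DataFrame(
        {
            "pid": records["pid"],
            "cluster_id": cluster_label,
            "age": np.round(age, 2),
            "sex": sex,
            "vision_true": vg,
            "hearing_true": hg,
            "msi_true": mg,
            "epilepsy_true": epilepsy_true.astype(int),
            "depression_band_true": dep_band,
            "frailty": np.round(frailty, 4),
            "cluster_effect": np.round(cluster_eff, 4),
        }
    )

    # Non-response: drop enumerated persons independently.
    if config.response_rate < 1.0:
        keep = rng.random(n) < config.response_rate
        records = records.loc[keep].reset_index(drop=True)
        truth = truth.loc[keep].reset_index(drop=True)
    return records, truth


_ALL_WG_DOMAINS = (
    "seeing",
    "hearing",
    "walking",
    "walking_climbing",
    "self_care",
    "understanding",
    "being_understood",
    "learning",
    "remembering",
    "concentrating",
    "upper_body",
    "fine_motor",
    "pain",
    "fatigue",
    "anxiety",
    "depression",
)
_BACKGROUND_CORE = (
    "self_care",
    "understanding",
    "being_understood",
    "learning",
    "remembering",
    "concentrating",
)


# ---------------------------------------------------------------------------
# Analytic expectations (parameter-recovery oracle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpectedPrevalences:
    """Expected all-age prevalences under a config, marginalised over the
    age distribution and person frailty (cluster effects at zero — exact
    when the intra-cluster correlation is zero)."""

    vision: float
    hearing: float
    msi: float
    epilepsy: float
    depression: float
    clinical: float
    self_reported: float
    overall: float


def _age_grid(config: CohortConfig, step: float = 1.0):
    edges = np.asarray(config.age_band_edges, dtype=float)
    ages, weights = [], []
    for i, p in enumerate(config.age_band_probs):
        lo, hi = edges[i], edges[i + 1]
        pts = np.arange(lo + step / 2, hi, step)
        ages.append(pts)
        weights.append(np.full(pts.size, p / pts.size))
    return np.concatenate(ages), np.concatenate(weights)


def analytic_expectations(
    config: CohortConfig, depression_case_band: str = "moderately_severe"
) -> ExpectedPrevalences:
    """Closed-form expected prevalences per instrument and case definition.

    Marginalises over the configured age distribution (mid-point rule within
    bands) and the shared frailty (Gauss–Hermite quadrature); cluster
    effects enter at their mean of zero, so the result is exact for
    ``cluster_sd == 0`` and a first-order approximation otherwise.
    """
    ages, w_age = _age_grid(config)
    if config.frailty_sd > 0:
        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(31)
        f_nodes = gh_x * config.frailty_sd
        f_w = gh_w / np.sqrt(2 * np.pi)
        f_w = f_w / f_w.sum()
    else:
        f_nodes, f_w = np.array([0.0]), np.array([1.0])

    A, F = np.meshgrid(ages, f_nodes, indexing="ij")  # (n_age, n_f)
    W = w_age[:, None] * f_w[None, :]
    rep = config.reporting
    adult = A[:, 0] >= 18
    child = (A[:, 0] >= 2) & ~adult

    from .instruments import PHQ9_BANDS

    dep_case = sum(
        p
        for band, p in zip(PHQ9_BANDS, config.depression_band_probs)
        if PHQ9_BANDS.index(band) >= PHQ9_BANDS.index(depression_case_band)
    )

    models = {"vision": config.vision, "hearing": config.hearing, "msi": config.msi}
    p_any = {d: _expit(m.base_logodds + m.age_slope * A + F) for d, m in models.items()}
    p_case = {d: p_any[d] * m.case_fraction for d, m in models.items()}

    instrument = {d: float((p_case[d] * W).sum()) for d in models}
    p_epi = config.epilepsy_prev
    p_dep = np.where(adult, dep_case, 0.0)[:, None]

    not_clin = (1 - p_case["vision"]) * (1 - p_case["hearing"]) * (1 - p_case["msi"])
    not_clin = not_clin * (1 - p_epi) * (1 - p_dep)
    clinical = float(((1 - not_clin) * W).sum())

    # Reporting: per domain group, P(no core report >= A LOT) and the joint
    # term P(grade < moderate and no report >= A LOT).
    def grade_dist(d):
        """[(grade value, prob), ...] including grade 0."""
        m = models[d]
        out = [(0, 1 - p_any[d])]
        out += [(int(g), p_any[d] * p) for g, p in m.ladder]
        return out

    def p_alot(grade, sensory, n_reports):
        p = rep.prob_at_or_above(grade, A, config.sensory_underreport if sensory else 0.0)[..., 1]
        return 1 - (1 - p) ** n_reports  # independent reports sharing the grade

    no_tool = (A[:, 0] < 2)[:, None]
    n_msi_reports = np.where(adult, 3, 1)[:, None]  # walking(+upper body, fine motor)

    none_terms = []  # P(no A-LOT report in group)
    neither_terms = []  # P(grade < moderate and no A-LOT report in group)
    for d, sensory in (("vision", True), ("hearing", True), ("msi", False)):
        n_rep = n_msi_reports if d == "msi" else 1
        none_t = np.zeros_like(A)
        neither_t = np.zeros_like(A)
        for g, pg in grade_dist(d):
            q = 1 - p_alot(g, sensory, n_rep)
            none_t = none_t + pg * q
            if g < int(SeverityGrade.MODERATE):
                neither_t = neither_t + pg * q
            # grades >= moderate are clinical cases regardless of reporting
        none_terms.append(np.where(no_tool, 1.0, none_t))
        neither_terms.append(np.where(no_tool, 1 - p_case[d], neither_t))

    n_bg = 5  # unmatched core domains (child and adult modules both have 5)
    bg_base_eta = config.background_age_coef * (A - rep.age_ref) - config.background_cutpoints[1]

    def bg_none(boost: float) -> np.ndarray:
        """P(no background-domain report >= A LOT) given a reporting boost."""
        return np.where(no_tool, 1.0, (1 - _expit(bg_base_eta + boost)) ** n_bg)

    # Health conditions shift background reporting, so marginalise the
    # background term jointly with epilepsy / depression-band status.
    band_probs = np.asarray(config.depression_band_probs)
    case_band_i = PHQ9_BANDS.index(depression_case_band)
    adult_col = adult[:, None]

    def dep_mix(bands) -> np.ndarray:
        """E[bg_none(dep boost)] over the given depression bands (adults);
        children carry no depression process."""
        terms = sum(
            band_probs[b] * bg_none(config.depression_report_boost * b) for b in bands
        )
        norm = band_probs[list(bands)].sum()
        return np.where(adult_col, terms / norm, bg_none(0.0))

    bg_all = (1 - p_epi) * np.where(
        adult_col,
        sum(band_probs[b] * bg_none(config.depression_report_boost * b) for b in range(5)),
        bg_none(0.0),
    ) + p_epi * np.where(
        adult_col,
        sum(
            band_probs[b] * bg_none(config.epilepsy_report_boost + config.depression_report_boost * b)
            for b in range(5)
        ),
        bg_none(config.epilepsy_report_boost),
    )
    p_no_self = none_terms[0] * none_terms[1] * none_terms[2] * bg_all
    self_reported = float(((1 - p_no_self) * W).sum())

    # "Neither" additionally requires no epilepsy and sub-case depression.
    noncase_bands = list(range(case_band_i))
    bg_neither = (1 - p_epi) * dep_mix(noncase_bands) * np.where(
        adult_col, band_probs[noncase_bands].sum(), 1.0
    )
    p_neither = neither_terms[0] * neither_terms[1] * neither_terms[2] * bg_neither
    overall = float(((1 - p_neither) * W).sum())

    adult_frac = float((w_age * (ages >= 18)).sum())
    return ExpectedPrevalences(
        vision=instrument["vision"],
        hearing=instrument["hearing"],
        msi=instrument["msi"],
        epilepsy=p_epi,
        depression=dep_case * adult_frac,
        clinical=clinical,
        self_reported=self_reported,
        overall=overall,
    )
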