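"""Composite disability case definitions and their overlap decomposition.

A participant is a *case* under either of two routes:

* **self-reported** — "a lot of difficulty" or "cannot do" in at least one
  age-appropriate core functional domain (threshold and domain count are
  configurable for expanded definitions);
* **clinical** — a moderate-or-worse clinical impairment (vision, hearing,
  musculoskeletal) or a severe potentially disabling health condition
  (epilepsy, or depression above a configurable PHQ-9 band).

Cases decompose into Category A (self-report only), B (both) and C
(clinical only).  The two-stage screening strategy — self-report screen,
then clinical screening of everyone reporting at least "some" difficulty —
is evaluated against the full composite case set.

Cohorts live in a :class:`pandas.DataFrame` whose columns follow the data
dictionary in :mod:`disabsurvey.cli_io`; scalar operations on
:class:`ParticipantRecord` mirror the vectorised cohort operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .instruments import (
    ADULT_CORE_DOMAINS,
    ADULT_MODULE_AGE,
    CHILD_CORE_DOMAINS,
    MIN_WG_AGE,
    MissingDataError,
    PHQ9_BANDS,
    PHQ9Response,
    ParticipationResponseSet,
    ReportLevel,
    SeverityGrade,
    WGResponseSet,
    score_wg,
)

__all__ = [
    "ClassificationConfig",
    "ParticipantRecord",
    "CaseStatus",
    "CohortCounts",
    "TwoStageResult",
    "SingleQuestionSummary",
    "NotCollectedError",
    "is_self_reported_case",
    "is_clinical_case",
    "self_reported_flags",
    "clinical_flags",
    "max_core_report_level",
    "grade_cohort",
    "classify_cohort",
    "decompose_counts",
    "evaluate_two_stage_strategy",
    "compare_single_question",
]


class NotCollectedError(ValueError):
    """A field needed by the analysis was not collected for this cohort."""


@dataclass(frozen=True)
class ClassificationConfig:
    """Tunable parameters of the composite case definitions."""

    #: PHQ-9 band at or above which depression is a clinical case.
    depression_case_band: str = "moderately_severe"
    #: Self-report threshold for the primary definition.
    report_threshold: ReportLevel = ReportLevel.A_LOT
    #: Minimum number of core domains at or above the threshold.
    min_domains: int = 1

    def __post_init__(self) -> None:
        if self.depression_case_band not in PHQ9_BANDS:
            raise ValueError(f"unknown PHQ-9 band: {self.depression_case_band!r}")
        if self.min_domains < 1:
            raise ValueError("min_domains must be >= 1")


DEFAULT_CONFIG = ClassificationConfig()


@dataclass
class ParticipantRecord:
    """One participant: demographics, graded screens, and responses."""

    pid: str
    cluster_id: str
    country: str
    age: float
    sex: str
    respondent_type: str = "self"
    wg: Optional[WGResponseSet] = None
    vision_grade: Optional[SeverityGrade] = None
    hearing_grade: Optional[SeverityGrade] = None
    msi_grade: Optional[SeverityGrade] = None
    epilepsy_case: Optional[bool] = None
    phq9: Optional[PHQ9Response] = None
    participation: Optional[ParticipationResponseSet] = None
    single_question_disability: Optional[bool] = None

    @property
    def partial_screening(self) -> bool:
        """True when any clinical screen result is missing."""
        return any(g is None for g in (self.vision_grade, self.hearing_grade, self.msi_grade))


@dataclass(frozen=True)
class CaseStatus:
    self_reported: bool
    clinical: bool

    @property
    def category(self) -> str:
        if self.self_reported and self.clinical:
            return "B"
        if self.self_reported:
            return "A"
        if self.clinical:
            return "C"
        return "none"


@dataclass(frozen=True)
class CohortCounts:
    total: int
    total_cases: int
    self_reported: int
    clinical: int
    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        assert self.a + self.b + self.c == self.total_cases
        assert self.a + self.b == self.self_reported
        assert self.b + self.c == self.clinical


# ---------------------------------------------------------------------------
# Scalar (per-record) operations
# ---------------------------------------------------------------------------


def is_self_reported_case(
    p: ParticipantRecord,
    threshold: ReportLevel = ReportLevel.A_LOT,
    min_domains: int = 1,
) -> bool:
    """Self-reported case: at least ``min_domains`` core domains at or above
    ``threshold``.  Ages 0-1 are never self-reported cases (no tool)."""
    if min_domains < 1:
        raise ValueError("min_domains must be >= 1")
    if p.age < MIN_WG_AGE or p.wg is None:
        return False
    score = score_wg(p.wg, p.age, p.country)
    return score.count_at_or_above(threshold) >= min_domains


def _band_index(band: Optional[str]) -> int:
    return PHQ9_BANDS.index(band) if band in PHQ9_BANDS else 0


def is_clinical_case(p: ParticipantRecord, config: ClassificationConfig = DEFAULT_CONFIG) -> bool:
    """Clinical case: any impairment grade >= moderate (impaired-unclassified
    counts), epilepsy, or depression at or above the configured band."""
    grades = [g for g in (p.vision_grade, p.hearing_grade, p.msi_grade) if g is not None]
    if any(g >= SeverityGrade.MODERATE for g in grades):
        return True
    if p.epilepsy_case:
        return True
    if p.phq9 is not None and p.age >= 18:
        band_i = _band_index_from_composite(p.phq9.composite)
        if band_i >= PHQ9_BANDS.index(config.depression_case_band):
            return True
    return False


def _band_index_from_composite(composite: int) -> int:
    from .instruments import phq9_band

    return PHQ9_BANDS.index(phq9_band(composite))


# ---------------------------------------------------------------------------
# Vectorised cohort operations
# ---------------------------------------------------------------------------

def grade_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the instrument classifiers row-wise to a raw cohort frame.

    Adds ``vision_grade`` / ``hearing_grade`` / ``msi_grade`` (integer
    severity codes, NaN when the screen is missing), ``epilepsy_case``,
    ``phq9_composite`` and a ``partial_screening`` flag.  A record missing a
    clinical screen stays classifiable on the remaining screens; the flag
    lets severity analyses exclude it.
    """
    from .instruments import (
        HearingMeasurement,
        VisualAcuity,
        classify_epilepsy,
        classify_hearing,
        classify_msi,
        classify_vision,
    )

    out = df.copy()
    n = len(df)
    vision = np.full(n, np.nan)
    hearing = np.full(n, np.nan)
    msi = np.full(n, np.nan)
    epilepsy = np.full(n, np.nan)
    phq9 = np.full(n, np.nan)

    def _get(row, name):
        v = row.get(name)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

    for i, row in enumerate(df.to_dict("records")):
        age = float(row["age"])
        try:
            va = VisualAcuity(
                denominator=_get(row, "va_denominator"),
                fix_and_follow=_maybe_bool(_get(row, "va_fix_and_follow")),
                counts_fingers=_maybe_bool(_get(row, "va_counts_fingers")),
            )
            vision[i] = int(classify_vision(age, va))
        except MissingDataError:
            pass
        try:
            left, right = _get(row, "oae_pass_left"), _get(row, "oae_pass_right")
            if left is None or right is None:
                raise MissingDataError("OAE results missing")
            h = HearingMeasurement(
                oae_pass_left=bool(left),
                oae_pass_right=bool(right),
                pta_better_ear=_get(row, "pta_better_ear"),
            )
            hearing[i] = int(classify_hearing(age, h))
        except MissingDataError:
            pass
        try:
            screen = _get(row, "msi_screen_positive")
            if screen is None:
                raise MissingDataError("MSI screen missing")
            exam = _get(row, "msi_exam_grade")
            msi[i] = int(
                classify_msi(
                    age, bool(screen), SeverityGrade(int(exam)) if exam is not None else None
                )
            )
        except MissingDataError:
            pass
        seiz = _get(row, "gtc_seizures_12m")
        if seiz is not None:
            epilepsy[i] = float(classify_epilepsy(int(seiz)))
        if age >= 18:
            items = [_get(row, f"phq9_{j}") for j in range(1, 10)]
            if all(v is not None for v in items):
                phq9[i] = sum(int(v) for v in items)

    out["vision_grade"] = vision
    out["hearing_grade"] = hearing
    out["msi_grade"] = msi
    out["epilepsy_case"] = epilepsy
    out["phq9_composite"] = phq9
    out["partial_screening"] = np.isnan(vision) | np.isnan(hearing) | np.isnan(msi)
    return out


def _maybe_bool(v):
    return None if v is None else bool(v)


_CHILD_WG_COLS = tuple(f"wg_{d}" for d in CHILD_CORE_DOMAINS)
_ADULT_WG_COLS = tuple(f"wg_{d}" for d in ADULT_CORE_DOMAINS)
_GRADE_COLS = ("vision_grade", "hearing_grade", "msi_grade")


def _core_level_matrix(df: pd.DataFrame) -> np.ndarray:
    """Per-row array of core-domain report levels (n x max-domains), with
    non-applicable cells at -1.  Child rows use the child core set, adult
    rows the adult core set; ages 0-1 contribute nothing."""
    n = len(df)
    age = df["age"].to_numpy(dtype=float)
    is_child = (age >= MIN_WG_AGE) & (age < ADULT_MODULE_AGE)
    is_adult = age >= ADULT_MODULE_AGE
    out = np.full((n, len(_ADULT_WG_COLS)), -1, dtype=float)

    def fill(mask: np.ndarray, cols: Sequence[str]) -> None:
        for j, col in enumerate(cols):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
                out[mask, j] = np.where(np.isnan(vals[mask]), 0.0, vals[mask])
            else:
                out[mask, j] = 0.0

    fill(is_child, _CHILD_WG_COLS)
    fill(is_adult, _ADULT_WG_COLS)
    return out


def max_core_report_level(df: pd.DataFrame) -> np.ndarray:
    """Per-row maximum reported level over age-appropriate core domains
    (0 = no difficulty ... 3 = cannot do; 0 for ages 0-1)."""
    levels = _core_level_matrix(df)
    return np.maximum(levels.max(axis=1), 0.0).astype(int)


def self_reported_flags(
    df: pd.DataFrame,
    threshold: ReportLevel = ReportLevel.A_LOT,
    min_domains: int = 1,
) -> np.ndarray:
    """Vectorised self-reported-case flags for a cohort frame."""
    if min_domains < 1:
        raise ValueError("min_domains must be >= 1")
    levels = _core_level_matrix(df)
    count = (levels >= int(threshold)).sum(axis=1)
    return count >= min_domains


def clinical_flags(df: pd.DataFrame, config: ClassificationConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Vectorised clinical-case flags for a graded cohort frame."""
    n = len(df)
    flag = np.zeros(n, dtype=bool)
    for col in _GRADE_COLS:
        if col in df.columns:
            g = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            flag |= np.nan_to_num(g, nan=-1.0) >= int(SeverityGrade.MODERATE)
    if "epilepsy_case" in df.columns:
        flag |= pd.to_numeric(df["epilepsy_case"], errors="coerce").fillna(0).to_numpy(dtype=float) > 0
    if "phq9_composite" in df.columns:
        comp = pd.to_numeric(df["phq9_composite"], errors="coerce").to_numpy(dtype=float)
        lower = _PHQ9_BAND_LOWER_BY_NAME[config.depression_case_band]
        adult = df["age"].to_numpy(dtype=float) >= 18
        flag |= adult & (np.nan_to_num(comp, nan=-1.0) >= lower)
    return flag


_PHQ9_BAND_LOWER_BY_NAME = dict(zip(PHQ9_BANDS, (0, 5, 10, 15, 20)))


def decompose_counts(self_flags: np.ndarray, clin_flags: np.ndarray) -> CohortCounts:
    """Category A/B/C decomposition from per-record case flags."""
    s = np.asarray(self_flags, dtype=bool)
    c = np.asarray(clin_flags, dtype=bool)
    if s.shape != c.shape:
        raise ValueError("flag arrays must have equal length")
    b = int((s & c).sum())
    a = int((s & ~c).sum())
    cc = int((~s & c).sum())
    return CohortCounts(
        total=int(s.size),
        total_cases=a + b + cc,
        self_reported=a + b,
        clinical=b + cc,
        a=a,
        b=b,
        c=cc,
    )


def classify_cohort(
    df: pd.DataFrame,
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, CohortCounts]:
    """Classify every record and decompose the cases.

    Returns a per-record status frame (pid, self_reported, clinical,
    category) and the cohort counts.  The partition invariant holds by
    construction: A + B + C = cases, A + B = self-reported, B + C = clinical.
    """
    s = self_reported_flags(df, config.report_threshold, config.min_domains)
    c = clinical_flags(df, config)
    category = np.select([s & c, s, c], ["B", "A", "C"], default="none")
    status = pd.DataFrame(
        {
            "pid": df["pid"].to_numpy() if "pid" in df.columns else np.arange(len(df)),
            "self_reported": s,
            "clinical": c,
            "category": category,
        }
    )
    return status, decompose_counts(s, c)


@dataclass(frozen=True)
class TwoStageResult:
    identified: int
    total_cases: int
    sensitivity: float
    clinical_screens_required: int


def evaluate_two_stage_strategy(
    df: pd.DataFrame,
    config: ClassificationConfig = DEFAULT_CONFIG,
    screen_threshold: ReportLevel = ReportLevel.SOME,
) -> TwoStageResult:
    """Evaluate the two-stage strategy: self-report screen, then clinical
    screening of everyone reporting at least ``screen_threshold`` difficulty.

    Identified = self-reported cases plus clinical cases whose maximum core
    report level reaches the screen threshold.  Sensitivity is relative to
    the full composite case set.
    """
    s = self_reported_flags(df, config.report_threshold, config.min_domains)
    c = clinical_flags(df, config)
    max_level = max_core_report_level(df)
    screened = max_level >= int(screen_threshold)
    identified = s | (c & screened)
    total_cases = int((s | c).sum())
    sensitivity = float(identified.sum() / total_cases) if total_cases else float("nan")
    return TwoStageResult(
        identified=int(identified.sum()),
        total_cases=total_cases,
        sensitivity=sensitivity,
        clinical_screens_required=int(screened.sum()),
    )


@dataclass(frozen=True)
class SingleQuestionSummary:
    prevalence: float
    frac_clinical_yes: float
    frac_self_reported_yes: float
    frac_yes_neither: float  # NaN when nobody answers yes


def compare_single_question(
    df: pd.DataFrame, config: ClassificationConfig = DEFAULT_CONFIG
) -> SingleQuestionSummary:
    """Compare the direct single question ("Do you consider yourself to have
    a disability?") with the composite case definitions."""
    col = "single_question_disability"
    if col not in df.columns or df[col].isna().all():
        raise NotCollectedError("single_question_disability was not collected for this cohort")
    yes = pd.to_numeric(df[col], errors="coerce").fillna(0).to_numpy(dtype=float) > 0
    s = self_reported_flags(df, config.report_threshold, config.min_domains)
    c = clinical_flags(df, config)
    n = len(df)
    prevalence = float(yes.sum() / n) if n else float("nan")
    frac_clin = float((yes & c).sum() / c.sum()) if c.sum() else float("nan")
    frac_self = float((yes & s).sum() / s.sum()) if s.sum() else float("nan")
    frac_neither = float((yes & ~c & ~s).sum() / yes.sum()) if yes.sum() else float("nan")
    return SingleQuestionSummary(prevalence, frac_clin, frac_self, frac_neither)
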