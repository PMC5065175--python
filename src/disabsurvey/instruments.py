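"""Scoring of the disability screening instruments.

Each screening tool used in the two-country survey is scored here from raw
responses or measurements into a graded result:

* vision        — Snellen acuity in the better eye (presenting), with
                  fix-and-follow / finger-counting screens below age 5;
* hearing       — oto-acoustic emissions (OAE) screen followed by pure-tone
                  audiometry (PTA) in the better ear, with age-specific
                  decibel thresholds;
* musculoskeletal — report screen with physiotherapist examination grade;
* epilepsy      — reported generalised tonic-clonic seizure count;
* depression    — PHQ-9 composite (adults only);
* self-reported functioning — Washington-Group style graded difficulty
                  across age-appropriate core domains;
* participation — summed ordinal restriction score.

Grades follow the ordered ladder none < mild < moderate < severe < profound.
Infant/toddler screens that detect impairment without grading it yield
``IMPAIRED_UNCLASSIFIED``, which counts as moderate-or-worse for the
composite case definition but is excluded from severity tabulations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "ReportLevel",
    "SeverityGrade",
    "VisualAcuity",
    "HearingMeasurement",
    "WGResponseSet",
    "WGScore",
    "PHQ9Response",
    "ParticipationResponseSet",
    "MissingDataError",
    "NotAdministeredError",
    "CHILD_CORE_DOMAINS",
    "ADULT_CORE_DOMAINS",
    "NON_CORE_DOMAINS",
    "core_domains_for_age",
    "expected_respondent_type",
    "classify_vision",
    "classify_hearing",
    "classify_msi",
    "classify_epilepsy",
    "score_phq9",
    "phq9_band",
    "score_wg",
    "participation_score",
]


class MissingDataError(ValueError):
    """A measurement required for the participant's age band is absent."""


class NotAdministeredError(ValueError):
    """The instrument is not administered to this participant (e.g. PHQ-9 < 18 y)."""


class ReportLevel(enum.IntEnum):
    """Graded self-reported difficulty in a functional domain."""

    NO_DIFFICULTY = 0
    SOME = 1
    A_LOT = 2
    CANNOT_DO = 3


class SeverityGrade(enum.IntEnum):
    """Ordered clinical impairment severity.

    ``IMPAIRED_UNCLASSIFIED`` marks infant/toddler screen failures where a
    graded severity could not be determined; it compares as >= MODERATE (its
    integer value sits above PROFOUND so any ``grade >= MODERATE`` test
    includes it) but must be excluded from severity-specific tabulations.
    """

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    PROFOUND = 4
    IMPAIRED_UNCLASSIFIED = 5

    @property
    def is_classified(self) -> bool:
        return self is not SeverityGrade.IMPAIRED_UNCLASSIFIED


# ---------------------------------------------------------------------------
# Washington-Group style functional domains
# ---------------------------------------------------------------------------

CHILD_CORE_DOMAINS: tuple[str, ...] = (
    "seeing",
    "hearing",
    "walking",
    "self_care",
    "understanding",
    "being_understood",
    "learning",
    "remembering",
)

ADULT_CORE_DOMAINS: tuple[str, ...] = (
    "seeing",
    "hearing",
    "walking_climbing",
    "understanding",
    "being_understood",
    "remembering",
    "concentrating",
    "self_care",
    "upper_body",
    "fine_motor",
)

NON_CORE_DOMAINS: tuple[str, ...] = ("pain", "fatigue", "anxiety", "depression")

#: Age (years, inclusive lower bound) at which the adult functioning module applies.
ADULT_MODULE_AGE = 18
#: Youngest age with any self-report functioning tool.
MIN_WG_AGE = 2


def core_domains_for_age(age: float) -> tuple[str, ...]:
    """Core functional domains applicable at ``age`` (empty below age 2)."""
    if age < MIN_WG_AGE:
        return ()
    if age < ADULT_MODULE_AGE:
        return CHILD_CORE_DOMAINS
    return ADULT_CORE_DOMAINS


def expected_respondent_type(age: float, country: str) -> str:
    """Respondent rule: caregiver 2-7; child self-report 8-17 (India) / 8-20
    (Cameroon); adult self-report thereafter.  Ages 0-1 have no tool."""
    country = country.lower()
    if country not in ("cameroon", "india"):
        raise ValueError(f"unknown country: {country!r}")
    if age < MIN_WG_AGE:
        return "none"
    if age < 8:
        return "caregiver"
    adult_age = 21 if country == "cameroon" else 18
    return "child_self" if age < adult_age else "self"


# ---------------------------------------------------------------------------
# Vision
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VisualAcuity:
    """Presenting acuity in the better eye, Snellen at 6 m (``numerator`` /
    ``denominator``), plus the sub-5-year screen outcomes."""

    denominator: Optional[float] = None
    numerator: float = 6.0
    pinhole_denominator: Optional[float] = None
    fix_and_follow: Optional[bool] = None
    counts_fingers: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.denominator is not None and self.denominator <= 0:
            raise ValueError("Snellen denominator must be positive")

    @property
    def decimal(self) -> float:
        if self.denominator is None:
            raise MissingDataError("visual acuity denominator is missing")
        return self.numerator / self.denominator


# Decimal-acuity cut-offs: 6/18, 6/60 and 3/60.
_VA_NONE = 6.0 / 18.0
_VA_MODERATE = 6.0 / 60.0
_VA_SEVERE = 3.0 / 60.0


def classify_vision(age: float, va: VisualAcuity) -> SeverityGrade:
    """Grade vision impairment from the age-appropriate screen.

    Ages >= 5 use presenting acuity in the better eye: no impairment at
    6/18 or better, moderate below 6/18 down to 6/60, severe below 6/60 down
    to 3/60, profound (blind) below 3/60 — each lower bound inclusive.
    Under 2 the screen is fix-and-follow; 2-4 finger counting; failing either
    yields IMPAIRED_UNCLASSIFIED.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if age < 2:
        if va.fix_and_follow is None:
            raise MissingDataError("fix_and_follow required below age 2")
        return SeverityGrade.NONE if va.fix_and_follow else SeverityGrade.IMPAIRED_UNCLASSIFIED
    if age < 5:
        if va.counts_fingers is None:
            raise MissingDataError("counts_fingers required for ages 2-4")
        return SeverityGrade.NONE if va.counts_fingers else SeverityGrade.IMPAIRED_UNCLASSIFIED
    acuity = va.decimal  # raises MissingDataError when the denominator is absent
    if acuity >= _VA_NONE:
        return SeverityGrade.NONE
    if acuity >= _VA_MODERATE:
        return SeverityGrade.MODERATE
    if acuity >= _VA_SEVERE:
        return SeverityGrade.SEVERE
    return SeverityGrade.PROFOUND


# ---------------------------------------------------------------------------
# Hearing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HearingMeasurement:
    """OAE pass/fail per ear plus the better-ear PTA threshold (dBA) when the
    OAE screen failed in both ears (or by configuration)."""

    oae_pass_left: bool
    oae_pass_right: bool
    pta_better_ear: Optional[float] = None

    @property
    def oae_fail_both(self) -> bool:
        return not (self.oae_pass_left or self.oae_pass_right)


#: PTA grade change-points (dBA): (moderate, severe, profound) lower bounds.
_PTA_CUTS_CHILD = (35.0, 61.0, 81.0)
_PTA_CUTS_ADULT = (41.0, 61.0, 81.0)
#: Children's thresholds apply up to the 18th birthday.
HEARING_ADULT_AGE = 18


def classify_hearing(age: float, h: HearingMeasurement) -> SeverityGrade:
    """Grade hearing impairment.

    Ages 0-3 use OAE only: failure in both ears is impaired-unclassified.
    From age 4, an OAE pass in at least one ear is no impairment; otherwise
    the better-ear PTA is graded — children (4-17): <35 none, 35-60
    moderate, 61-80 severe, >80 profound; adults: <41 none then the same
    severe/profound cuts.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if age < 4:
        return SeverityGrade.IMPAIRED_UNCLASSIFIED if h.oae_fail_both else SeverityGrade.NONE
    if not h.oae_fail_both:
        return SeverityGrade.NONE
    if h.pta_better_ear is None:
        raise MissingDataError("pta_better_ear required after OAE failure in both ears (age >= 4)")
    mod, sev, prof = _PTA_CUTS_CHILD if age < HEARING_ADULT_AGE else _PTA_CUTS_ADULT
    pta = h.pta_better_ear
    if pta < mod:
        return SeverityGrade.NONE
    if pta < sev:
        return SeverityGrade.MODERATE
    if pta < prof:
        return SeverityGrade.SEVERE
    return SeverityGrade.PROFOUND


# ---------------------------------------------------------------------------
# Musculoskeletal impairment (MSI)
# ---------------------------------------------------------------------------

_MSI_GRADES = (SeverityGrade.NONE, SeverityGrade.MILD, SeverityGrade.MODERATE, SeverityGrade.SEVERE)


def classify_msi(
    age: float, screen_positive: bool, exam_grade: Optional[SeverityGrade] = None
) -> SeverityGrade:
    """Grade musculoskeletal impairment: a negative report screen is no
    impairment; a positive screen passes through the physiotherapist
    examination grade (none/mild/moderate/severe — no profound level)."""
    if age < 0:
        raise ValueError("age must be non-negative")
    if not screen_positive:
        if exam_grade is not None:
            raise ValueError("exam_grade given for a screen-negative participant")
        return SeverityGrade.NONE
    if exam_grade is None:
        raise MissingDataError("exam_grade required when the MSI screen is positive")
    if exam_grade not in _MSI_GRADES:
        raise ValueError(f"MSI examination grade must be one of none/mild/moderate/severe, got {exam_grade.name}")
    return exam_grade


def classify_epilepsy(gtc_seizures_12m: int) -> bool:
    """Epilepsy case: three or more generalised tonic-clonic seizures
    reported in the past 12 months."""
    if gtc_seizures_12m < 0:
        raise ValueError("seizure count must be non-negative")
    return gtc_seizures_12m >= 3


# ---------------------------------------------------------------------------
# Depression (PHQ-9, adults only)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PHQ9Response:
    """Nine PHQ-9 items scored 0-3.  The first three items screen; the
    remaining six are administered only when the screen is positive
    (``administered_full``), otherwise they count as zero."""

    items: Sequence[int]
    administered_full: bool = True

    def __post_init__(self) -> None:
        if len(self.items) != 9:
            raise ValueError("PHQ-9 requires exactly 9 items")
        if any((not isinstance(i, (int,)) or i < 0 or i > 3) for i in self.items):
            raise ValueError("PHQ-9 items must be integers in 0..3")

    @property
    def composite(self) -> int:
        counted = self.items if self.administered_full else self.items[:3]
        return int(sum(counted))


PHQ9_BANDS = ("none", "mild", "moderate", "moderately_severe", "severe")
_PHQ9_BAND_LOWER = (0, 5, 10, 15, 20)


def phq9_band(composite: int) -> str:
    """Standard PHQ-9 severity band for a composite score 0-27."""
    if not 0 <= composite <= 27:
        raise ValueError("PHQ-9 composite must be in 0..27")
    band = "none"
    for name, low in zip(PHQ9_BANDS, _PHQ9_BAND_LOWER):
        if composite >= low:
            band = name
    return band


def score_phq9(r: PHQ9Response, age: float) -> tuple[int, str]:
    """Composite PHQ-9 score and severity band; adults (18+) only."""
    if age < 18:
        raise NotAdministeredError("PHQ-9 is administered to adults (18+) only")
    c = r.composite
    return c, phq9_band(c)


# ---------------------------------------------------------------------------
# Self-reported functioning (Washington-Group style)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WGResponseSet:
    """Graded difficulty responses, domain -> ReportLevel, for the
    age-appropriate module (child core 2-17, adult core 18+, plus optional
    non-core domains)."""

    responses: Mapping[str, ReportLevel] = field(default_factory=dict)

    def level(self, domain: str) -> ReportLevel:
        return self.responses.get(domain, ReportLevel.NO_DIFFICULTY)


@dataclass(frozen=True)
class WGScore:
    """Summary of a functioning response set over *core* domains."""

    max_core_level: ReportLevel
    domains_at_or_above: Mapping[ReportLevel, frozenset[str]]
    tool_available: bool = True

    def count_at_or_above(self, threshold: ReportLevel) -> int:
        return len(self.domains_at_or_above[threshold])


def score_wg(responses: WGResponseSet, age: float, country: str = "cameroon") -> WGScore:
    """Score a functioning response set.

    Returns the maximum reported level over the age-appropriate core domains
    and, for each threshold level, the set of core domains at or above it.
    Non-core domains (pain, fatigue, anxiety, depression) never contribute.
    Ages 0-1 have no tool: the result is empty and flagged unavailable.
    """
    expected_respondent_type(age, country)  # validates country
    core = core_domains_for_age(age)
    if not core:
        empty = {lvl: frozenset() for lvl in ReportLevel}
        return WGScore(ReportLevel.NO_DIFFICULTY, empty, tool_available=False)
    unknown = set(responses.responses) - set(core) - set(NON_CORE_DOMAINS)
    if unknown:
        raise ValueError(f"domains not in the age-appropriate module: {sorted(unknown)}")
    levels = {d: responses.level(d) for d in core}
    max_level = max(levels.values(), default=ReportLevel.NO_DIFFICULTY)
    sets = {
        threshold: frozenset(d for d, lvl in levels.items() if lvl >= threshold)
        for threshold in ReportLevel
    }
    return WGScore(max_level, sets, tool_available=True)


# ---------------------------------------------------------------------------
# Participation restriction score
# ---------------------------------------------------------------------------

PARTICIPATION_LEVELS = ("no_difficulty", "moderate_difficulty", "severe_difficulty", "inability")
PARTICIPATION_ITEMS = {"child": 15, "adult": 21}


@dataclass(frozen=True)
class ParticipationResponseSet:
    """Per-item participation restriction responses on the four-level scale
    (no difficulty < moderate < severe < inability to perform); 15 items on
    the child form, 21 on the adult form."""

    items: Sequence[int]  # per-item scores 1..4
    form: str = "adult"

    def __post_init__(self) -> None:
        if self.form not in PARTICIPATION_ITEMS:
            raise ValueError("form must be 'child' or 'adult'")


def participation_score(p: ParticipationResponseSet) -> int:
    """Sum of per-item ordinal scores (no difficulty = 1 ... inability = 4).

    Higher scores denote greater participation restriction.  Range is
    [15, 60] on the child form and [21, 84] on the adult form.  Missing items
    are an error — no imputation.
    """
    n_required = PARTICIPATION_ITEMS[p.form]
    if len(p.items) != n_required:
        raise MissingDataError(
            f"{p.form} participation form requires {n_required} items, got {len(p.items)}"
        )
    if any((i is None) for i in p.items):
        raise MissingDataError("participation items contain missing responses")
    if any(not 1 <= int(i) <= 4 for i in p.items):
        raise ValueError("participation item scores must be in 1..4")
    return int(sum(int(i) for i in p.items))
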