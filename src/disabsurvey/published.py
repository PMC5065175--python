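"""Published counts from the motivating two-country survey, and their
arithmetic recomputation.

The survey (North-West Cameroon 2013; Telangana State, India 2014; 51
clusters x 80 people per country) printed participant counts, case counts
and cross-tabulations but deposited no microdata.  This module stores those
printed counts verbatim and recomputes every quantity that is pure
arithmetic on them — overall prevalence, prevalence at ages 50+, the
Category A/B/C decomposition by inclusion-exclusion, row percentages of
the severity-by-report cross-tabulation, and the closed-form severity odds
ratio — so the pipeline's own set algebra and estimators can be checked
against the published values.

Percentages use round-half-up, matching the printed tables.  Two printed
entries are known not to be reproducible by arithmetic on the printed
counts (both documented where they arise): the Cameroon Category B share
(118/373 = 31.6% -> 32, printed 33) and the Cameroon "none x
severe/profound" cross-tab cell (3/1643 = 0.2% -> 0, printed 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .case_classification import CohortCounts

__all__ = [
    "SAMPLE_SIZES",
    "CASE_COUNTS",
    "AGE_50_PLUS",
    "CROSSTAB_COUNTS",
    "CROSSTAB_PRINTED_PCT",
    "SEVERITY_2X2",
    "PRINTED",
    "round_half_up",
    "category_decomposition",
    "crosstab_row_percentages",
    "severity_crude_or",
    "compute_checks",
]

#: Survey respondents per country.
SAMPLE_SIZES = {"cameroon": 3567, "india": 3574}

#: (total cases, self-reported cases, clinical cases).
CASE_COUNTS = {"cameroon": (373, 197, 294), "india": (437, 258, 376)}

#: Ages 50+: (cases, sample size) — denominators are the printed age-band
#: totals 207+187+152+90 and 316+234+88+30.
AGE_50_PLUS = {"cameroon": (214, 636), "india": (256, 668)}

_ROWS = ("none", "some", "a_lot_cannot")
_COLS = ("none", "mild", "moderate", "severe_profound")

#: Severity-by-report cross-tabulation counts (ages 5+, severity-complete).
CROSSTAB_COUNTS = {
    "india": pd.DataFrame(
        [[1769, 162, 16, 10], [499, 410, 82, 34], [12, 43, 89, 92]],
        index=list(_ROWS),
        columns=list(_COLS),
    ),
    "cameroon": pd.DataFrame(
        [[1555, 52, 33, 3], [790, 247, 106, 16], [28, 26, 64, 35]],
        index=list(_ROWS),
        columns=list(_COLS),
    ),
}

#: The row percentages as printed.
CROSSTAB_PRINTED_PCT = {
    "india": pd.DataFrame(
        [[90, 8, 1, 1], [49, 40, 8, 3], [5, 18, 38, 39]],
        index=list(_ROWS),
        columns=list(_COLS),
    ),
    "cameroon": pd.DataFrame(
        [[95, 3, 2, 1], [68, 21, 9, 1], [18, 17, 42, 23]],
        index=list(_ROWS),
        columns=list(_COLS),
    ),
}

#: Severity concordance 2x2 (Cameroon): severe impairment vs moderate,
#: cross-classified by also-self-reporting: (a, b, c, d) =
#: (severe & reports, severe & not, moderate & reports, moderate & not).
SEVERITY_2X2 = {"cameroon": (19, 9, 73, 136), "india": (76, 33, 95, 108)}

#: Printed summary values the arithmetic is compared against.
PRINTED = {
    "overall_prevalence_pct": {"cameroon": 10.5, "india": 12.2},
    "prevalence_50plus_pct": {"cameroon": 33.6, "india": 38.3},
    "category_share_pct": {
        "cameroon": {"A": 21, "B": 33, "C": 47},
        "india": {"A": 14, "B": 45, "C": 41},
    },
    "severity_crude_or": {"cameroon": 3.93},
}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero, as the printed tables do."""
    scale = 10.0 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def category_decomposition(country: str) -> CohortCounts:
    """Category A/B/C from the printed totals by inclusion-exclusion."""
    cases, self_rep, clinical = CASE_COUNTS[country]
    b = self_rep + clinical - cases
    return CohortCounts(
        total=SAMPLE_SIZES[country],
        total_cases=cases,
        self_reported=self_rep,
        clinical=clinical,
        a=self_rep - b,
        b=b,
        c=clinical - b,
    )


def crosstab_row_percentages(country: str) -> pd.DataFrame:
    """Row percentages recomputed from the printed cross-tab counts."""
    counts = CROSSTAB_COUNTS[country]
    totals = counts.sum(axis=1)
    pct = 100 * counts.div(totals, axis=0)
    return pct.map(lambda v: int(round_half_up(v)))


def severity_crude_or(country: str = "cameroon") -> float:
    """Crude (cross-product) odds ratio of reporting a limitation for severe
    vs moderate impairment, from the printed 2x2."""
    a, b, c, d = SEVERITY_2X2[country]
    return (a * d) / (b * c)


def compute_checks() -> dict:
    """Recompute every printed-arithmetic quantity.

    Returns a flat dict of computed values (percentages on the printed
    scale); the companions in :data:`PRINTED` say what the tables show.
    """
    out: dict[str, float] = {}
    for country in ("cameroon", "india"):
        cases, _, _ = CASE_COUNTS[country]
        n = SAMPLE_SIZES[country]
        out[f"overall_prevalence_{country}_pct"] = round_half_up(100 * cases / n, 1)
        k, m = AGE_50_PLUS[country]
        out[f"prevalence_50plus_{country}_pct"] = round_half_up(100 * k / m, 1)
        dec = category_decomposition(country)
        for cat, val in (("a", dec.a), ("b", dec.b), ("c", dec.c)):
            out[f"category_{cat}_share_{country}_pct"] = round_half_up(100 * val / dec.total_cases)
        pct = crosstab_row_percentages(country)
        for row in _ROWS:
            for col in _COLS:
                out[f"crosstab_{country}_{row}_{col}_pct"] = float(pct.loc[row, col])
    out["severity_crude_or_cameroon"] = round(severity_crude_or("cameroon"), 2)
    return out
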