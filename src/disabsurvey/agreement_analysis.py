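"""Agreement between self-reported functioning and clinical screening.

The results-layer analyses of the survey pipeline:

* :func:`matched_domain_crosstab` — cross-tabulation of the most severe
  clinical grade (vision / hearing / musculoskeletal) against the maximum
  reported difficulty in the directly matched functional domains,
  restricted to ages 5+ with complete severity data;
* :func:`concordance_regression` — logistic regression, among clinical
  cases, of also being a self-reported case on age band, sex, impairment
  severity and impairment type (odds ratios with Wald 95% CIs);
* :func:`participation_comparison` — mean participation-restriction scores
  by case category with pooled-variance t-tests for A vs B and B vs C,
  children (5-16) and adults (17+) separately;
* :func:`definition_sweep` — prevalence under expanded self-report
  definitions ("some difficulty in any domain", "some in any two", ...)
  and the share of baseline clinical-only cases each re-classifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from . import case_classification as cc
from .instruments import ReportLevel, SeverityGrade

__all__ = [
    "CrossTab",
    "ORResult",
    "ParticipationComparison",
    "DefinitionResult",
    "matched_domain_crosstab",
    "concordance_regression",
    "participation_comparison",
    "participation_scores_frame",
    "definition_sweep",
    "pooled_t_test",
]

#: Functional domains directly matched to a clinical screen, per module.
MATCHED_CHILD = {"vision": ("seeing",), "hearing": ("hearing",), "msi": ("walking",)}
MATCHED_ADULT = {
    "vision": ("seeing",),
    "hearing": ("hearing",),
    "msi": ("walking_climbing", "upper_body", "fine_motor"),
}

ROW_LABELS = ("none", "some", "a_lot_cannot")
COL_LABELS = ("none", "mild", "moderate", "severe_profound")


@dataclass(frozen=True)
class CrossTab:
    """Reported-limitation by clinical-severity table with row percentages."""

    counts: pd.DataFrame  # rows ROW_LABELS, cols COL_LABELS
    n_excluded_missing: int

    @property
    def row_percentages(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return (100 * self.counts.div(totals.replace(0, np.nan), axis=0)).round(0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def _collapse_report(level: np.ndarray) -> np.ndarray:
    """0/1/2 for none / some / a-lot-or-cannot."""
    return np.clip(level, 0, 2)


def _collapse_grade(grade: np.ndarray) -> np.ndarray:
    """0..3 for none / mild / moderate / severe-profound."""
    return np.clip(grade, 0, 3)


def matched_domain_crosstab(df: pd.DataFrame, min_age: float = 5.0) -> CrossTab:
    """Cross-tabulate the most severe clinical grade against the maximum
    matched-domain report.

    Rows: maximum reported level over the matched domains (seeing, hearing,
    plus walking for children / walking-climbing, upper body strength and
    fine motor for adults), collapsed to none / some / a lot-cannot.
    Columns: most severe grade among vision, hearing and musculoskeletal,
    collapsed to none / mild / moderate / severe-profound.  Restricted to
    ages >= ``min_age``; records with any missing or unclassified severity
    are excluded and counted.
    """
    age = df["age"].to_numpy(dtype=float)
    eligible = age >= min_age
    grades = np.stack(
        [
            pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
            for c in ("vision_grade", "hearing_grade", "msi_grade")
        ]
    )
    missing = np.isnan(grades).any(axis=0) | (
        grades == int(SeverityGrade.IMPAIRED_UNCLASSIFIED)
    ).any(axis=0)
    keep = eligible & ~missing
    n_excluded = int((eligible & missing).sum())

    max_grade = grades.max(axis=0)
    adult = age >= 18
    report = np.zeros(len(df))
    for domain_map, mask in ((MATCHED_CHILD, ~adult), (MATCHED_ADULT, adult)):
        cols = [f"wg_{d}" for doms in domain_map.values() for d in doms]
        block = np.stack(
            [
                pd.to_numeric(df[c], errors="coerce").fillna(0).to_numpy(dtype=float)
                if c in df.columns
                else np.zeros(len(df))
                for c in cols
            ]
        )
        report[mask] = block.max(axis=0)[mask]

    rows = _collapse_report(report[keep]).astype(int)
    cols_ = _collapse_grade(max_grade[keep]).astype(int)
    counts = np.zeros((3, 4), dtype=int)
    np.add.at(counts, (rows, cols_), 1)
    frame = pd.DataFrame(counts, index=list(ROW_LABELS), columns=list(COL_LABELS))
    return CrossTab(frame, n_excluded)


# ---------------------------------------------------------------------------
# Concordance regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ORResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    reference: str
    separation: bool = False


AGE_BANDS = ((2, 18, "2-17"), (18, 34, "18-33"), (34, 50, "34-49"), (50, 66, "50-65"), (66, 200, "66+"))
AGE_REFERENCE = "34-49"
SEVERITY_REFERENCE = "moderate"
TYPE_REFERENCE = "vision"


def _age_band(age: np.ndarray) -> np.ndarray:
    labels = np.full(age.shape, "", dtype=object)
    for lo, hi, name in AGE_BANDS:
        labels[(age >= lo) & (age < hi)] = name
    return labels


def impairment_type_and_severity(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Case-level impairment type and severity labels.

    Type: vision / hearing / musculoskeletal / epilepsy at case-defining
    level, with ties broken by the fixed order vision < hearing <
    musculoskeletal, and "multiple" (two or more at case level) taking
    precedence.  Severity: name of the most severe classified grade
    (moderate / severe / profound), or "missing" when no graded severity is
    available (e.g. unclassified infant screens only).
    """
    g = {
        name: pd.to_numeric(df[f"{col}_grade"], errors="coerce").to_numpy(dtype=float)
        for name, col in (("vision", "vision"), ("hearing", "hearing"), ("musculoskeletal", "msi"))
    }
    epi = (
        pd.to_numeric(df.get("epilepsy_case"), errors="coerce").fillna(0).to_numpy(dtype=float) > 0
        if "epilepsy_case" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    case_level = {
        name: np.nan_to_num(v, nan=-1.0) >= int(SeverityGrade.MODERATE) for name, v in g.items()
    }
    n_types = sum(v.astype(int) for v in case_level.values()) + epi.astype(int)

    # fixed tie-break order vision < hearing < musculoskeletal; epilepsy when
    # no impairment reaches case level; "multiple" overrides everything
    type_label = np.full(len(df), "none", dtype=object)
    for name in ("vision", "hearing", "musculoskeletal"):
        sel = case_level[name] & (type_label == "none")
        type_label[sel] = name
    type_label[epi & (type_label == "none")] = "epilepsy"
    type_label[n_types >= 2] = "multiple"

    classified = {
        name: np.where(v == int(SeverityGrade.IMPAIRED_UNCLASSIFIED), np.nan, v)
        for name, v in g.items()
    }
    max_sev = np.nanmax(np.stack([np.nan_to_num(v, nan=-1.0) for v in classified.values()]), axis=0)
    sev_label = np.select(
        [
            max_sev == int(SeverityGrade.MODERATE),
            max_sev == int(SeverityGrade.SEVERE),
            max_sev == int(SeverityGrade.PROFOUND),
        ],
        ["moderate", "severe", "profound"],
        default="missing",
    )
    return type_label, sev_label


def concordance_regression(
    df: pd.DataFrame,
    config: cc.ClassificationConfig = cc.DEFAULT_CONFIG,
    covariates: Sequence[str] = ("age_band", "sex", "severity", "type"),
    exclude_depression_only: bool = True,
) -> list[ORResult]:
    """Odds of also being a self-reported case, among clinical cases.

    Maximum-likelihood logistic fit (Newton); ORs are exponentiated
    coefficients with Wald 95% CIs.  Records with missing graded severity
    are excluded when severity is a covariate; depression-only cases are
    excluded by default (they are sparse and carry no impairment severity
    or type).  Separation (an unbounded coefficient) is flagged on the
    affected terms rather than silently reported.
    """
    s = cc.self_reported_flags(df, config.report_threshold, config.min_domains)
    c = cc.clinical_flags(df, config)
    sub = df.loc[c].copy()
    outcome = s[c]
    type_label, sev_label = impairment_type_and_severity(sub)
    if exclude_depression_only:
        keep = type_label != "none"  # depression-only cases have no impairment type
        sub, outcome = sub.loc[keep], outcome[keep]
        type_label, sev_label = type_label[keep], sev_label[keep]

    cols = {}
    if "age_band" in covariates:
        bands = _age_band(sub["age"].to_numpy(dtype=float))
        for lo, hi, name in AGE_BANDS:
            if name != AGE_REFERENCE:
                cols[f"age_{name}"] = (bands == name).astype(float)
    if "sex" in covariates:
        cols["sex_female"] = (sub["sex"].astype(str).str.lower().str.startswith("f")).to_numpy(dtype=float)
    if "severity" in covariates:
        keep = sev_label != "missing"
        sub, outcome = sub.loc[keep], outcome[keep]
        type_label, sev_label = type_label[keep], sev_label[keep]
        cols = {k: v[keep] for k, v in cols.items()}
        for name in ("severe", "profound"):
            cols[f"severity_{name}"] = (sev_label == name).astype(float)
    if "type" in covariates:
        for name in ("musculoskeletal", "hearing", "epilepsy", "multiple"):
            cols[f"type_{name}"] = (type_label == name).astype(float)

    design = pd.DataFrame(cols, index=sub.index)
    # drop empty dummy levels (no observations) so the Hessian stays regular
    design = design.loc[:, design.any(axis=0)]
    X = sm.add_constant(design, has_constant="add")
    y = outcome.astype(float)
    model = sm.Logit(y, X)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # non-convergence under separation is detected and flagged below
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(method="newton", maxiter=50, tol=1e-10, disp=False)
            params, bse = fit.params, fit.bse
        except (np.linalg.LinAlgError, PerfectSeparationError):
            params = pd.Series(np.nan, index=X.columns)
            bse = pd.Series(np.nan, index=X.columns)

    results = []
    z = stats.norm.ppf(0.975)
    references = {"age": AGE_REFERENCE, "severity": SEVERITY_REFERENCE, "type": TYPE_REFERENCE, "sex": "male"}
    for term in X.columns:
        if term == "const":
            continue
        beta, se = float(params[term]), float(bse[term])
        separated = not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15 or se > 50
        ref = references.get(term.split("_")[0], "")
        if separated:
            results.append(ORResult(term, float("nan"), float("nan"), float("nan"), ref, True))
        else:
            results.append(
                ORResult(term, float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se)), ref)
            )
    return results


# ---------------------------------------------------------------------------
# Participation comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticipationComparison:
    group: str  # "child" (5-16) or "adult" (17+)
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    t_a_vs_b: float
    p_a_vs_b: float
    t_b_vs_c: float
    p_b_vs_c: float


def pooled_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample pooled-variance (Student) t-test; returns (t, two-sided p).
    Undefined (NaN) when either group has fewer than two observations."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def participation_scores_frame(
    df: pd.DataFrame, config: cc.ClassificationConfig = cc.DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-case participation scores with category and age-group labels."""
    status, _ = cc.classify_cohort(df, config)
    cat = status["category"].to_numpy()
    age = df["age"].to_numpy(dtype=float)
    n_items = np.where(age < 17, 15, 21)
    part_cols = [f"part_{j}" for j in range(1, 22) if f"part_{j}" in df.columns]
    part = df[part_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    score = np.nansum(part, axis=1)
    answered = (~np.isnan(part)).sum(axis=1)
    valid = (cat != "none") & (answered == n_items)
    out = pd.DataFrame(
        {
            "pid": df["pid"],
            "age": age,
            "category": cat,
            "age_group": np.where(age < 5, "under5", np.where(age < 17, "child", "adult")),
            "score": score,
        }
    )
    return out.loc[valid & (age >= 5)].reset_index(drop=True)


def participation_comparison(
    df: pd.DataFrame, config: cc.ClassificationConfig = cc.DEFAULT_CONFIG
) -> list[ParticipationComparison]:
    """Participation restriction by case category (children 5-16, adults 17+),
    with pooled t-tests for Category A vs B and B vs C."""
    scores = participation_scores_frame(df, config)
    results = []
    for group in ("child", "adult"):
        sub = scores.loc[scores["age_group"] == group]
        by_cat = {cat: sub.loc[sub["category"] == cat, "score"].to_numpy() for cat in "ABC"}
        means = {c: (float(v.mean()) if v.size else float("nan")) for c, v in by_cat.items()}
        sds = {c: (float(v.std(ddof=1)) if v.size > 1 else float("nan")) for c, v in by_cat.items()}
        ns = {c: int(v.size) for c, v in by_cat.items()}
        t_ab, p_ab = pooled_t_test(by_cat["A"], by_cat["B"])
        t_bc, p_bc = pooled_t_test(by_cat["B"], by_cat["C"])
        results.append(ParticipationComparison(group, means, sds, ns, t_ab, p_ab, t_bc, p_bc))
    return results


# ---------------------------------------------------------------------------
# Alternative case-definition sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DefinitionResult:
    name: str
    threshold: ReportLevel
    min_domains: int
    self_report_prevalence: float
    overall_prevalence: float
    counts: cc.CohortCounts
    share_c_reclassified: float  # share of baseline Category C moved to B


DEFAULT_DEFINITIONS = (
    ("some_any", ReportLevel.SOME, 1),
    ("some_two", ReportLevel.SOME, 2),
    ("alot_any", ReportLevel.A_LOT, 1),
)


def definition_sweep(
    df: pd.DataFrame,
    definitions: Sequence[tuple[str, ReportLevel, int]] = DEFAULT_DEFINITIONS,
    config: cc.ClassificationConfig = cc.DEFAULT_CONFIG,
) -> list[DefinitionResult]:
    """Re-classify the cohort under alternative self-report definitions.

    For each definition: the self-report and overall prevalence, the
    A/B/C decomposition, and the share of *baseline* clinical-only cases
    (Category C under the primary definition) re-classified to Category B.
    """
    base_s = cc.self_reported_flags(df, config.report_threshold, config.min_domains)
    clin = cc.clinical_flags(df, config)
    base_c_mask = clin & ~base_s
    n = len(df)
    results = []
    for name, threshold, min_domains in definitions:
        s = cc.self_reported_flags(df, threshold, min_domains)
        counts = cc.decompose_counts(s, clin)
        reclassified = float((base_c_mask & s).sum() / base_c_mask.sum()) if base_c_mask.sum() else float("nan")
        results.append(
            DefinitionResult(
                name=name,
                threshold=threshold,
                min_domains=min_domains,
                self_report_prevalence=float(s.sum() / n) if n else float("nan"),
                overall_prevalence=float((s | clin).sum() / n) if n else float("nan"),
                counts=counts,
                share_c_reclassified=reclassified,
            )
        )
    return results
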