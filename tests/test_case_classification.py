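"""Composite case definitions, A/B/C set algebra, two-stage screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from disabsurvey import case_classification as cc
from disabsurvey.instruments import (
    PHQ9Response,
    ReportLevel,
    SeverityGrade,
    WGResponseSet,
)

G = SeverityGrade
L = ReportLevel


def adult(wg=None, **kw):
    defaults = dict(
        pid="x", cluster_id="c", country="cameroon", age=40.0, sex="f",
        vision_grade=G.NONE, hearing_grade=G.NONE, msi_grade=G.NONE, epilepsy_case=False,
    )
    defaults.update(kw)
    return cc.ParticipantRecord(wg=WGResponseSet(wg or {}), **defaults)


class TestSelfReported:
    def test_cannot_do_walking_is_case(self):
        assert cc.is_self_reported_case(adult({"walking_climbing": L.CANNOT_DO}))

    def test_three_some_not_case_at_default_threshold(self):
        wg = {"seeing": L.SOME, "hearing": L.SOME, "self_care": L.SOME}
        assert not cc.is_self_reported_case(adult(wg))

    def test_expanded_definition_some_two(self):
        wg = {"seeing": L.SOME, "hearing": L.SOME, "self_care": L.SOME}
        assert cc.is_self_reported_case(adult(wg), threshold=L.SOME, min_domains=2)

    def test_infants_never_self_reported(self):
        assert not cc.is_self_reported_case(adult({"seeing": L.CANNOT_DO}, age=1.0))


class TestClinical:
    def test_all_clear_is_not_case(self):
        p = adult(phq9=PHQ9Response([0] * 9))
        assert not cc.is_clinical_case(p)

    def test_moderate_hearing_is_case(self):
        assert cc.is_clinical_case(adult(hearing_grade=G.MODERATE))

    def test_mild_msi_below_threshold(self):
        assert not cc.is_clinical_case(adult(msi_grade=G.MILD))

    def test_unclassified_infant_screen_counts(self):
        assert cc.is_clinical_case(adult(age=1.0, hearing_grade=G.IMPAIRED_UNCLASSIFIED))

    def test_depression_band_configurable(self):
        p = adult(phq9=PHQ9Response([3, 3, 3, 1, 0, 0, 0, 0, 0]))  # composite 10
        assert not cc.is_clinical_case(p)
        cfg = cc.ClassificationConfig(depression_case_band="moderate")
        assert cc.is_clinical_case(p, cfg)

    def test_missing_screen_still_classifiable(self):
        p = adult(hearing_grade=None, msi_grade=G.SEVERE)
        assert p.partial_screening
        assert cc.is_clinical_case(p)


class TestDecomposition:
    @pytest.mark.parametrize(
        "totals, expected",
        [
            ((3567, 373, 197, 294), (79, 118, 176)),
            ((3574, 437, 258, 376), (61, 197, 179)),
        ],
    )
    def test_inclusion_exclusion_on_survey_totals(self, totals, expected):
        """Flags built to match the two countries' printed totals decompose
        into the A/B/C counts implied by set algebra."""
        n, cases, self_rep, clinical = totals
        b = self_rep + clinical - cases
        s = np.zeros(n, dtype=bool)
        c = np.zeros(n, dtype=bool)
        s[:b] = True
        c[:b] = True  # B
        s[b : b + (self_rep - b)] = True  # A
        c[self_rep : self_rep + (clinical - b)] = True  # C
        counts = cc.decompose_counts(s, c)
        assert (counts.a, counts.b, counts.c) == expected
        assert counts.total_cases == cases
        assert counts.self_reported == self_rep and counts.clinical == clinical

    def test_empty_cohort(self):
        counts = cc.decompose_counts(np.array([], dtype=bool), np.array([], dtype=bool))
        assert counts.total_cases == counts.a == counts.b == counts.c == 0

    @given(
        s=st.lists(st.booleans(), min_size=0, max_size=200),
        c_extra=st.lists(st.booleans(), min_size=200, max_size=200),
    )
    def test_partition_invariant(self, s, c_extra):
        s = np.array(s, dtype=bool)
        c = np.array(c_extra[: len(s)], dtype=bool)
        counts = cc.decompose_counts(s, c)
        assert counts.a + counts.b + counts.c == counts.total_cases
        assert counts.a + counts.b == counts.self_reported
        assert counts.b + counts.c == counts.clinical
        assert counts.total_cases <= counts.total


class TestVectorisedAgainstScalar:
    """The frame-level flags must agree with per-record classification."""

    def test_self_reported_flags_match_score_wg(self, small_cohort):
        df, _ = small_cohort
        from disabsurvey.instruments import (
            ADULT_CORE_DOMAINS,
            CHILD_CORE_DOMAINS,
            NON_CORE_DOMAINS,
        )

        for threshold, min_domains in ((L.A_LOT, 1), (L.SOME, 1), (L.SOME, 2)):
            flags = cc.self_reported_flags(df, threshold, min_domains)
            for i, row in df.iterrows():
                age = row["age"]
                core = () if age < 2 else (CHILD_CORE_DOMAINS if age < 18 else ADULT_CORE_DOMAINS)
                responses = {}
                for d in list(core) + list(NON_CORE_DOMAINS):
                    v = row.get(f"wg_{d}")
                    if v is not None and not np.isnan(v):
                        responses[d] = L(int(v))
                rec = adult(age=age, country=row["country"])
                rec.wg = WGResponseSet(responses)
                expected = cc.is_self_reported_case(rec, threshold, min_domains)
                assert flags[i] == expected, f"row {i}"

    def test_clinical_flags_match_scalar(self, small_cohort):
        df, _ = small_cohort
        flags = cc.clinical_flags(df)
        for i, row in df.iterrows():
            rec = adult(
                age=row["age"],
                vision_grade=_grade(row["vision_grade"]),
                hearing_grade=_grade(row["hearing_grade"]),
                msi_grade=_grade(row["msi_grade"]),
                epilepsy_case=bool(row["epilepsy_case"]) if not np.isnan(row["epilepsy_case"]) else None,
                phq9=_phq9(row),
            )
            assert flags[i] == cc.is_clinical_case(rec), f"row {i}"


def _grade(v):
    return None if v is None or np.isnan(v) else G(int(v))


def _phq9(row):
    items = [row.get(f"phq9_{j}") for j in range(1, 10)]
    if any(v is None or np.isnan(v) for v in items):
        return None
    return PHQ9Response([int(v) for v in items])


class TestClassifyCohort:
    def test_counts_match_brute_force(self, small_cohort):
        df, _ = small_cohort
        status, counts = cc.classify_cohort(df)
        s = status["self_reported"].to_numpy()
        c = status["clinical"].to_numpy()
        assert counts.a == int((s & ~c).sum())
        assert counts.b == int((s & c).sum())
        assert counts.c == int((~s & c).sum())
        cats = status["category"].to_numpy()
        assert ((cats == "A") == (s & ~c)).all()
        assert ((cats == "B") == (s & c)).all()
        assert ((cats == "C") == (~s & c)).all()

    def test_threshold_monotonicity(self, cameroon_cohort):
        df, _ = cameroon_cohort
        n_some1 = cc.self_reported_flags(df, L.SOME, 1).sum()
        n_some2 = cc.self_reported_flags(df, L.SOME, 2).sum()
        n_alot1 = cc.self_reported_flags(df, L.A_LOT, 1).sum()
        assert n_some1 >= n_some2 >= n_alot1


class TestTwoStage:
    def test_sensitivity_one_when_all_clinical_report_some(self):
        df = pd.DataFrame(
            {
                "pid": ["a", "b", "c"],
                "age": [40.0, 40.0, 40.0],
                "wg_seeing": [1.0, 0.0, 2.0],
                "hearing_grade": [2.0, np.nan, np.nan],
                "gtc_seizures_12m": [0.0, 0.0, 0.0],
            }
        )
        res = cc.evaluate_two_stage_strategy(df)
        assert res.sensitivity == 1.0
        assert res.total_cases == 2  # one clinical (reports some), one self-reported

    def test_cannot_do_screen_adds_nothing(self, cameroon_cohort):
        df, _ = cameroon_cohort
        _, counts = cc.classify_cohort(df)
        max_level = cc.max_core_report_level(df)
        clin_only = cc.clinical_flags(df) & ~cc.self_reported_flags(df)
        if not (clin_only & (max_level >= int(L.CANNOT_DO))).any():
            res = cc.evaluate_two_stage_strategy(df, screen_threshold=L.CANNOT_DO)
            assert res.sensitivity == pytest.approx(counts.self_reported / counts.total_cases)

    def test_matches_per_record_enumeration(self, small_cohort):
        df, _ = small_cohort
        status, _ = cc.classify_cohort(df)
        s = status["self_reported"].to_numpy()
        c = status["clinical"].to_numpy()
        max_level = cc.max_core_report_level(df)
        for threshold in (L.SOME, L.A_LOT):
            res = cc.evaluate_two_stage_strategy(df, screen_threshold=threshold)
            identified = sum(
                bool(si or (ci and ml >= int(threshold))) for si, ci, ml in zip(s, c, max_level)
            )
            assert res.identified == identified
            assert res.sensitivity == pytest.approx(identified / (s | c).sum())
            assert res.clinical_screens_required == int((max_level >= int(threshold)).sum())

    def test_cascade_dominance(self, india_cohort):
        df, _ = india_cohort
        sens = [
            cc.evaluate_two_stage_strategy(df, screen_threshold=t).sensitivity
            for t in (L.CANNOT_DO, L.A_LOT, L.SOME)
        ]
        _, counts = cc.classify_cohort(df)
        floor = counts.self_reported / counts.total_cases
        assert sens[0] <= sens[1] <= sens[2]
        assert all(x >= floor - 1e-12 for x in sens)


class TestSingleQuestion:
    def test_not_collected(self, cameroon_cohort):
        df, _ = cameroon_cohort
        with pytest.raises(cc.NotCollectedError):
            cc.compare_single_question(df)

    def test_all_no(self):
        df = pd.DataFrame(
            {"pid": ["a", "b"], "age": [30.0, 40.0], "single_question_disability": [0.0, 0.0],
             "wg_seeing": [0.0, 2.0]}
        )
        res = cc.compare_single_question(df)
        assert res.prevalence == 0.0
        assert np.isnan(res.frac_yes_neither)

    def test_yes_subset_of_cases(self):
        df = pd.DataFrame(
            {"pid": list("abc"), "age": [30.0] * 3, "single_question_disability": [1.0, 0.0, 0.0],
             "wg_seeing": [2.0, 0.0, 0.0]}
        )
        res = cc.compare_single_question(df)
        assert res.frac_yes_neither == 0.0
        assert res.frac_self_reported_yes == 1.0

    def test_matches_direct_counting(self, india_cohort):
        df, _ = india_cohort
        res = cc.compare_single_question(df)
        yes = df["single_question_disability"].to_numpy() > 0
        s = cc.self_reported_flags(df)
        c = cc.clinical_flags(df)
        assert res.prevalence == pytest.approx(yes.mean())
        assert res.frac_clinical_yes == pytest.approx((yes & c).sum() / c.sum())
        assert res.frac_self_reported_yes == pytest.approx((yes & s).sum() / s.sum())
        assert res.frac_yes_neither == pytest.approx((yes & ~s & ~c).sum() / yes.sum())
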