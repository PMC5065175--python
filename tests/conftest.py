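import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from disabsurvey import case_classification as cc
from disabsurvey import synthetic_cohort as syn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cameroon_cohort():
    """One default-scale Cameroon cohort, graded, with its latent truth."""
    records, truth = syn.generate_cohort(syn.default_config("cameroon", seed=7))
    return cc.grade_cohort(records), truth


@pytest.fixture(scope="session")
def india_cohort():
    records, truth = syn.generate_cohort(syn.default_config("india", seed=7))
    return cc.grade_cohort(records), truth


@pytest.fixture(scope="session")
def small_cohort():
    """A small graded cohort for brute-force oracle comparisons."""
    cfg = dataclasses.replace(
        syn.default_config("india", seed=3), n_clusters=4, cluster_size=50, response_rate=1.0
    )
    records, truth = syn.generate_cohort(cfg)
    return cc.grade_cohort(records), truth


def identity_reporting_config(seed: int = 0, country: str = "cameroon") -> syn.CohortConfig:
    """Adults-only config whose reporting is the deterministic identity map:
    a domain is reported at exactly A_LOT iff its latent grade is moderate
    or worse, background and non-core reporting never fire, and no health
    conditions or random effects are present."""
    base = syn.default_config(country, seed=seed)
    return dataclasses.replace(
        base,
        age_band_edges=(20, 31),
        age_band_probs=(1.0,),
        reporting=syn.ReportingModel(cutpoints=(90.0, 91.0, 1e6), grade_coef=60.0, age_coef=0.0),
        sensory_underreport=0.0,
        background_cutpoints=(1e6, 2e6, 3e6),
        noncore_cutpoints=(1e6, 2e6, 3e6),
        epilepsy_prev=0.0,
        depression_band_probs=(1.0, 0.0, 0.0, 0.0, 0.0),
        epilepsy_report_boost=0.0,
        depression_report_boost=0.0,
        frailty_sd=0.0,
        cluster_sd=0.0,
        response_rate=1.0,
        collect_single_question=False,
    )
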