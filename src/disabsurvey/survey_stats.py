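"""Design and estimation for two-stage cluster surveys.

Covers the survey-statistics layer of the pipeline: sample-size calculation
for a prevalence survey with relative precision, probability-proportionate-
to-size (PPS) systematic cluster selection, compact-segment selection within
clusters, and cluster-robust (Taylor-linearised) prevalence estimation with
a design-effect report.

The design is self-weighted (equal selection probability for every person),
so the point estimate is the plain sample proportion; only the variance and
confidence interval depend on the cluster structure.  With cluster case
totals :math:`y_i`, cluster sizes :math:`m_i`, :math:`k` clusters and
:math:`\\hat p = \\sum y_i / \\sum m_i`,

.. math::

    \\widehat{\\mathrm{var}}(\\hat p)
        = \\frac{k}{k-1} \\cdot \\frac{\\sum_i (y_i - \\hat p m_i)^2}
                                      {(\\sum_i m_i)^2},

the default 95% CI is a logit-scale Wald interval with a :math:`t_{k-1}`
quantile (the behaviour of standard survey software), and the design effect
is the ratio of this variance to the binomial variance at the same
:math:`n`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PrevalenceEstimate",
    "DesignSpec",
    "sample_size",
    "pps_select_clusters",
    "compact_segment_sample",
    "estimate_prevalence",
    "simulate_cluster_flags",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Point estimate with cluster-robust 95% CI and design effect."""

    point: float
    ci_low: float
    ci_high: float
    n: int
    n_clusters: int
    deff: float
    ci_defined: bool = True

    def __post_init__(self) -> None:
        if self.ci_defined:
            assert 0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0


@dataclass(frozen=True)
class DesignSpec:
    """Survey design parameters for planning."""

    n_clusters: int
    cluster_size: int
    expected_prevalence: float
    rel_precision: float
    confidence: float = 0.95
    deff_assumed: float = 1.4
    nonresponse: float = 0.2

    def required_sample(self) -> int:
        return sample_size(
            self.expected_prevalence,
            self.rel_precision,
            self.confidence,
            self.deff_assumed,
            self.nonresponse,
        )

    def __post_init__(self) -> None:
        if self.n_clusters * self.cluster_size < self.required_sample():
            raise ValueError("n_clusters x cluster_size is below the required sample size")


def sample_size(
    p: float,
    rel_precision: float,
    confidence: float = 0.95,
    deff: float = 1.0,
    nonresponse: float = 0.0,
) -> int:
    """Required sample size for estimating a prevalence ``p`` to a given
    *relative* precision.

    ``ceil( z^2 p(1-p) / (rel_precision * p)^2 * deff / (1 - nonresponse) )``
    with ``z`` the standard-normal quantile at ``(1 + confidence) / 2``.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if not 0 < rel_precision < 1:
        raise ValueError("rel_precision must be in (0, 1)")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if deff < 1:
        raise ValueError("deff must be >= 1")
    if not 0 <= nonresponse < 1:
        raise ValueError("nonresponse must be in [0, 1)")
    z = stats.norm.ppf((1 + confidence) / 2)
    base = z * z * p * (1 - p) / (rel_precision * p) ** 2
    return int(math.ceil(base * deff / (1 - nonresponse)))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def pps_select_clusters(
    units: Sequence[tuple[str, float]],
    k: int,
    seed: Optional[int | np.random.Generator] = None,
) -> list[str]:
    """Systematic probability-proportionate-to-size selection of ``k``
    clusters from census ``units`` of (name, population).

    The sampling interval is total population / k with a uniform random
    start; a unit is selected once per selection point falling in its
    cumulative range, so units larger than the interval can be selected
    multiply.  Selection probability is proportional to population.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    names = [name for name, _ in units]
    pops = np.asarray([pop for _, pop in units], dtype=float)
    if len(units) == 0:
        raise ValueError("no census units supplied")
    if np.any(pops <= 0):
        raise ValueError("unit populations must be positive")
    total = pops.sum()
    interval = total / k
    start = _rng(seed).uniform(0.0, interval)
    points = start + interval * np.arange(k)
    cum = np.cumsum(pops)
    idx = np.searchsorted(cum, points, side="right")
    return [names[i] for i in idx]


def compact_segment_sample(
    cluster_population: int,
    segment_size: int = 80,
    seed: Optional[int | np.random.Generator] = None,
) -> int:
    """Pick one compact segment from a cluster map divided into segments of
    approximately ``segment_size`` people.

    The number of segments is round-half-up of population / segment_size
    (minimum 1); one segment index is chosen uniformly.
    """
    if cluster_population < segment_size:
        raise ValueError("cluster population must be at least the segment size")
    n_segments = max(1, int(math.floor(cluster_population / segment_size + 0.5)))
    return int(_rng(seed).integers(0, n_segments))


def estimate_prevalence(
    case_flags: Sequence[bool] | np.ndarray,
    cluster_ids: Sequence,
    confidence: float = 0.95,
    ci_method: str = "logit",
) -> PrevalenceEstimate:
    """Cluster-robust prevalence estimate for a self-weighted sample.

    ``ci_method`` is ``"logit"`` (logit-scale Wald, back-transformed; the
    default of standard survey software) or ``"wald"`` (plain).  The t
    quantile uses k-1 degrees of freedom.  A single cluster, or a degenerate
    proportion of 0 or 1, yields a flagged estimate with an undefined or
    degenerate CI and a design effect reported as 1 by convention.
    """
    flags = np.asarray(case_flags, dtype=float)
    ids = np.asarray(cluster_ids)
    if flags.shape != ids.shape:
        raise ValueError("case_flags and cluster_ids must have equal length")
    n = flags.size
    if n == 0:
        raise ValueError("empty sample")
    if ci_method not in ("logit", "wald"):
        raise ValueError("ci_method must be 'logit' or 'wald'")

    _, inverse = np.unique(ids, return_inverse=True)
    k = int(inverse.max()) + 1
    y = np.bincount(inverse, weights=flags)  # cluster case totals
    m = np.bincount(inverse).astype(float)  # cluster sizes
    p = float(flags.sum() / n)

    if k < 2:
        return PrevalenceEstimate(p, math.nan, math.nan, n, k, 1.0, ci_defined=False)
    if p in (0.0, 1.0):
        return PrevalenceEstimate(p, p, p, n, k, 1.0, ci_defined=True)

    var = k / (k - 1) * float(np.sum((y - p * m) ** 2)) / float(m.sum()) ** 2
    se = math.sqrt(var)
    deff = var / (p * (1 - p) / n)
    tq = stats.t.ppf((1 + confidence) / 2, df=k - 1)
    if ci_method == "logit":
        logit = math.log(p / (1 - p))
        se_logit = se / (p * (1 - p))
        lo_l, hi_l = logit - tq * se_logit, logit + tq * se_logit
        lo = 1 / (1 + math.exp(-lo_l))
        hi = 1 / (1 + math.exp(-hi_l))
    else:
        lo = max(0.0, p - tq * se)
        hi = min(1.0, p + tq * se)
    return PrevalenceEstimate(p, lo, hi, n, k, deff, ci_defined=True)


def simulate_cluster_flags(
    p: float,
    icc: float,
    n_clusters: int,
    cluster_size: int,
    seed: Optional[int | np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate equal-size clustered binary outcomes with a given
    intra-cluster correlation (beta-binomial cluster effects).

    With ``icc`` > 0 cluster-level probabilities are Beta with mean ``p`` and
    variance ``icc * p (1-p)``, giving an expected design effect of
    ``1 + (cluster_size - 1) * icc``; with ``icc`` = 0 outcomes are i.i.d.
    Bernoulli.  Returns (flags, cluster_ids).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if not 0 <= icc < 1:
        raise ValueError("icc must be in [0, 1)")
    rng = _rng(seed)
    if icc > 0:
        s = (1 - icc) / icc
        cluster_p = rng.beta(p * s, (1 - p) * s, size=n_clusters)
    else:
        cluster_p = np.full(n_clusters, p)
    flags = rng.random((n_clusters, cluster_size)) < cluster_p[:, None]
    ids = np.repeat(np.arange(n_clusters), cluster_size)
    return flags.ravel(), ids
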