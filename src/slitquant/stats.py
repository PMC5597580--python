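"""Group comparison and diagnostic scoring.

Covers the statistics used to turn per-subject SD densities and
foot-process widths into a diagnosis: descriptive summaries in the
M/Median/StdDev/n layout, the Mann–Whitney U test (min(U1, U2)
convention, exact by enumeration at small n), Student's pooled t test,
ordinary least-squares regression, and the stereological harmonic-mean
correction for section-based width measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "RegressionResult",
    "SeverityScore",
    "GUNDERSEN_FACTOR",
    "group_summary",
    "severity_below_control",
    "mann_whitney_u",
    "student_t",
    "linear_regression",
    "harmonic_mean",
    "gundersen_true_mean",
    "obliquity_correction_factor",
]

#: 8/(3π): multiplies the harmonic mean of apparent section widths to give
#: the true width under the sin²θ section-obliquity model.
GUNDERSEN_FACTOR = 8.0 / (3.0 * math.pi)

#: combined group size at or below which the Mann–Whitney p-value is
#: computed exactly by enumeration
EXACT_MWU_LIMIT = 16


@dataclass(frozen=True)
class GroupSummary:
    """Mean / median / sample SD / n, the layout of a results-table row."""

    mean: float
    median: float
    stddev: float
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact", "approximate", or either with "-degenerate"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class SeverityScore:
    """Effacement severity: control-group standard deviations below the control mean."""

    sds_below_control: float


def _as_array(values: Sequence[float], name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Arithmetic mean, median, and sample (n−1) standard deviation.

    A single value has stddev 0 by convention.
    """
    arr = _as_array(values, "values")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(
        mean=float(arr.mean()), median=float(np.median(arr)), stddev=sd, n=int(arr.size)
    )


def severity_below_control(value: float, control: GroupSummary) -> SeverityScore:
    """(control mean − value) / control SD; positive when below control."""
    if control.stddev <= 0:
        raise ValueError("control group has zero standard deviation")
    return SeverityScore(sds_below_control=(control.mean - value) / control.stddev)


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------


def _u_from_ranks(ranks: np.ndarray, n1: int, n2: int) -> float:
    """min(U1, U2) from the midranks of group 1 within the pooled sample."""
    r1 = float(ranks.sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return min(u1, n1 * n2 - u1)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test, reporting U = min(U1, U2).

    Ties are handled by midranks. For combined samples of up to
    ``EXACT_MWU_LIMIT`` values the two-sided p is exact: all assignments
    of group labels to the pooled midranks are enumerated and
    ``p = P(min(U1, U2) <= observed)``. Larger samples use the normal
    approximation with tie and continuity corrections.
    """
    x = _as_array(a, "a")
    y = _as_array(b, "b")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_from_ranks(ranks[:n1], n1, n2)

    if np.all(pooled == pooled[0]):
        return TestResult(statistic=u_obs, p_value=1.0, method="degenerate")

    if n1 + n2 <= EXACT_MWU_LIMIT:
        count = 0
        total = 0
        idx = range(n1 + n2)
        for combo in combinations(idx, n1):
            u = _u_from_ranks(ranks[list(combo)], n1, n2)
            total += 1
            if u <= u_obs + 1e-12:
                count += 1
        return TestResult(statistic=u_obs, p_value=count / total, method="exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(statistic=u_obs, p_value=1.0, method="approximate-degenerate")
    z = (u_obs - mu + 0.5) / math.sqrt(var)  # continuity correction; U = min <= mu
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return TestResult(statistic=u_obs, p_value=p, method="approximate")


def student_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided pooled-variance (Student's) t test."""
    x = _as_array(a, "a", min_n=2)
    y = _as_array(b, "b", min_n=2)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, p_value=1.0, method="degenerate")
        return TestResult(statistic=math.inf, p_value=0.0, method="degenerate")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(statistic=float(t), p_value=float(p), method="exact")


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with R² = 1 − SS_res/SS_tot.

    A constant y is reported as a perfect flat fit (slope 0, R² 0 by
    convention); a constant x is a domain error.
    """
    xa = _as_array(x, "x", min_n=3)
    ya = _as_array(y, "y", min_n=3)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(xa) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(xa, ya)
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    if ss_tot == 0:
        return RegressionResult(slope=0.0, intercept=float(ya.mean()), r_squared=0.0)
    pred = res.intercept + res.slope * xa
    ss_res = float(np.sum((ya - pred) ** 2))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=1.0 - ss_res / ss_tot,
    )


# ---------------------------------------------------------------------------
# Stereology
# ---------------------------------------------------------------------------


def harmonic_mean(values: Sequence[float]) -> float:
    """n / Σ(1/vᵢ); requires strictly positive values."""
    arr = _as_array(values, "values")
    if np.any(arr <= 0):
        raise ValueError("harmonic mean requires strictly positive values")
    return float(arr.size / np.sum(1.0 / arr))


def gundersen_true_mean(apparent_widths: Sequence[float]) -> float:
    """True mean width from section-based apparent widths.

    Thin sections almost never cut a foot process orthogonally, so each
    measured width overestimates the true one by 1/sin of the obliquity
    angle. The harmonic mean of the apparent widths times 8/(3π) undoes
    that bias.
    """
    return harmonic_mean(apparent_widths) * GUNDERSEN_FACTOR


def obliquity_correction_factor(
    method: str = "quadrature", n: int = 1_000_000, seed: Optional[int] = None
) -> float:
    """E[sin θ] for θ with density ∝ sin²θ on (0, π/2].

    This is the factor that converts the harmonic mean of apparent
    section widths into the true width; in closed form it is 8/(3π).
    ``method="quadrature"`` integrates sin³/sin² numerically;
    ``method="monte_carlo"`` estimates it from ``n`` seeded draws of the
    obliquity model (via :func:`slitquant.phantom.sample_apparent_widths`).
    """
    if method == "quadrature":
        num, _ = integrate.quad(lambda t: math.sin(t) ** 3, 0.0, math.pi / 2.0)
        den, _ = integrate.quad(lambda t: math.sin(t) ** 2, 0.0, math.pi / 2.0)
        return num / den
    if method == "monte_carlo":
        from .phantom import sample_apparent_widths

        widths = sample_apparent_widths(1.0, n, seed=seed)
        # apparent width at unit true width is 1/sin θ, so E[sin θ] is the
        # reciprocal of the harmonic mean of the apparent widths
        return 1.0 / harmonic_mean(widths)
    raise ValueError(f"unknown method {method!r}")
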