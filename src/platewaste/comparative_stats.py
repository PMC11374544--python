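"""Normality-gated two-group comparison protocol.

Each variable is screened for normality per group (Kolmogorov-Smirnov with
estimated parameters, Lilliefors-corrected by default); the two groups are
then compared with a pooled-variance Student t-test if *both* pass at
alpha = 0.05, and with the Mann-Whitney U test otherwise.  Descriptives
follow the chosen test: mean +/- SD for normal data, median (Q1, Q3)
otherwise.  All tests are two-sided.

The Mann-Whitney implementation is self-contained: an exact null distribution
(dynamic programming over rank configurations) when the pooled sample is
small and tie-free, and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .errors import DegenerateSampleError, ValidationError

ALPHA = 0.05
#: largest pooled sample size for which the exact Mann-Whitney null is used
EXACT_LIMIT = 16
#: categories never tested between cases (too few serving days)
EXCLUDED_VARIABLES: tuple[str, ...] = ("other", "dessert")


# ---------------------------------------------------------------------------
# normality screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool


def ks_normality(sample: Sequence[float], alpha: float = ALPHA,
                 correction: str = "lilliefors") -> NormalityResult:
    """One-sample KS test against a normal with estimated mean/SD.

    ``correction='lilliefors'`` (default) uses the Lilliefors null
    distribution, which accounts for the estimated parameters; ``'none'``
    runs the plain KS test against N(mean, sd) (anticonservative, provided
    for comparability).  Verdict is *normal* iff p >= alpha.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValidationError("normality screen requires n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample: normality is undefined")
    if correction == "lilliefors":
        stat, p = _lilliefors(x, dist="norm", pvalmethod="table")
    elif correction == "none":
        stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    return NormalityResult(statistic=float(stat), p_value=float(p), normal=bool(p >= alpha))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # 'exact' | 'normal_approx'


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of rank configurations per U value under the tie-free null.

    ``counts[u]`` is the number of the C(n1+n2, n1) equally likely group
    assignments yielding Mann-Whitney statistic u for the first group.
    Subset-sum dynamic programme: dp[k, s] counts k-subsets of ranks
    {1..n1+n2} with rank sum s; U = s - n1(n1+1)/2.
    """
    n = n1 + n2
    max_sum = n * (n + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    offset = n1 * (n1 + 1) // 2
    return dp[n1, offset : offset + n1 * n2 + 1]


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   continuity: bool = False) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact null (full enumeration via dynamic programming) when
    n1 + n2 <= 16 and the pooled sample is tie-free; tie-corrected normal
    approximation otherwise.  ``continuity`` applies the 0.5 continuity
    correction in the approximation (off by default, matching common
    statistical-package output).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and n1 + n2 <= EXACT_LIMIT:
        counts = _exact_u_counts(n1, n2)
        total = int(counts.sum())
        u_lo = int(round(min(u1, u2)))
        # symmetric null: two-sided tail = both extremes at distance >= |u - mean|
        favourable = int(counts[: u_lo + 1].sum()) + int(counts[n1 * n2 - u_lo:].sum())
        p = min(1.0, favourable / total)
        return MannWhitneyResult(u=u1, p_value=p, method="exact")

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        # every pooled value identical: no evidence either way
        return MannWhitneyResult(u=u1, p_value=1.0, method="normal_approx")
    delta = abs(u1 - mean_u)
    if continuity:
        delta = max(delta - 0.5, 0.0)
    z = delta / math.sqrt(var_u)
    p = 2.0 * sps.norm.sf(z)
    return MannWhitneyResult(u=u1, p_value=min(1.0, p), method="normal_approx")


# ---------------------------------------------------------------------------
# Student t
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float


def student_t(x: Sequence[float], y: Sequence[float], equal_var: bool = True) -> TTestResult:
    """Two-sample two-sided t-test, pooled variance by default (Welch by flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("t-test requires n >= 2 per group")
    s2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
    if s2 == 0 and equal_var:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, p_value=1.0)
        raise DegenerateSampleError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(t=float(t), p_value=float(p))


# ---------------------------------------------------------------------------
# the gated protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    variable: str
    n1: int
    n2: int
    normal1: bool
    normal2: bool
    test_used: str  # 'student_t' | 'mann_whitney_u'
    statistic: float
    p_value: float
    descriptive1: str
    descriptive2: str
    significant: bool


@dataclass(frozen=True)
class SkippedComparison:
    variable: str
    reason: str


def _describe(sample: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{sample.mean():.1f} ± {sample.std(ddof=1):.1f}"
    q1, med, q3 = np.percentile(sample, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def compare_cases(
    x: Sequence[float],
    y: Sequence[float],
    variable: str,
    alpha: float = ALPHA,
    excluded: Sequence[str] = EXCLUDED_VARIABLES,
) -> GroupComparison | SkippedComparison:
    """Run the full protocol on two per-day series.

    Variables in *excluded* (the sparsely served categories) come back as an
    explicit :class:`SkippedComparison`, never a silent omission.  The t-test
    is used iff both groups pass the normality screen; otherwise Mann-Whitney.
    """
    if variable in excluded:
        return SkippedComparison(
            variable=variable,
            reason="statistical analysis not performed: too few serving days",
        )
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both series must be non-empty")

    def _screen(sample: np.ndarray) -> bool:
        try:
            return ks_normality(sample, alpha=alpha).normal
        except (DegenerateSampleError, ValidationError):
            return False

    normal1, normal2 = _screen(x), _screen(y)
    if normal1 and normal2:
        result_t = student_t(x, y)
        test_used, statistic, p = "student_t", result_t.t, result_t.p_value
    else:
        result_u = mann_whitney_u(x, y)
        test_used, statistic, p = "mann_whitney_u", result_u.u, result_u.p_value
    gaussian = normal1 and normal2
    return GroupComparison(
        variable=variable,
        n1=int(x.size),
        n2=int(y.size),
        normal1=normal1,
        normal2=normal2,
        test_used=test_used,
        statistic=float(statistic),
        p_value=float(p),
        descriptive1=_describe(x, gaussian),
        descriptive2=_describe(y, gaussian),
        significant=bool(p < alpha),
    )


def comparison_table(results: Sequence[GroupComparison | SkippedComparison]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for r in results:
        if isinstance(r, SkippedComparison):
            rows.append({"variable": r.variable, "test": "skipped", "statistic": None,
                         "p_value": None, "group1": None, "group2": None,
                         "note": r.reason})
        else:
            rows.append(
                {
                    "variable": r.variable,
                    "test": r.test_used,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "group1": r.descriptive1,
                    "group2": r.descriptive2,
                    "note": "significant" if r.significant else "",
                }
            )
    return pd.DataFrame(
        rows, columns=["variable", "test", "statistic", "p_value", "group1", "group2", "note"]
    )
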