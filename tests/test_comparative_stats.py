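import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from platewaste.comparative_stats import (
    GroupComparison,
    SkippedComparison,
    compare_cases,
    ks_normality,
    mann_whitney_u,
    student_t,
)
from platewaste.errors import DegenerateSampleError, ValidationError


def permutation_oracle_p(x, y):
    """Brute-force two-sided Mann-Whitney p over all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    u_values = []
    for idx in itertools.combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        u_values.append(r1 - n1 * (n1 + 1) / 2)
    u_values = np.array(u_values)
    r1_obs = ranks[:n1].sum()
    u_obs = r1_obs - n1 * (n1 + 1) / 2
    u_min = min(u_obs, n1 * (n - n1) - u_obs)
    favourable = np.sum(u_values <= u_min) + np.sum(u_values >= n1 * (n - n1) - u_min)
    return min(1.0, favourable / len(u_values))


class TestKsNormality:
    def test_normal_draws_pass(self):
        passes = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=5000)
            passes += ks_normality(x).normal
        assert passes >= 90

    def test_exponential_draws_fail(self):
        fails = 0
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(size=5000)
            fails += not ks_normality(x).normal
        assert fails == 50

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            ks_normality([3.0, 3.0, 3.0, 3.0])

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_normality([1.0, 2.0])

    def test_plain_ks_variant(self):
        x = np.random.default_rng(0).normal(size=200)
        out = ks_normality(x, correction="none")
        assert out.normal


class TestMannWhitney:
    def test_spec_example_separated_triples(self):
        result = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert result.u == 0.0
        assert result.method == "exact"
        assert result.p_value == pytest.approx(0.1)  # 2/20 arrangements

    def test_identical_multisets(self):
        x = [1.0, 2.0, 2.0, 5.0]
        result = mann_whitney_u(x, list(x))
        assert result.u == len(x) ** 2 / 2
        assert result.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_complement_identity(self, rng):
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(2, 30)))
            y = rng.normal(size=int(rng.integers(2, 30)))
            u1 = mann_whitney_u(x, y).u
            u2 = mann_whitney_u(y, x).u
            assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_monotone_transform_invariance(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=9)
            p1 = mann_whitney_u(x, y).p_value
            p2 = mann_whitney_u(np.exp(x), np.exp(y)).p_value
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_exact_branch_matches_permutation_oracle_small(self, rng):
        """Random tie-free inputs with n1+n2 <= 12 (full sweep in acceptance)."""
        for _ in range(30):
            n1 = int(rng.integers(1, 7))
            n2 = int(rng.integers(1, 13 - n1))
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            result = mann_whitney_u(x, y)
            assert result.method == "exact"
            assert result.p_value == pytest.approx(permutation_oracle_p(x, y), rel=1e-12)

    def test_ties_use_normal_approx(self):
        result = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert result.method == "normal_approx"

    def test_large_sample_agrees_with_scipy(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(loc=0.7, size=30)
        ours = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert ours.u == pytest.approx(float(ref.statistic))
        assert ours.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)


class TestStudentT:
    def test_equal_samples(self):
        result = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 4.0, 5.0])
        n = 4
        sp2 = (x.var(ddof=1) * (n - 1) + y.var(ddof=1) * (n - 1)) / (2 * n - 2)
        t_hand = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n + 1 / n))
        p_hand = 2 * sps.t.sf(abs(t_hand), 2 * n - 2)
        result = student_t(x, y)
        assert result.t == pytest.approx(t_hand, rel=1e-12)
        assert result.p_value == pytest.approx(p_hand, rel=1e-12)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateSampleError):
            student_t([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(42)
        reps = 2000
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=20)
            y = rng.normal(size=19)
            rejections += student_t(x, y).p_value < 0.05
        assert abs(rejections / reps - 0.05) < 0.02

    def test_welch_flag(self):
        x = np.random.default_rng(1).normal(size=10)
        y = np.random.default_rng(2).normal(scale=5.0, size=12)
        pooled = student_t(x, y, equal_var=True)
        welch = student_t(x, y, equal_var=False)
        assert pooled.p_value != welch.p_value


class TestCompareCases:
    def test_identical_series(self, rng):
        x = rng.normal(size=20)
        result = compare_cases(x, x.copy(), "total:waste_pct")
        assert isinstance(result, GroupComparison)
        assert result.p_value == pytest.approx(1.0)

    def test_gate_selects_t_for_normal_data(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        result = compare_cases(x, y, "v")
        assert result.test_used == "student_t"
        assert "±" in result.descriptive1

    def test_gate_selects_mw_for_skewed_data(self, rng):
        x = rng.exponential(size=200)
        y = rng.exponential(size=200)
        result = compare_cases(x, y, "v")
        assert result.test_used == "mann_whitney_u"
        assert "(" in result.descriptive1

    def test_excluded_category_skips_explicitly(self):
        result = compare_cases([1.0], [2.0], "dessert")
        assert isinstance(result, SkippedComparison)
        assert "not performed" in result.reason

    def test_planted_shift_power(self):
        """2-SD location shift at n 20 vs 19 detected with >= 80 % power."""
        detections = 0
        reps = 200
        rng = np.random.default_rng(7)
        for _ in range(reps):
            x = rng.normal(loc=0.0, size=20)
            y = rng.normal(loc=2.0, size=19)
            result = compare_cases(x, y, "v")
            detections += result.significant
        assert detections / reps >= 0.80
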