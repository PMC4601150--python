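"""Limits of agreement, ICC, ROC/AUC and the paired DeLong test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import auc_by_pair_counting, icc21_by_anova
from stenoquant import (
    compare_auc_paired,
    descriptives,
    icc_two_way_random,
    limits_of_agreement,
    roc_auc,
)


class TestDescriptives:
    def test_single_value(self):
        mean, sd, n = descriptives([5.0])
        assert (mean, n) == (5.0, 1)
        assert np.isnan(sd)

    def test_hand_arithmetic(self):
        mean, sd, n = descriptives([2.0, 4.0])
        assert mean == 3.0
        assert sd == pytest.approx(np.sqrt(2.0))

    def test_constant_list(self):
        assert descriptives([7, 7, 7])[1] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            descriptives([])


class TestLimitsOfAgreement:
    def test_zero_spread(self):
        assert limits_of_agreement([3.0, 3.0, 3.0]) == (3.0, 3.0, 3.0)

    def test_hand_computed_sample_sd(self):
        mean, lo, hi = limits_of_agreement([-1.0, 1.0])
        assert mean == 0.0
        assert lo == pytest.approx(-2 * np.sqrt(2.0))
        assert hi == pytest.approx(2 * np.sqrt(2.0))

    @given(k=st.floats(min_value=-5, max_value=5))
    def test_linearity(self, k):
        base = np.array([0.3, -1.2, 2.0, 0.7])
        mean, lo, hi = limits_of_agreement(base)
        got = limits_of_agreement(k * base)
        ref = sorted([k * mean, k * lo, k * hi])
        assert got[0] == pytest.approx(k * mean, abs=1e-9)
        assert [got[1], got[2]] == pytest.approx([ref[0], ref[2]] if k >= 0 else [ref[0], ref[2]])

    def test_uses_two_sd_not_1_96(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1, 500)
        mean, lo, hi = limits_of_agreement(d)
        assert hi - mean == pytest.approx(2.0 * d.std(ddof=1))

    def test_gaussian_coverage_near_954(self):
        rng = np.random.default_rng(12)
        d = rng.normal(0.0, 3.0, 100_000)
        mean, lo, hi = limits_of_agreement(d)
        coverage = np.mean((d >= lo) & (d <= hi))
        se = np.sqrt(0.9545 * (1 - 0.9545) / len(d))
        assert abs(coverage - 0.9545) < 3 * se

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            limits_of_agreement([1.0])


class TestIcc:
    def test_perfect_agreement(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        icc, lo, hi = icc_two_way_random(x)
        assert icc == pytest.approx(1.0)

    def test_matches_hand_anova_on_small_matrix(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        icc, _, _ = icc_two_way_random(x)
        assert icc == pytest.approx(icc21_by_anova(x), abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=(500, 2))
        icc, _, _ = icc_two_way_random(x)
        assert abs(icc) < 0.1

    def test_variance_components_recovery(self):
        """ICC approaches case-variance / total-variance for simulated
        two-reader data."""
        rng = np.random.default_rng(8)
        case = rng.normal(50, 20, size=1000)
        x = case[:, None] + rng.normal(0, 5, size=(1000, 2))
        icc, lo, hi = icc_two_way_random(x)
        assert icc == pytest.approx(400 / 425, abs=0.05)
        assert lo <= icc <= hi

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(5)
        x = rng.normal(10, 4, size=(30, 1)) + rng.normal(0, 2, size=(30, 2))
        icc, lo, hi = icc_two_way_random(x)
        long = pd.DataFrame(
            {
                "case": np.repeat(np.arange(30), 2),
                "rater": np.tile([0, 1], 30),
                "value": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="case", raters="rater", ratings="value")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]  # absolute agreement, single
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        assert (lo, hi) == pytest.approx(tuple(row["CI95"]), abs=0.01)

    def test_average_measures_variant(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 3, size=(40, 1)) + rng.normal(0, 2, size=(40, 2))
        single, _, _ = icc_two_way_random(x, measures="single")
        avg, _, _ = icc_two_way_random(x, measures="average")
        assert avg == pytest.approx(2 * single / (1 + single))

    def test_zero_variance_reported_missing(self):
        icc, lo, hi = icc_two_way_random(np.full((5, 2), 3.0))
        assert np.isnan(icc)

    def test_incomplete_cases_dropped(self):
        x = np.array([[1.0, 1.1], [2.0, np.nan], [3.0, 3.2], [4.0, 3.9]])
        icc_full, _, _ = icc_two_way_random(x)
        icc_drop, _, _ = icc_two_way_random(x[[0, 2, 3]])
        assert icc_full == pytest.approx(icc_drop)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.fpr[0] == 0.0 and res.tpr[-1] == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5

    @pytest.mark.parametrize(
        "scores,expected", [([1, 2, 3, 4], 1.0), ([1, 3, 2, 4], 0.75), ([1, 2, 2, 4], 0.875)]
    )
    def test_small_examples_vs_pair_counting(self, scores, expected):
        labels = [0, 0, 1, 1]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(expected)
        assert res.auc == pytest.approx(auc_by_pair_counting(scores, labels))

    @pytest.mark.parametrize("trial", range(10))
    def test_random_instances_match_pair_counting_exactly(self, trial):
        rng = np.random.default_rng(40 + trial)
        n = int(rng.integers(5, 30))
        scores = rng.integers(0, 8, size=n).astype(float)  # many ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
        if labels.sum() in (0, n):
            pytest.skip("single class")
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_lower_direction_inverts(self):
        # smaller MinD = more stenotic = positive
        scores = [1.0, 1.5, 4.0, 5.0]
        labels = [1, 1, 0, 0]
        assert roc_auc(scores, labels, positive_direction="lower").auc == 1.0

    @given(
        shift=st.floats(min_value=-3, max_value=3),
        scale=st.floats(min_value=0.1, max_value=5),
    )
    def test_invariance_under_increasing_transform(self, shift, scale):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 40)
        labels = (rng.random(40) < 0.4).astype(int)
        if labels.sum() in (0, 40):
            return
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(scale * scores) + shift, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.normal(0, 1, 200) + np.repeat([0.0, 1.0], 100)
        labels = np.repeat([0, 1], 100)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_ci_methods_and_errors(self):
        scores = np.r_[np.random.default_rng(0).normal(0, 1, 50), np.random.default_rng(1).normal(1, 1, 50)]
        labels = np.repeat([0, 1], 50)
        d = roc_auc(scores, labels, ci_method="delong")
        h = roc_auc(scores, labels, ci_method="hanley-mcneil")
        assert d.ci_low <= d.auc <= d.ci_high
        assert h.ci_low <= h.auc <= h.ci_high
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], [1, 1])


class TestDeLongComparison:
    def test_identical_classifiers(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 60)
        y = (rng.random(60) < 0.3).astype(int)
        a, b, p = compare_auc_paired(s, s, y)
        assert a == b
        assert p == 1.0

    def test_monotone_transform_equivalent(self):
        rng = np.random.default_rng(4)
        s = rng.normal(0, 1, 80)
        y = (rng.random(80) < 0.4).astype(int)
        a, b, p = compare_auc_paired(s, np.exp(s), y)
        assert a == pytest.approx(b)
        assert p == pytest.approx(1.0)

    def test_type_one_error_under_paired_null(self):
        """Two noisy copies of a common signal have equal true AUC; the
        rejection rate at alpha=0.05 stays within 3 SE of 5 %."""
        rng = np.random.default_rng(77)
        n, reps = 300, 200
        rejections = 0
        for _ in range(reps):
            signal = rng.normal(0, 1, n)
            y = (rng.random(n) < 0.3).astype(int)
            signal += 0.8 * y
            sa = signal + rng.normal(0, 0.7, n)
            sb = signal + rng.normal(0, 0.7, n)
            _, _, p = compare_auc_paired(sa, sb, y)
            rejections += p < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_auc_paired([1, 2, 3], [1, 2], [0, 1, 1])
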