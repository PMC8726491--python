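"""Statistical layer vs independent oracles (pair enumeration, trapezoid AUC,
brute-force ANOVA, exact permutation Mann-Whitney, pingouin cross-checks)."""

import itertools
import math

import numpy as np
import pytest

from femhu import (
    auc_mann_whitney,
    boxplot_summary,
    classify_tscore,
    confusion_from_rates,
    delong_test,
    group_difference_test,
    icc_two_way_mixed_absolute,
    spearman_with_ci,
    youden_cutoff,
)
from femhu.stats import (
    POSITIVE_IF_HIGH,
    POSITIVE_IF_LOW,
    DegenerateInputError,
    _placements,
)


class TestClassifyTscore:
    @pytest.mark.parametrize(
        "t, three, binary",
        [
            (-2.5, "osteoporosis", "osteoporosis"),
            (-2.6, "osteoporosis", "osteoporosis"),
            (-1.0, "normal", "non-osteoporosis"),
            (-1.5, "osteopenia", "non-osteoporosis"),
            (-2.49, "osteopenia", "non-osteoporosis"),
            (0.3, "normal", "non-osteoporosis"),
        ],
    )
    def test_boundaries(self, t, three, binary):
        assert classify_tscore(t) == (three, binary)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_tscore(float("nan"))


class TestAuc:
    def test_pair_enumeration_example(self):
        scores = [2.0, 3.0, 1.0, 2.0]
        labels = [1, 1, 0, 0]
        res = auc_mann_whitney(scores, labels, POSITIVE_IF_HIGH)
        assert res.auc == pytest.approx(0.875)

    def test_perfect_separation(self):
        res = auc_mann_whitney([5, 6, 1, 2], [1, 1, 0, 0], POSITIVE_IF_HIGH)
        assert res.auc == 1.0

    def test_all_ties_give_half(self):
        res = auc_mann_whitney([3.0] * 6, [1, 1, 1, 0, 0, 0], POSITIVE_IF_HIGH)
        assert res.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            auc_mann_whitney([1, 2], [1, 1], POSITIVE_IF_HIGH)

    def test_equals_trapezoidal_roc_area(self):
        """Pairwise Mann-Whitney AUC == trapezoidal area under the empirical
        ROC curve (independent computation via scikit-learn)."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.normal(size=n) + labels, 1)  # ties likely
            mine = auc_mann_whitney(scores, labels, POSITIVE_IF_HIGH).auc
            assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        a = auc_mann_whitney(scores, labels, POSITIVE_IF_HIGH).auc
        b = auc_mann_whitney(np.exp(scores), labels, POSITIVE_IF_HIGH).auc
        assert a == pytest.approx(b)

    def test_direction_flip(self):
        scores = [1.0, 2.0, 5.0, 6.0]
        labels = [1, 1, 0, 0]
        assert auc_mann_whitney(scores, labels, POSITIVE_IF_LOW).auc == 1.0


class TestYouden:
    def test_exhaustive_scan_low_direction(self):
        cutoff, sens, spec = youden_cutoff([1, 2, 3, 4], [1, 1, 0, 0], POSITIVE_IF_LOW)
        assert (cutoff, sens, spec) == (2.0, 100.0, 100.0)

    def test_high_direction_single_pair(self):
        cutoff, sens, spec = youden_cutoff([5, 1], [1, 0], POSITIVE_IF_HIGH)
        assert cutoff == 1.0 and sens == 100.0 and spec == 100.0

    def test_identical_multisets_tie_break_deterministic(self):
        scores = [1.0, 2.0, 1.0, 2.0]
        labels = [1, 1, 0, 0]
        r1 = youden_cutoff(scores, labels, POSITIVE_IF_LOW)
        r2 = youden_cutoff(list(reversed(scores)), list(reversed(labels)), POSITIVE_IF_LOW)
        assert r1 == r2
        # J = 0 everywhere; tie-break prefers the most sensitive cutoff
        assert r1[1] == 100.0

    def test_cutoff_is_observed_value(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        labels[0], labels[1] = True, False
        cutoff, _, _ = youden_cutoff(scores, labels, POSITIVE_IF_LOW)
        assert cutoff in scores


class TestConfusionFromRates:
    @pytest.mark.parametrize(
        "sens, spec, ppv, npv",
        [
            (94.8, 85.0, 64.5, 98.3),  # 3D mean-HU row
            (89.6, 87.4, 67.2, 96.7),  # 2D mean-HU row
        ],
    )
    def test_screening_cohort_rows(self, sens, spec, ppv, npv):
        *_, got_ppv, got_npv = confusion_from_rates(96, 334, sens, spec)
        assert round(got_ppv, 1) == ppv
        assert round(got_npv, 1) == npv

    def test_perfect_rates(self):
        tp, fp, fn, tn, ppv, npv = confusion_from_rates(10, 10, 100.0, 100.0)
        assert (tp, fp, fn, tn) == (10, 0, 0, 10)
        assert ppv == 100.0 and npv == 100.0

    def test_round_trip_from_integer_matrix(self):
        """rates -> matrix -> rates -> matrix is the identity on integer tables."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_pos, n_neg = int(rng.integers(5, 200)), int(rng.integers(5, 400))
            tp = int(rng.integers(1, n_pos + 1))
            tn = int(rng.integers(1, n_neg + 1))
            sens, spec = 100.0 * tp / n_pos, 100.0 * tn / n_neg
            got = confusion_from_rates(n_pos, n_neg, sens, spec)
            assert got[:4] == (tp, n_neg - tn, n_pos - tp, tn)

    def test_undefined_predictive_value(self):
        with pytest.raises(DegenerateInputError):
            confusion_from_rates(10, 10, 0.0, 100.0)


def _brute_delong_z(a, b, labels):
    """Direct expansion of the placement-value covariance formulas."""
    a, b, labels = np.asarray(a, float), np.asarray(b, float), np.asarray(labels, bool)
    pos, neg = np.nonzero(labels)[0], np.nonzero(~labels)[0]
    m, n = len(pos), len(neg)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    out = {}
    for name, s in (("a", a), ("b", b)):
        v10 = np.array([np.mean([psi(s[i], s[j]) for j in neg]) for i in pos])
        v01 = np.array([np.mean([psi(s[i], s[j]) for i in pos]) for j in neg])
        out[name] = (v10, v01, v10.mean())
    s10 = np.zeros((2, 2))
    s01 = np.zeros((2, 2))
    for x, na in enumerate("ab"):
        for y, nb in enumerate("ab"):
            s10[x, y] = np.sum(
                (out[na][0] - out[na][2]) * (out[nb][0] - out[nb][2])
            ) / (m - 1)
            s01[x, y] = np.sum(
                (out[na][1] - out[na][2]) * (out[nb][1] - out[nb][2])
            ) / (n - 1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    return (out["a"][2] - out["b"][2]) / math.sqrt(var)


class TestDelong:
    def test_self_comparison_is_degenerate_p_one(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = [1, 1, 1, 0, 0, 0]
        res = delong_test(scores, scores, labels)
        assert res.z == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_monotone_transform_of_index_gives_z_zero(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=20)
        labels = np.array([1] * 10 + [0] * 10, bool)
        res = delong_test(scores, np.exp(scores), labels)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_matches_brute_force_covariance_on_small_fixture(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=10) + np.r_[np.ones(5), np.zeros(5)]
        b = 0.5 * a + rng.normal(size=10)
        labels = np.array([1] * 5 + [0] * 5, bool)
        res = delong_test(a, b, labels)
        assert res.z == pytest.approx(_brute_delong_z(a, b, labels), abs=1e-12)

    def test_type_one_error_calibrated(self):
        """Under random labels the self-vs-correlated comparison rejects at
        ~5%: the empirical rate over 1000 simulations must stay inside the
        binomial 95% band [36, 64]."""
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(1000):
            a = rng.normal(size=40)
            b = 0.6 * a + 0.8 * rng.normal(size=40)
            labels = np.zeros(40, bool)
            labels[rng.choice(40, 15, replace=False)] = True
            if delong_test(a, b, labels).p_value < 0.05:
                rejections += 1
        assert 36 <= rejections <= 64

    def test_placements_mean_is_auc(self):
        pos, neg = np.array([2.0, 3.0]), np.array([1.0, 2.0])
        v10, v01, auc = _placements(pos, neg)
        assert auc == pytest.approx(0.875)
        assert v10.mean() == pytest.approx(v01.mean())


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_with_ci(x, x**3).rho == pytest.approx(1.0)
        assert spearman_with_ci(x, -x).rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        res = spearman_with_ci([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)

    def test_categories(self):
        x = np.arange(40.0)
        rng = np.random.default_rng(11)
        noisy = x + rng.normal(0, 40, 40)
        res = spearman_with_ci(x, noisy)
        assert res.category in {"negligible", "weak", "moderate", "strong", "very strong"}
        assert res.ci95[0] <= res.rho <= res.ci95[1]

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_with_ci([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])


def _brute_icc(x):
    """Two-way ANOVA mean squares expanded from definitions."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        res = icc_two_way_mixed_absolute(x)
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_constant_offset_penalized_and_matches_anova(self):
        subj = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x = np.stack([subj, subj + 1.0], axis=1)
        res = icc_two_way_mixed_absolute(x)
        assert res.icc < 1.0
        assert res.icc == pytest.approx(_brute_icc(x), abs=1e-12)

    def test_hand_computed_3x2_table(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        # MSR = 8, MSC = 1.5, MSE = 0 -> ICC = 8 / (8 + (2/3)*1.5) = 8/9
        res = icc_two_way_mixed_absolute(x)
        assert res.icc == pytest.approx(8.0 / 9.0)

    def test_matches_brute_force_anova_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(3, 20))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            res = icc_two_way_mixed_absolute(x)
            assert res.icc == pytest.approx(_brute_icc(x), abs=1e-10)

    def test_matches_pingouin_point_estimate_and_ci(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(13)
        x = rng.normal(size=(12, 2)) + 2.0 * rng.normal(size=(12, 1))
        res = icc_two_way_mixed_absolute(x)
        long = pd.DataFrame(
            dict(
                subject=np.repeat(np.arange(12), 2),
                rater=np.tile(["A", "B"], 12),
                score=x.ravel(),
            )
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        assert res.icc == pytest.approx(row.ICC, abs=1e-9)
        assert res.ci95 == pytest.approx(tuple(row.CI95), abs=0.01)

    def test_incomplete_table_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            icc_two_way_mixed_absolute(x)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            icc_two_way_mixed_absolute(np.zeros((4, 2)))


class TestBoxplotSummary:
    def test_linear_interpolation_quartiles(self):
        assert boxplot_summary([1, 2, 3, 4, 5]) == (1.0, 2.0, 3.0, 4.0, 5.0)

    def test_single_value(self):
        assert boxplot_summary([7.0]) == (7.0,) * 5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        v = rng.normal(size=31)
        assert boxplot_summary(v) == boxplot_summary(rng.permutation(v))


def _exact_mw_p(a, b):
    """Exhaustive permutation enumeration of the Mann-Whitney U statistic."""
    pooled = np.asarray(list(a) + list(b), float)
    na = len(a)
    idx = range(len(pooled))

    def u_stat(sel):
        x = pooled[list(sel)]
        y = pooled[[i for i in idx if i not in sel]]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)

    observed = u_stat(range(na))
    us = [u_stat(c) for c in itertools.combinations(idx, na)]
    ge = np.mean([u >= observed for u in us])
    le = np.mean([u <= observed for u in us])
    return min(1.0, 2.0 * min(ge, le))


class TestGroupDifference:
    def test_identical_groups(self):
        assert group_difference_test([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0]) == 1.0

    def test_separated_large_groups(self):
        v = np.r_[np.zeros(40), np.ones(40)]
        y = np.r_[np.ones(40), np.zeros(40)]
        assert group_difference_test(v, y) < 0.001

    def test_matches_exact_enumeration_at_small_n(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            v = np.r_[a, b]
            y = np.r_[np.ones(3), np.zeros(3)]
            assert group_difference_test(v, y) == pytest.approx(_exact_mw_p(a, b), abs=1e-12)

    def test_ttest_option(self):
        rng = np.random.default_rng(16)
        v = np.r_[rng.normal(0, 1, 10), rng.normal(3, 1, 10)]
        y = np.r_[np.ones(10), np.zeros(10)]
        assert group_difference_test(v, y, method="ttest") < 0.01
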