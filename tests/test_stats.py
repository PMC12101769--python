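"""Welch/paired t, Spearman, ROC/DeLong, Bonferroni, binormal analytics."""

import numpy as np
import pytest
from scipy import stats as sps

from silentpupil.stats import (
    binormal_auc,
    binormal_d_for_sens_spec,
    bonferroni,
    paired_t,
    power_two_sample,
    roc_auc,
    spearman,
    welch_t,
)


class TestWelch:
    def test_identical_groups(self):
        g = np.array([3.0, 4.0, 5.0])
        res = welch_t(g, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_small_example(self):
        # A={1,2,3}, B={4,5,6}: s^2=1 each, se=sqrt(2/3),
        # t=(2-5)/se=-3.674, Satterthwaite df = 4
        res = welch_t(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == pytest.approx(4.0)
        assert res.p_value == pytest.approx(
            2 * sps.t.sf(3.674, 4), abs=1e-3)

    def test_reduces_to_classical_t_for_equal_sizes_and_variances(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 20)
        welch = welch_t(a, b)
        classical = sps.ttest_ind(a, b, equal_var=True)
        assert welch.statistic == pytest.approx(float(classical.statistic),
                                                rel=1e-12)

    def test_ci_contains_mean(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(10, 2, 15), rng.normal(11, 2, 12)
        res = welch_t(a, b)
        assert res.ci_a[0] <= res.mean_a <= res.ci_a[1]
        assert res.ci_b[0] <= res.mean_b <= res.ci_b[1]

    def test_zero_variance_equal_means_convention(self):
        res = welch_t(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert res.p_value == 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t(np.array([1.0]), np.array([2.0, 3.0]))


class TestPaired:
    def test_identical_conditions(self):
        x = np.array([5.0, 6.0, 7.0])
        res = paired_t(x, x)
        assert res.p_value == 1.0
        assert res.mean_difference == 0.0

    def test_constant_difference_no_variance(self):
        a = np.array([3.0, 4.0, 5.0])
        res = paired_t(a + 2.0, a)
        assert res.mean_difference == pytest.approx(2.0)
        assert res.p_value < 1e-12

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 25)
        b = a + rng.normal(0.3, 0.5, 25)
        res = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_t(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        assert spearman(x, x ** 3).rho == pytest.approx(1.0)
        assert spearman(x, -np.sqrt(x)).rho == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force_rank_formula(self):
        # n=6 with one tie in y: rho = Pearson correlation of midranks
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0])
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)        # midranks: [2, 1, 3.5, 3.5, 6, 5]
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).rho == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1 = spearman(x, y).rho
        r2 = spearman(np.exp(x), y ** 3).rho
        # note: cubing preserves order; exp preserves order
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_exact_p_for_small_n_matches_enumeration_extremes(self):
        # perfectly concordant n=5: only 2 of 5! orderings reach |rho|=1
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = spearman(x, 2 * x)
        assert res.p_value == pytest.approx(2 / 120)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(6), np.arange(6.0))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = roc_auc(scores, labels)
        assert res.auc == 1.0

    def test_exact_interleave_is_half(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(0.625)  # Mann-Whitney count: 10/16
        scores2 = np.array([1.0, 1.0, 2.0, 2.0])
        labels2 = np.array([0, 1, 0, 1])
        assert roc_auc(scores2, labels2).auc == pytest.approx(0.5)

    def test_matches_mann_whitney_count_with_ties(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 6, 30).astype(float)
        labels = rng.integers(0, 2, 30)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        count = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        oracle = count / (pos.size * neg.size)
        assert roc_auc(scores, labels).auc == pytest.approx(oracle)

    def test_delong_ci_matches_pROC_oracle(self):
        # frozen oracle from R pROC::ci.auc(method="delong") on this dataset
        scores = np.array([2.1, 3.4, 1.2, 5.6, 4.4, 3.3,
                           0.9, 4.1, 2.8, 3.9, 5.0, 1.7])
        labels = np.array([0, 0, 0, 1, 1, 0, 0, 1, 1, 0, 1, 0])
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(0.9142857, abs=1e-6)
        assert res.ci_lower == pytest.approx(0.7285581, abs=1e-6)
        assert res.ci_upper == pytest.approx(1.0, abs=1e-9)

    def test_monotone_transform_invariance_and_negation(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        auc = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(auc)
        assert roc_auc(-scores, labels).auc == pytest.approx(1.0 - auc)

    def test_sensitivity_at_specificity(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 2.5])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = roc_auc(scores, labels, at_specificity=0.9)
        assert res.sensitivity_at_specificity == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, dtype=int))


class TestBonferroni:
    def test_threshold_is_strict(self):
        assert bonferroni([0.0125], family_size=4) == [False]

    def test_below_threshold_significant(self):
        assert bonferroni([0.01], family_size=4) == [True]

    def test_family_of_one(self):
        assert bonferroni([0.049], family_size=1) == [True]

    def test_monotone_in_p(self):
        ps = np.linspace(0.001, 0.05, 20)
        decisions = bonferroni(ps, family_size=4)
        # once non-significant, later (larger) p never flips back
        flips = np.diff(np.asarray(decisions).astype(int))
        assert np.all(flips <= 0)


class TestBinormal:
    def test_chance_level_is_zero_separation(self):
        assert binormal_d_for_sens_spec(0.5, 0.5) == pytest.approx(0.0)

    def test_70_sens_90_spec_needs_d_1_8(self):
        d = binormal_d_for_sens_spec(0.70, 0.90)
        assert round(d, 1) == 1.8

    def test_monte_carlo_consistency(self):
        # place the threshold Phi^-1(spec) above the control mean; the
        # empirical sensitivity of the diseased group must hit the target
        d = binormal_d_for_sens_spec(0.70, 0.90)
        rng = np.random.default_rng(7)
        n = 10 ** 6
        controls = rng.normal(0.0, 1.0, n)
        patients = rng.normal(d, 1.0, n)
        thr = sps.norm.ppf(0.90)
        assert np.mean(controls < thr) == pytest.approx(0.90, abs=0.01)
        assert np.mean(patients >= thr) == pytest.approx(0.70, abs=0.01)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            binormal_d_for_sens_spec(1.0, 0.9)

    def test_binormal_auc_closed_form(self):
        assert binormal_auc(0.0) == pytest.approx(0.5)
        assert binormal_auc(1.8) == pytest.approx(
            sps.norm.cdf(1.8 / np.sqrt(2)))


class TestPower:
    def test_null_effect_power_is_alpha(self):
        assert power_two_sample(0.0, 20, 15) == pytest.approx(0.05, abs=1e-6)

    def test_large_effect_exceeds_99(self):
        assert power_two_sample(1.8, 20, 15) > 0.99

    def test_matches_welch_simulation(self):
        # 2e5-replicate vectorized Welch t-test simulation at d=1, n=15/15
        d, n = 1.0, 15
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 1.0, (200_000, n))
        b = rng.normal(d, 1.0, (200_000, n))
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        se2 = va / n + vb / n
        t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(se2)
        df = se2 ** 2 / ((va / n) ** 2 / (n - 1) + (vb / n) ** 2 / (n - 1))
        p = 2 * sps.t.sf(np.abs(t), df)
        empirical = np.mean(p < 0.05)
        assert power_two_sample(d, n, n) == pytest.approx(empirical, abs=0.005)
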