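"""Evaluation-metric tests, including independent brute-force oracles
for AUC and the DeLong covariance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from ecrisk.evaluation import (
    aic_bic,
    delong_compare,
    nri,
    operating_point,
    roc_auc,
)


def auc_brute_force(scores, labels):
    """Exhaustive pairwise concordance with half credit for ties."""
    cases = [s for s, l in zip(scores, labels) if l == 1]
    controls = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for x in cases:
        for y in controls:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(cases) * len(controls))


def delong_cov_brute_force(scores_a, scores_b, labels):
    """Naive double-loop structural components and their covariance."""
    out = []
    for scores in (scores_a, scores_b):
        cases = scores[labels == 1]
        controls = scores[labels == 0]
        m, n = len(cases), len(controls)
        v10 = np.array(
            [np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for y in controls]) for x in cases]
        )
        v01 = np.array(
            [np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for x in cases]) for y in controls]
        )
        out.append((v10, v01))
    (v10a, v01a), (v10b, v01b) = out
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    return s10 / m + s01 / n


scores_labels = st.integers(5, 200).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 20), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls)
        ),
    )
)


class TestAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_four_point_hand_count(self):
        auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_constant_scores_are_chance(self):
        auc, _ = roc_auc([1.0] * 10, [1] * 5 + [0] * 5)
        assert auc == pytest.approx(0.5)

    @given(scores_labels)
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_concordance(self, data):
        scores, labels = data
        auc, _ = roc_auc(np.array(scores, dtype=float), np.array(labels))
        assert auc == pytest.approx(auc_brute_force(scores, labels), abs=1e-12)

    @given(scores_labels)
    @settings(max_examples=50, deadline=None)
    def test_matches_sklearn_cross_check(self, data):
        scores, labels = data
        auc, _ = roc_auc(np.array(scores, dtype=float), np.array(labels))
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.random(80)
        labels = (rng.random(80) < 0.4).astype(int)
        auc1, _ = roc_auc(scores, labels)
        auc2, _ = roc_auc(np.exp(5 * scores), labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestOperatingPoint:
    def test_perfect_classifier(self):
        ev = operating_point([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert ev.youden == pytest.approx(1.0)
        assert ev.accuracy == pytest.approx(100.0)

    def test_constant_scores_give_zero_youden(self):
        ev = operating_point([1.0] * 10, [1] * 5 + [0] * 5)
        assert ev.youden == pytest.approx(0.0)

    def test_four_point_youden_tie_prefers_specificity(self):
        # two thresholds tie at Youden 0.5; the higher-specificity one wins
        ev = operating_point([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert ev.youden == pytest.approx(0.5)
        assert ev.specificity == pytest.approx(100.0)
        assert ev.sensitivity == pytest.approx(50.0)
        assert math.isinf(ev.lr_pos)

    def test_likelihood_ratios(self):
        ev = operating_point([0.9, 0.6, 0.55, 0.5, 0.7, 0.1], [1, 1, 1, 0, 0, 0])
        sens, spec = ev.sensitivity / 100, ev.specificity / 100
        assert spec < 1.0
        assert ev.lr_pos == pytest.approx(sens / (1 - spec))
        assert ev.lr_neg == pytest.approx((1 - sens) / spec)

    def test_infinite_lr_pos_reported_at_perfect_specificity(self):
        ev = operating_point([0.9, 0.8, 0.6, 0.1, 0.7, 0.2], [1, 1, 1, 0, 0, 0])
        assert ev.specificity == pytest.approx(100.0)
        assert math.isinf(ev.lr_pos)


class TestDelong:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        labels = np.array([1] * 30 + [0] * 30)
        delta, _, z, p = delong_compare(scores, scores, labels)
        assert delta == 0.0
        assert p == 1.0

    def test_single_auc_variance_consistent_with_ci(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = np.array([1] * 20 + [0] * 30)
        auc, (lo, hi) = roc_auc(scores, labels)
        cov = delong_cov_brute_force(scores, scores, labels)
        half_width = 1.959963984540054 * math.sqrt(cov[0, 0])
        assert hi - lo == pytest.approx(2 * half_width, abs=1e-10)

    def test_covariance_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        labels = np.array([1] * 15 + [0] * 25)
        base = rng.random(40)
        scores_a = base + 0.3 * rng.random(40)
        scores_b = base + 0.3 * rng.random(40)
        # include ties to exercise the midrank path
        scores_a[:4] = scores_a[4]
        cov = delong_cov_brute_force(scores_a, scores_b, labels)
        delta, _, z, _ = delong_compare(scores_a, scores_b, labels)
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        assert z == pytest.approx(delta / math.sqrt(var), abs=1e-10)

    def test_null_p_values_uniform(self):
        """Paired DeLong p for two independent uninformative models is
        uniform over replicates."""
        rng = np.random.default_rng(7)
        labels = np.array([1] * 30 + [0] * 30)
        ps = []
        for _ in range(1000):
            a = rng.random(60)
            b = rng.random(60)
            ps.append(delong_compare(a, b, labels)[3])
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([0.1, 0.2], [0.1, 0.2, 0.3], [1, 0, 1])


class TestNri:
    def test_identical_predictions_are_null(self):
        s = np.array([0.1, 0.5, 0.9, 0.2])
        value, z, p = nri(s, s, np.array([1, 1, 0, 0]))
        assert value == 0.0
        assert p == 1.0

    def test_maximal_improvement_is_two(self):
        old = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.9, 0.9, 0.1, 0.1])
        value, _, _ = nri(old, new, np.array([1, 1, 0, 0]))
        assert value == pytest.approx(2.0)

    def test_six_subject_hand_count(self):
        # cases: up, up, down -> +1/3; controls: down, down, up -> +1/3
        old = np.array([0.5] * 6)
        new = np.array([0.6, 0.7, 0.4, 0.3, 0.2, 0.9])
        labels = np.array([1, 1, 1, 0, 0, 0])
        value, _, _ = nri(old, new, labels)
        assert value == pytest.approx(2 / 3)

    @given(
        st.integers(4, 40).flatmap(
            lambda n: st.tuples(
                st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n),
                st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n),
                st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                    lambda ls: 0 < sum(ls) < len(ls)
                ),
            )
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_antisymmetric_in_old_new(self, data):
        old, new, labels = (np.array(v) for v in data)
        forward, _, _ = nri(old, new, labels)
        backward, _, _ = nri(new, old, labels)
        assert forward == pytest.approx(-backward, abs=1e-12)

    def test_categorical_mode_reclassifies_across_thresholds(self):
        old = np.array([0.05, 0.15, 0.35, 0.05])
        new = np.array([0.15, 0.05, 0.25, 0.04])
        labels = np.array([1, 1, 0, 0])
        # categories: <0.1, 0.1-0.3, >=0.3; case1 up, case2 down, ctrl1 down
        value, _, _ = nri(old, new, labels, mode="categorical", thresholds=(0.1, 0.3))
        assert value == pytest.approx(0.0 + 0.5)

    def test_categorical_mode_requires_thresholds(self):
        with pytest.raises(ValueError):
            nri(np.zeros(4), np.ones(4), np.array([1, 0, 1, 0]), mode="categorical")


class TestInformationCriteria:
    def test_forced_values_at_zero_log_likelihood(self):
        aic, bic = aic_bic(0.0, 1, 7)
        assert aic == pytest.approx(2.0)
        assert bic == pytest.approx(math.log(7), rel=1e-12)

    def test_identity_between_bic_and_aic(self):
        for k, n, ll in ((2, 50, -10.0), (5, 600, -370.275)):
            aic, bic = aic_bic(ll, k, n)
            assert bic - aic == pytest.approx(k * (math.log(n) - 2), rel=1e-12)

    def test_combined_model_training_aic(self):
        aic, _ = aic_bic(-370.275, 5, 600)
        assert aic == pytest.approx(750.55)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            aic_bic(-10.0, 0, 100)
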