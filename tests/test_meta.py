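"""Meta-analysis engine tests."""

import math

import numpy as np
import pytest

from ecrisk.meta import (
    StudyCounts,
    apply_inclusion_rules,
    begg_test,
    egger_test,
    heterogeneity,
    meta_analyze,
    pool_fixed_mh,
    pool_random_dl,
    select_model,
    study_or,
)
from ecrisk.simulate import generate_study_collection


def mh_oracle(tables):
    """Direct evaluation of sum(ad/n)/sum(bc/n)."""
    num = sum(a * d / (a + b + c + d) for a, b, c, d in tables)
    den = sum(b * c / (a + b + c + d) for a, b, c, d in tables)
    return num / den


class TestStudyOr:
    def test_homozygous_hand_value(self):
        s = StudyCounts("s1", (10, 20, 30), (30, 20, 10))
        log_or, se = study_or(s, "homozygous")
        assert log_or == pytest.approx(math.log(9.0), rel=1e-12)
        assert se == pytest.approx(math.sqrt(1 / 30 + 1 / 10 + 1 / 10 + 1 / 30), rel=1e-12)

    def test_identical_arms_are_null(self):
        s = StudyCounts("s1", (10, 20, 30), (10, 20, 30))
        assert study_or(s, "dominant")[0] == pytest.approx(0.0, abs=1e-12)


class TestMantelHaenszel:
    def test_single_study_returns_its_or(self):
        table = (10, 10, 5, 15)
        pooled, ci, _, _ = pool_fixed_mh([table])
        assert pooled == pytest.approx(10 * 15 / (10 * 5), rel=1e-12)
        assert ci[0] < pooled < ci[1]

    @pytest.mark.parametrize("k", [1, 2, 7, 23, 50])
    def test_identical_tables_pool_to_common_or(self, k):
        table = (12, 28, 9, 31)
        pooled, _, _, _ = pool_fixed_mh([table] * k)
        assert pooled == pytest.approx(12 * 31 / (28 * 9), rel=1e-12)

    def test_matches_formula_oracle(self):
        tables = [(10, 10, 5, 15), (20, 10, 10, 20)]
        pooled, _, _, _ = pool_fixed_mh(tables)
        assert pooled == pytest.approx(mh_oracle(tables), rel=1e-12)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed_mh([(0, 0, 0, 0)])


class TestDerSimonianLaird:
    def test_identical_studies_have_no_heterogeneity(self):
        y = np.full(5, math.log(1.7))
        se = np.full(5, 0.3)
        pooled, _, _, _, q, tau2 = pool_random_dl(y, se)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert tau2 == 0.0
        assert pooled == pytest.approx(1.7, rel=1e-12)

    def test_collapses_to_inverse_variance_fixed_when_q_below_df(self):
        y = np.array([0.10, 0.12, 0.11])
        se = np.array([0.5, 0.4, 0.6])
        w = 1 / se**2
        fixed = (w * y).sum() / w.sum()
        pooled, _, _, _, q, tau2 = pool_random_dl(y, se)
        assert q < len(y) - 1
        assert tau2 == 0.0
        assert math.log(pooled) == pytest.approx(fixed, rel=1e-12)

    def test_q_formula_hand_value(self):
        # w = 4 each, weighted mean = ln4/2, Q = 2*4*(ln4/2)^2 = 2 (ln4)^2
        y = np.array([0.0, math.log(4.0)])
        se = np.array([0.5, 0.5])
        _, _, _, _, q, _ = pool_random_dl(y, se)
        assert q == pytest.approx(2 * math.log(4.0) ** 2, rel=1e-12)

    def test_single_study_flagged(self):
        pooled, _, _, _, _, tau2 = pool_random_dl(np.array([0.5]), np.array([0.2]))
        assert pooled == pytest.approx(math.exp(0.5))
        assert math.isnan(tau2)

    def test_pooled_estimate_within_study_range(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.4, 0.5, size=8)
        se = rng.uniform(0.1, 0.6, size=8)
        pooled, _, _, _, _, _ = pool_random_dl(y, se)
        assert math.exp(y.min()) <= pooled <= math.exp(y.max())


class TestHeterogeneity:
    @pytest.mark.parametrize("q,df,i2", [(0.0, 5, 0.0), (10.0, 10, 0.0), (20.0, 10, 50.0)])
    def test_i2_values(self, q, df, i2):
        _, got = heterogeneity(q, df)
        assert got == pytest.approx(i2)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity(-1.0, 3)

    def test_increasing_deviation_never_decreases_q(self):
        se = np.array([0.3, 0.3, 0.3])
        y = np.array([0.1, 0.2, 0.3])
        _, _, _, _, q1, _ = pool_random_dl(y, se)
        y2 = y.copy()
        y2[2] = 0.8
        _, _, _, _, q2, _ = pool_random_dl(y2, se)
        assert q2 >= q1


class TestSelectModel:
    @pytest.mark.parametrize(
        "p_q,i2,expected",
        [
            (0.5, 80.0, "fixed"),  # disjunction: p alone suffices
            (0.05, 60.0, "random"),
            (0.05, 50.0, "fixed"),  # boundary, I2 <= 50
            (0.10, 90.0, "fixed"),  # boundary, p >= 0.10
        ],
    )
    def test_rule(self, p_q, i2, expected):
        assert select_model(p_q, i2) == expected


class TestPublicationBias:
    def test_too_few_studies_not_evaluable(self):
        y = np.array([0.1, 0.2])
        se = np.array([0.3, 0.4])
        assert math.isnan(begg_test(y, se))
        assert all(math.isnan(v) for v in egger_test(y, se))

    def test_forced_asymmetry_gives_positive_egger_intercept(self):
        se = np.linspace(0.1, 1.0, 12)
        y = 2.0 * se  # effects proportional to SE: classic small-study effect
        intercept, p = egger_test(y, se)
        assert intercept > 0
        assert p < 0.05

    def test_symmetric_funnel_rarely_flags(self):
        """Unbiased simulated studies: both tests exceed p = 0.05 in at
        least 90% of replicates."""
        ok_begg = ok_egger = 0
        reps = 20
        for r in range(reps):
            # a funnel needs a spread of precisions: vary study sizes
            sizes = [(int(n), int(n)) for n in np.random.default_rng(r).integers(100, 2000, 50)]
            studies = generate_study_collection(
                k=50, true_or=1.5, tau2=0.0, sizes=sizes, seed=1000 + r
            )
            ys, ses = zip(*(study_or(s, "allelic") for s in studies))
            if begg_test(np.array(ys), np.array(ses)) > 0.05:
                ok_begg += 1
            if egger_test(np.array(ys), np.array(ses))[1] > 0.05:
                ok_egger += 1
        assert ok_begg >= 0.9 * reps
        assert ok_egger >= 0.9 * reps


class TestInclusionRules:
    def test_small_arm_excluded(self):
        studies = [
            StudyCounts("big", (50, 100, 50), (60, 90, 50)),
            StudyCounts("tiny", (2, 3, 1), (50, 80, 40)),
        ]
        kept, audit = apply_inclusion_rules(studies)
        assert [s.study_id for s in kept] == ["big"]
        assert audit[0][0] == "tiny"

    def test_hwe_failing_controls_excluded(self):
        studies = [
            StudyCounts("ok", (50, 100, 50), (50, 100, 50)),
            StudyCounts("offhwe", (50, 100, 50), (100, 0, 100)),
        ]
        kept, audit = apply_inclusion_rules(studies)
        assert [s.study_id for s in kept] == ["ok"]
        assert "HWE" in audit[0][1]


class TestMetaAnalyze:
    def test_homogeneous_studies_use_fixed_effects(self):
        studies = generate_study_collection(
            k=10, true_or=2.0, tau2=0.0, sizes=(500, 500), seed=21
        )
        res = meta_analyze(studies, "allelic")
        assert res.model_used == "fixed"
        assert res.k == 10
        assert res.ci95[0] < 2.0 < res.ci95[1] or abs(math.log(res.pooled_or / 2.0)) < 0.15

    def test_null_collection_covers_one(self):
        studies = generate_study_collection(k=5, true_or=1.0, tau2=0.0, sizes=(300, 300), seed=2)
        res = meta_analyze(studies, "allelic")
        assert res.ci95[0] < 1.0 < res.ci95[1]

    def test_fixed_and_random_agree_without_heterogeneity(self):
        studies = generate_study_collection(
            k=20, true_or=2.0, tau2=0.0, sizes=(500, 500), seed=3
        )
        tables = []
        ys, ses = [], []
        for s in studies:
            y, se = study_or(s, "allelic")
            ys.append(y)
            ses.append(se)
        mh = meta_analyze(studies, "allelic")
        dl_pooled, _, _, _, _, _ = pool_random_dl(np.array(ys), np.array(ses))
        assert mh.pooled_or == pytest.approx(dl_pooled, rel=0.02)

    def test_i2_near_zero_without_between_study_variance(self):
        i2s = []
        for r in range(11):
            studies = generate_study_collection(
                k=20, true_or=2.0, tau2=0.0, sizes=(400, 400), seed=300 + r
            )
            i2s.append(meta_analyze(studies, "allelic").I2)
        assert np.median(i2s) < 25.0

    def test_tau2_detected_when_present(self):
        positive = 0
        reps = 20
        for r in range(reps):
            studies = generate_study_collection(
                k=20, true_or=2.0, tau2=0.4, sizes=(400, 400), seed=500 + r
            )
            if meta_analyze(studies, "allelic").tau2 > 0:
                positive += 1
        assert positive > 0.9 * reps
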