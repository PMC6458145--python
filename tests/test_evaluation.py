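"""Validation metrics against brute-force, hand-computed and simulation oracles."""

import numpy as np
import pandas as pd
import pytest

from difekit.cohort import SyntheticCohortConfig, generate_cohort
from difekit.evaluation import (
    compare_auc_bootstrap,
    bootstrap_auc_ci,
    confusion_metrics,
    egfr_risk_scores,
    fit_logistic_comparator,
    hosmer_lemeshow,
    km_estimate,
    logrank_test,
    mortality_rate_per100py,
    roc_auc,
)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 1, 0])
        m = confusion_metrics(y, y)
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_all_flipped(self):
        y = np.array([1, 0, 1, 1, 0])
        m = confusion_metrics(1 - y, y)
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.0, 0.0, 0.0)

    def test_hand_computed_two_by_two(self):
        # TP=26, FN=31, TN=339, FP=108 in a 504-patient table
        truth = np.array([1] * 57 + [0] * 447)
        pred = np.array([1] * 26 + [0] * 31 + [0] * 339 + [1] * 108)
        m = confusion_metrics(pred, truth)
        assert m.sensitivity == pytest.approx(26 / 57)
        assert m.specificity == pytest.approx(339 / 447)
        assert m.accuracy == pytest.approx(365 / 504)

    def test_single_class_truth_flagged(self):
        m = confusion_metrics(np.array([1, 0, 1]), np.array([1, 1, 1]))
        assert np.isnan(m.specificity)
        assert any("specificity" in f for f in m.flags)


def auc_pairwise_oracle(scores, labels):
    """O(n^2) comparison of every case/control pair, ties at half credit."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        s = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        assert roc_auc(s, y) == 1.0

    def test_antisymmetry_under_score_reversal(self, rng):
        s = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[:3] = 1
        y[-3:] = 0
        assert roc_auc(-s, y) == pytest.approx(1.0 - roc_auc(s, y))

    @pytest.mark.parametrize("n", [10, 40, 200])
    def test_matches_pairwise_oracle_with_ties(self, n, rng):
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, n)
        labels[0], labels[1] = 1, 0
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pairwise_oracle(scores, labels), abs=1e-12
        )

    def test_agrees_with_sklearn_implementation(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=150)
        labels = rng.integers(0, 2, 150)
        labels[0], labels[1] = 1, 0
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestBootstrapAuc:
    def test_degenerate_perfect_scores(self):
        s = np.array([0.0] * 20 + [1.0] * 20)
        y = np.array([0] * 20 + [1] * 20)
        r = bootstrap_auc_ci(s, y, n_boot=200, seed=0)
        assert r.ci_low == r.ci_high == r.auc == 1.0

    def test_seeded_reproducibility(self, rng):
        s = rng.normal(size=120)
        y = rng.integers(0, 2, 120)
        y[:5], y[-5:] = 1, 0
        a = bootstrap_auc_ci(s, y, n_boot=300, seed=11)
        b = bootstrap_auc_ci(s, y, n_boot=300, seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_brackets_point_estimate(self, rng):
        s = rng.normal(size=200) + rng.integers(0, 2, 200)
        y = (s > np.median(s)).astype(int)
        s = s + rng.normal(0, 1, 200)
        r = bootstrap_auc_ci(s, y, n_boot=500, seed=3)
        assert r.ci_low <= r.auc <= r.ci_high


class TestCompareAuc:
    def test_identical_scores_null_p(self, rng):
        s = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        y[:5], y[-5:] = 1, 0
        c = compare_auc_bootstrap(s, s, y, n_boot=300, seed=0)
        assert c.p_value >= 0.9

    def test_strong_difference_detected(self, rng):
        y = np.array([1] * 200 + [0] * 200)
        strong = np.concatenate([rng.normal(2.0, 1, 200), rng.normal(0, 1, 200)])
        noise = rng.normal(size=400)
        c = compare_auc_bootstrap(strong, noise, y, n_boot=2000, seed=1)
        assert c.p_value < 0.01

    def test_symmetric_in_model_order(self, rng):
        y = np.array([1] * 50 + [0] * 70)
        a = rng.normal(size=120) + y
        b = rng.normal(size=120)
        p_ab = compare_auc_bootstrap(a, b, y, n_boot=400, seed=5).p_value
        p_ba = compare_auc_bootstrap(b, a, y, n_boot=400, seed=5).p_value
        assert p_ab == pytest.approx(p_ba)


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.uniform(1, 36, 30).round(1)
        e = np.ones(30, dtype=int)
        curve = km_estimate(t, e)
        for grid_t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(t > grid_t), abs=1e-12)

    def test_all_censored_survival_stays_one(self):
        curve = km_estimate([10.0, 20.0, 36.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_hand_worked_six_patient_set(self):
        # deaths at 3 and 10; censored at 12, 36, 36, 36:
        # S(3) = 5/6, S(10) = 5/6 * 4/5 = 2/3, flat afterwards
        curve = km_estimate([3, 10, 12, 36, 36, 36], [1, 1, 0, 0, 0, 0])
        assert curve.survival_at(3.0) == pytest.approx(5 / 6)
        assert curve.survival_at(10.0) == pytest.approx(2 / 3)
        assert curve.survival_at(36.0) == pytest.approx(2 / 3)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 5.0], [1, 1])


def logrank_oracle(t1, e1, t2, e2):
    """Direct O-E / variance computation of the two-group log-rank chi-square."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    all_t = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O1 = E1 = V = 0.0
    for t in all_t:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        O1 += d1
        E1 += d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([3.0, 8.0, 15.0, 36.0])
        e = np.array([1, 1, 0, 0])
        res = logrank_test(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_under_relabeling(self, rng):
        t1, t2 = rng.uniform(1, 36, 25), rng.uniform(1, 30, 20)
        e1, e2 = rng.integers(0, 2, 25), rng.integers(0, 2, 20)
        e1[0] = e2[0] = 1
        a = logrank_test(t1, e1, t2, e2)
        b = logrank_test(t2, e2, t1, e1)
        assert a.chi2 == pytest.approx(b.chi2)

    def test_matches_hand_computation_small_instance(self):
        t1 = [2.0, 5.0, 9.0, 14.0, 36.0]
        e1 = [1, 1, 1, 0, 0]
        t2 = [8.0, 20.0, 30.0, 36.0, 36.0]
        e2 = [1, 0, 1, 0, 0]
        res = logrank_test(t1, e1, t2, e2)
        assert res.chi2 == pytest.approx(logrank_oracle(t1, e1, t2, e2), rel=1e-9)

    def test_no_events_flagged_zero(self):
        res = logrank_test([5.0, 6.0], [0, 0], [7.0], [0])
        assert res.chi2 == 0.0
        assert res.flags


class TestMortalityRate:
    def test_zero_deaths(self):
        assert mortality_rate_per100py([36.0, 36.0], [0, 0]) == 0.0

    def test_direct_arithmetic_example(self):
        # 2 deaths at 18 months among 10 patients, 8 survivors at 36 months:
        # 100 * 2 / (2*1.5 + 8*3) patient-years
        t = [18.0] * 2 + [36.0] * 8
        e = [1] * 2 + [0] * 8
        assert mortality_rate_per100py(t, e) == pytest.approx(100 * 2 / 27, rel=1e-12)

    def test_doubling_followup_halves_rate(self):
        t = np.array([6.0, 12.0, 18.0])
        e = np.array([1, 0, 1])
        assert mortality_rate_per100py(2 * t, e) == pytest.approx(
            mortality_rate_per100py(t, e) / 2
        )

    def test_zero_followup_rejected(self):
        with pytest.raises(ValueError):
            mortality_rate_per100py([0.0], [1])


class TestLogisticComparator:
    def test_known_coefficient_recovery_coverage(self):
        # simulate logistic data at n = 5000; each true coefficient should
        # fall inside its 95% Wald CI in >= 90% of replicates
        rng = np.random.default_rng(7)
        true_beta = np.array([0.4, -0.6, 0.25])
        inside = np.zeros(3)
        reps = 50
        for _ in range(reps):
            X = rng.normal(size=(5000, 3))
            p = 1 / (1 + np.exp(-(0.2 + X @ true_beta)))
            y_poor = (rng.random(5000) < p).astype(int)
            df = pd.DataFrame(X, columns=["age", "alb_gdl", "hb_gdl"])
            res = fit_logistic_comparator(df, variables=["age", "alb_gdl", "hb_gdl"],
                                          outcome=y_poor)
            tab = res.table.drop(index="const")
            lo = np.log(tab["or_ci_low"].to_numpy())
            hi = np.log(tab["or_ci_high"].to_numpy())
            inside += (lo <= true_beta) & (true_beta <= hi)
        assert np.all(inside / reps >= 0.90)

    def test_null_calibration_statistic_mean_near_df(self):
        rng = np.random.default_rng(11)
        stats_out = []
        for _ in range(200):
            x = rng.normal(size=(400, 1))
            p = 1 / (1 + np.exp(-(x[:, 0] - 1.5)))
            y = (rng.random(400) < p).astype(float)
            import statsmodels.api as sm

            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            stat, _, df = hosmer_lemeshow(y, np.asarray(fit.predict()))
            stats_out.append(stat)
        mean = np.mean(stats_out)
        se = np.std(stats_out) / np.sqrt(len(stats_out))
        assert abs(mean - df) < 4 * se + 0.5

    def test_constant_covariate_dropped_with_flag(self, small_cohort):
        df = small_cohort.df.copy()
        df["heart_failure"] = 0
        res = fit_logistic_comparator(df)
        assert any("heart_failure" in f for f in res.flags)
        assert "heart_failure" not in res.table.index

    def test_intercept_only_matches_base_rate(self, small_cohort):
        df = small_cohort.df.copy()
        df["age"] = 50.0
        res = fit_logistic_comparator(df, variables=["age"])
        y_poor = 1 - ((df["survival_months"] >= 36) & (df["died_within_36m"] == 0)).astype(int)
        base = y_poor.mean()
        assert res.table.loc["const", "coefficient"] == pytest.approx(
            np.log(base / (1 - base)), abs=1e-6
        )


class TestEgfrRiskScores:
    def test_orientation_negates_egfr(self, small_cohort):
        from difekit.egfr import egfr_cmdrd

        df = small_cohort.df
        s = egfr_risk_scores(df, "cmdrd")
        direct = egfr_cmdrd(
            df["scr_mgdl"].to_numpy(), df["age"].to_numpy(), df["bun_mgdl"].to_numpy(),
            df["alb_gdl"].to_numpy(), female=df["female"].to_numpy(dtype=bool),
        )
        np.testing.assert_allclose(s, -direct)

    def test_unknown_equation_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            egfr_risk_scores(small_cohort.df, "schwartz")
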