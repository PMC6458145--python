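"""Outlier removal, PSO equation fitting and threshold selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from difekit.cohort import Cohort, SyntheticCohortConfig, generate_cohort
from difekit.simulation import simulate_equation_cohort
from difekit.tsfnn import (
    DEFAULT_THRESHOLD_GRID,
    DifeModel,
    PsoConfig,
    fit_dife,
    remove_outliers,
    select_threshold,
)

FAST_PSO = dict(swarm_size=30, max_iterations=60, cv_early_stop=False)


class TestRemoveOutliers:
    def test_clean_cohort_untouched(self, small_cohort):
        out, removed = remove_outliers(small_cohort, cutoff=6.0)
        assert removed == []
        assert len(out) == len(small_cohort)

    def test_injected_extreme_record_removed(self, small_cohort):
        df = small_cohort.df.copy()
        target = df.loc[5, "patient_id"]
        # ~10 SD above the creatinine mean (still a valid positive lab)
        df.loc[5, "scr_mgdl"] = df["scr_mgdl"].mean() + 10 * df["scr_mgdl"].std()
        out, removed = remove_outliers(Cohort(df, "t"), rule="zscore", cutoff=4.0)
        assert removed == [target]
        assert len(out) == len(df) - 1

    def test_removal_log_matches_size_difference(self, small_cohort):
        out, removed = remove_outliers(small_cohort, rule="iqr", cutoff=1.5)
        assert len(removed) == len(small_cohort) - len(out)

    def test_bad_cutoff_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            remove_outliers(small_cohort, cutoff=0.0)

    def test_unknown_rule_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            remove_outliers(small_cohort, rule="grubbs")


class TestFitDife:
    def test_global_best_trace_non_increasing(self):
        gt = simulate_equation_cohort(400, seed=1)
        model = DifeModel(PsoConfig(seed=1, **FAST_PSO)).fit(gt.cohort.df, gt.good_survival)
        assert np.all(np.diff(model.loss_trace_) <= 0)

    def test_seeded_determinism(self):
        gt = simulate_equation_cohort(300, seed=2)
        cfg = PsoConfig(seed=9, **FAST_PSO)
        p1, _ = fit_dife(gt.cohort, cfg)
        p2, _ = fit_dife(gt.cohort, cfg)
        assert p1 == p2

    def test_single_outcome_rejected(self, small_cohort):
        y = np.ones(len(small_cohort))
        with pytest.raises(ValueError, match="both"):
            DifeModel(PsoConfig(**FAST_PSO)).fit(small_cohort.df, y)

    def test_training_loss_beats_constant_baseline(self):
        # the intercept-only score cannot be beaten by less than the fit
        for seed in range(3):
            gt = simulate_equation_cohort(350, seed=100 + seed)
            model = DifeModel(PsoConfig(seed=seed, **FAST_PSO)).fit(
                gt.cohort.df, gt.good_survival
            )
            base = gt.good_survival.mean()
            base_ce = -(base * np.log(base) + (1 - base) * np.log(1 - base))
            assert model.loss_trace_[-1] <= base_ce + 1e-12

    def test_parameter_recovery_on_held_out_cohort(self):
        dev = simulate_equation_cohort(1200, seed=31)
        val = simulate_equation_cohort(400, seed=32, link_c=dev.link_c)
        model = DifeModel(PsoConfig(seed=3, max_iterations=200, cv_early_stop=False)).fit(
            dev.cohort.df, dev.good_survival
        )
        fitted = model.decision_function(val.cohort.df)
        rho = spearmanr(fitted, val.true_scores).statistic
        assert rho >= 0.9

    def test_anchored_scale_preserves_probabilities(self):
        gt = simulate_equation_cohort(300, seed=4)
        cfg_raw = PsoConfig(seed=5, anchor=None, **FAST_PSO)
        cfg_anchored = PsoConfig(seed=5, anchor=(30.0, 5.0), **FAST_PSO)
        raw = DifeModel(cfg_raw).fit(gt.cohort.df, gt.good_survival)
        anc = DifeModel(cfg_anchored).fit(gt.cohort.df, gt.good_survival)
        np.testing.assert_allclose(
            raw.predict_proba(gt.cohort.df), anc.predict_proba(gt.cohort.df), rtol=1e-8
        )
        assert anc.c_ == 30.0 and anc.s_ == 5.0

    def test_cv_early_stop_records_traces(self):
        gt = simulate_equation_cohort(300, seed=6)
        cfg = PsoConfig(seed=7, swarm_size=20, max_iterations=25, n_folds=4, cv_early_stop=True)
        model = DifeModel(cfg).fit(gt.cohort.df, gt.good_survival)
        assert model.cv_val_traces_.shape == (4, 25)
        assert 1 <= model.n_iter_ <= 25


def brute_force_threshold_row(scores, y_poor, t):
    tp = fn = tn = fp = 0
    for s, y in zip(scores, y_poor):
        pred = s < t
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and y:
            fn += 1
        else:
            tn += 1
    return (
        tp / (tp + fn) if tp + fn else np.nan,
        tn / (tn + fp) if tn + fp else np.nan,
        (tp + tn) / len(scores),
    )


class TestSelectThreshold:
    def test_default_candidate_grid(self):
        assert DEFAULT_THRESHOLD_GRID == (29.0, 30.0, 31.0, 32.0, 33.0)

    def test_perfect_separation(self):
        scores = np.array([20.0] * 10 + [40.0] * 30)
        y_poor = np.array([1] * 10 + [0] * 30)
        report = select_threshold(scores, y_poor, candidates=[30.0])
        row = report.table.iloc[0]
        assert row["sensitivity"] == row["specificity"] == row["accuracy"] == 1.0

    def test_matches_brute_force_confusion_matrix(self, rng):
        scores = rng.uniform(25, 35, 200)
        y_poor = rng.integers(0, 2, 200)
        report = select_threshold(scores, y_poor)
        for _, row in report.table.iterrows():
            sens, spec, acc = brute_force_threshold_row(scores, y_poor, row["threshold"])
            assert row["sensitivity"] == pytest.approx(sens, nan_ok=True)
            assert row["specificity"] == pytest.approx(spec, nan_ok=True)
            assert row["accuracy"] == pytest.approx(acc)

    def test_group_sizes_sum_to_cohort(self, rng):
        scores = rng.uniform(25, 35, 150)
        y_poor = rng.integers(0, 2, 150)
        report = select_threshold(scores, y_poor)
        assert ((report.table["n_pred_poor"] + report.table["n_pred_good"]) == 150).all()

    def test_shift_invariance(self, rng):
        scores = rng.uniform(25, 35, 120)
        y_poor = rng.integers(0, 2, 120)
        a = select_threshold(scores, y_poor, candidates=[29, 30, 31])
        b = select_threshold(scores + 100.0, y_poor, candidates=[129, 130, 131])
        pd.testing.assert_frame_equal(
            a.table.drop(columns="threshold"), b.table.drop(columns="threshold")
        )
        assert b.chosen_threshold == a.chosen_threshold + 100.0

    def test_sensitivity_floor_governs_choice(self):
        # the most accurate threshold misses too many poor survivors; the
        # floor forces the next candidate up
        scores = np.array([28.5] * 3 + [29.5] * 4 + [35.0] * 3 + [29.2] * 20 + [40.0] * 70)
        y_poor = np.array([1] * 10 + [0] * 90)
        report = select_threshold(scores, y_poor, candidates=[29.0, 30.0],
                                  sensitivity_floor=0.4)
        assert report.chosen_threshold == 30.0
        unconstrained = select_threshold(scores, y_poor, candidates=[29.0, 30.0],
                                         sensitivity_floor=0.0)
        assert unconstrained.chosen_threshold == 29.0

    def test_mortality_columns_present_with_followup(self, small_cohort):
        df = small_cohort.df
        scores = np.linspace(25, 35, len(df))
        y_poor = 1 - ((df["survival_months"] >= 36) & (df["died_within_36m"] == 0)).astype(int)
        report = select_threshold(scores, y_poor, times=df["survival_months"],
                                  events=df["died_within_36m"])
        assert "mortality_per100py_pred_poor" in report.table.columns

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(np.ones(5), np.ones(4))
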