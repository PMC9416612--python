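import numpy as np
import pytest

from serumnmr.dataset import make_sample_table
from serumnmr.models import OPLS, ColumnScaler, encode_classes
from serumnmr.simulate import SimulationConfig, simulate_cohort
from serumnmr.validation import (
    bayesian_thresholds,
    block_geometry,
    classify_and_score,
    cross_validate,
    make_cv_plan,
    permutation_test,
)

from helpers import toy_dataset


def triplicate_table(n_subjects, n_case=None):
    n_case = n_subjects // 2 if n_case is None else n_case
    ids = [f"P{i:03d}" for i in range(n_subjects)]
    labels = ["Schizophrenia"] * n_case + ["Control"] * (n_subjects - n_case)
    return make_sample_table(ids, labels, 3)


class TestCVPlan:
    def test_block_geometry_matches_triplicate_arithmetic(self):
        assert block_geometry(265, 3, 7) == (13, 39)
        assert block_geometry(21, 3, 7) == (1, 3)

    def test_seven_subjects_seven_folds_one_subject_each(self):
        plan = make_cv_plan(triplicate_table(7), n_folds=7, seed=0)
        assert plan.n_folds == 7
        assert plan.block_size_samples == 3
        counts = np.bincount(plan.fold_of_sample)
        assert np.all(counts == 3)

    def test_no_subject_ever_splits_across_folds(self):
        table = triplicate_table(20)
        for seed in range(10):
            plan = make_cv_plan(table, n_folds=7, seed=seed)
            grouped = table.assign(fold=plan.fold_of_sample).groupby("subject_id")[
                "fold"
            ]
            assert grouped.nunique().eq(1).all()

    def test_unequal_replicate_counts_rejected(self):
        table = triplicate_table(6).iloc[:-1]  # break one triplicate
        with pytest.raises(ValueError):
            make_cv_plan(table, n_folds=3, seed=0)

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(triplicate_table(5), n_folds=7, seed=0)


class TestCrossValidate:
    def test_separable_cohort_reaches_low_rmsecv(self, library):
        # noiseless, doubled marker concentrations: near-perfect separation
        fc = {m: 2.0 for m in (
            "lactate", "alanine", "glucose", "glycine",
            "glutamine", "valine", "isoleucine", "citrate",
        )}
        config = SimulationConfig(
            n_subjects_per_class=(5, 5), grid=(0.0, 10.0, 4096),
            noise_sd=0.0, baseline_slope_range=(0.0, 0.0),
            baseline_offset_range=(0.0, 0.0), shift_jitter_sd=0.0,
            global_shift_sd=0.0,
            dilution_log_sd=0.0, concentration_cv=0.05,
            marker_fold_changes=fc, include_water_hump=False,
            include_lipid_humps=False, seed=5,
        )
        ds = simulate_cohort(library, config)
        plan = make_cv_plan(ds.samples, n_folds=5, seed=1)
        metrics = cross_validate(ds, plan, "auto", max_orth=2)
        assert metrics.rmsecv[metrics.chosen_components] < 0.05

    def test_rmsec_non_increasing_in_components(self, small_cohort):
        plan = make_cv_plan(small_cohort.samples, n_folds=7, seed=2)
        metrics = cross_validate(small_cohort, plan, "auto", max_orth=3)
        assert np.all(np.diff(metrics.rmsec) <= 1e-10)

    def test_rmsecv_matches_plain_fold_loop_oracle(self, small_cohort):
        ds = small_cohort
        plan = make_cv_plan(ds.samples, n_folds=7, seed=3)
        metrics = cross_validate(ds, plan, "auto", max_orth=1)

        y, _ = encode_classes(ds.class_labels)
        X = ds.intensities
        for i, k in enumerate([0, 1]):
            sq = []
            for fold in range(plan.n_folds):
                test = plan.fold_of_sample == fold
                scaler = ColumnScaler("auto").fit(X[~test])
                model = OPLS(n_orthogonal=k).fit(scaler.transform(X[~test]), y[~test])
                pred = model.predict(scaler.transform(X[test]))
                sq.extend((pred - y[test]) ** 2)
            assert metrics.rmsecv[i] == pytest.approx(np.sqrt(np.mean(sq)), abs=1e-12)


class TestBayesianThresholds:
    def make_preds(self, m0, s0, n0, m1, s1, n1, seed=0):
        rng = np.random.default_rng(seed)
        yhat = np.concatenate(
            [rng.normal(m1, s1, size=n1), rng.normal(m0, s0, size=n0)]
        )
        labels = np.array(["Schizophrenia"] * n1 + ["Control"] * n0)
        return yhat, labels

    def test_symmetric_classes_give_midpoint_threshold(self):
        # construct calibration predictions with exactly mirrored moments
        base = np.array([-1.5, -0.5, 0.5, 1.5]) * 0.1
        yhat = np.concatenate([0.8 + base, 0.2 + base])
        labels = np.array(["Schizophrenia"] * 4 + ["Control"] * 4)
        tm = bayesian_thresholds(yhat, labels, prior="equal")
        assert tm.thresholds["Schizophrenia"] == pytest.approx(0.5, abs=1e-10)

    def test_threshold_matches_grid_search_posterior_oracle(self):
        yhat, labels = self.make_preds(0.2, 0.05, 40, 0.8, 0.15, 60, seed=4)
        tm = bayesian_thresholds(yhat, labels, prior="proportions")
        (m1, s1) = tm.class_stats["Schizophrenia"]
        (m0, s0) = tm.class_stats["Control"]
        pi1, pi0 = tm.priors["Schizophrenia"], tm.priors["Control"]
        grid = np.arange(min(m0, m1), max(m0, m1), 1e-5)
        post1 = pi1 * np.exp(-0.5 * ((grid - m1) / s1) ** 2) / s1
        post0 = pi0 * np.exp(-0.5 * ((grid - m0) / s0) ** 2) / s0
        oracle = grid[np.argmin(np.abs(post1 - post0))]
        assert tm.thresholds["Schizophrenia"] == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_class_thresholds_sum_to_one(self, seed):
        yhat, labels = self.make_preds(0.25, 0.1, 30, 0.75, 0.2, 45, seed=seed)
        tm = bayesian_thresholds(yhat, labels)
        assert sum(tm.thresholds.values()) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_overlap_falls_back_to_midpoint(self):
        # identical class distributions: no posterior crossing between means
        yhat = np.array([0.5, 0.6, 0.4, 0.5, 0.6, 0.4])
        labels = np.array(["Schizophrenia"] * 3 + ["Control"] * 3)
        tm = bayesian_thresholds(yhat, labels, prior="equal")
        assert tm.fallback_used
        assert tm.thresholds["Schizophrenia"] == pytest.approx(0.5)


class TestClassifyAndScore:
    def table1_style_predictions(self):
        """30 correct + 2 missed cases and 39 correct controls."""
        yhat = np.concatenate([np.full(30, 0.9), np.full(2, 0.1), np.full(39, 0.1)])
        actual = np.array(["Schizophrenia"] * 32 + ["Control"] * 39)
        return yhat, actual

    def test_published_confusion_matrix_accuracy(self):
        yhat, actual = self.table1_style_predictions()
        tm = bayesian_thresholds(
            np.concatenate([np.array([0.85, 0.9, 0.95] * 10 + [0.1, 0.15]),
                            np.array([0.05, 0.1, 0.15] * 13)]),
            np.array(["Schizophrenia"] * 32 + ["Control"] * 39),
        )
        tm.thresholds = {"Schizophrenia": 0.4086, "Control": 0.5914}
        cm = classify_and_score(yhat, tm, actual)
        assert cm.counts.loc["Schizophrenia", "Schizophrenia"] == 30
        assert cm.counts.loc["Control", "Schizophrenia"] == 2
        assert cm.counts.loc["Control", "Control"] == 39
        assert cm.counts.loc["Unassigned"].sum() == 0
        assert round(cm.accuracy, 4) == 0.9718

    def test_all_correct_gives_accuracy_one(self):
        yhat = np.array([0.9, 0.9, 0.1, 0.1])
        actual = np.array(["Schizophrenia"] * 2 + ["Control"] * 2)
        tm = bayesian_thresholds(
            np.array([0.8, 0.9, 1.0, 0.0, 0.1, 0.2]),
            np.array(["Schizophrenia"] * 3 + ["Control"] * 3),
        )
        cm = classify_and_score(yhat, tm, actual)
        assert cm.accuracy == 1.0
        assert cm.counts.to_numpy().sum() == 4

    def test_matrix_matches_explicit_counting_loop(self):
        rng = np.random.default_rng(12)
        yhat = rng.uniform(0, 1, size=20)
        actual = rng.choice(["Schizophrenia", "Control"], size=20)
        tm = bayesian_thresholds(
            rng.normal(0.7, 0.1, 30).tolist() + rng.normal(0.3, 0.1, 30).tolist(),
            ["Schizophrenia"] * 30 + ["Control"] * 30,
        )
        cm = classify_and_score(yhat, tm, actual)
        th_pos, th_neg = tm.thresholds["Schizophrenia"], tm.thresholds["Control"]
        expected = {("Schizophrenia", c): 0 for c in ("Schizophrenia", "Control")}
        expected.update({("Control", c): 0 for c in ("Schizophrenia", "Control")})
        expected.update({("Unassigned", c): 0 for c in ("Schizophrenia", "Control")})
        correct = 0
        for v, a in zip(yhat, actual):
            fire_pos = v >= th_pos
            fire_neg = (1 - v) >= th_neg
            if fire_pos and not fire_neg:
                pred = "Schizophrenia"
            elif fire_neg and not fire_pos:
                pred = "Control"
            else:
                pred = "Unassigned"
            expected[(pred, a)] += 1
            correct += pred == a
        for (pred, a), cnt in expected.items():
            assert cm.counts.loc[pred, a] == cnt
        assert cm.accuracy == pytest.approx(correct / 20)

    def test_accuracy_complements_miss_and_unassigned(self):
        rng = np.random.default_rng(3)
        yhat = rng.uniform(0, 1, size=40)
        actual = rng.choice(["Schizophrenia", "Control"], size=40)
        tm = bayesian_thresholds(
            rng.normal(0.7, 0.15, 30).tolist() + rng.normal(0.35, 0.15, 30).tolist(),
            ["Schizophrenia"] * 30 + ["Control"] * 30,
        )
        cm = classify_and_score(yhat, tm, actual)
        wrong = 0
        neg, pos = tm.classes
        for a in (neg, pos):
            for pred in (neg, pos, "Unassigned"):
                if pred != a:
                    wrong += cm.counts.loc[pred, a]
        assert cm.accuracy == pytest.approx(1 - wrong / 40)


class TestPermutationTest:
    def separable_cohort(self, library):
        # 8+8 subjects: the chance that any of 99 subject-level permutations
        # reproduces the true labeling (or its mirror) is ~2/12870 per draw
        config = SimulationConfig(
            n_subjects_per_class=(8, 8), grid=(0.0, 10.0, 1024),
            noise_sd=0.5, shift_jitter_sd=0.0,
            global_shift_sd=0.0, dilution_log_sd=0.0,
            baseline_slope_range=(0.0, 0.0), baseline_offset_range=(0.0, 0.0),
            marker_fold_changes={"glucose": 2.0, "lactate": 2.0, "alanine": 2.0},
            seed=30,
        )
        return simulate_cohort(library, config)

    def test_strong_effect_reaches_minimum_p(self, library):
        ds = self.separable_cohort(library)
        result = permutation_test(
            ds, plan_seed=0, n_folds=8, scaling_method="auto",
            n_orth=1, n_iter=99, seed=0,
        )
        assert result.observed == 1.0
        assert result.p_value == pytest.approx(1 / 100)

    def test_identity_permutation_reproduces_observed(self, library):
        from serumnmr.validation import _cv_statistic, make_cv_plan

        ds = self.separable_cohort(library)
        plan = make_cv_plan(ds.samples, 8, seed=0)
        a = _cv_statistic(
            ds.intensities, ds.class_labels, ds.samples, plan, "auto", 1,
            "cv_accuracy",
        )
        b = _cv_statistic(
            ds.intensities, ds.class_labels, ds.samples, plan, "auto", 1,
            "cv_accuracy",
        )
        assert a == b

    def test_rmsecv_statistic_direction(self, library):
        ds = self.separable_cohort(library)
        result = permutation_test(
            ds, plan_seed=0, n_folds=8, scaling_method="auto",
            n_orth=1, n_iter=19, seed=1, statistic="rmsecv",
        )
        assert result.p_value == pytest.approx(1 / 20)
        assert np.all(result.null_statistics >= result.observed)
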