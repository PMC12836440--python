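import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from condylefd.classify import (
    ConfusionMatrix,
    UnsupportedModelError,
    benchmark,
    build_features,
    cross_validate,
    feature_importance,
    make_models,
    metrics_from_confusion,
    pr_points,
    report_table,
    roc_points,
    stratified_split,
    train_models,
)
from condylefd.synthetic import simulate_cohort


def separable_cohort(n_per_group=60, seed=0):
    """Label determined by a wide lc_fd gap: trivially separable."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, lc_centre in (("patient", 0.6), ("control", 1.8)):
        for i in range(n_per_group):
            rows.append(
                {
                    "subject_id": f"{group[0]}{i}",
                    "age": int(rng.integers(18, 76)),
                    "gender": rng.choice(["male", "female"]),
                    "group": group,
                    "lc_fd": lc_centre + rng.normal(0, 0.02),
                    "rc_fd": rng.normal(1.25, 0.08),
                }
            )
    return pd.DataFrame(rows)


class FixedScores:
    """Minimal score-emitting stub for curve functions."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def decision_function(self, X):
        return self.scores[: len(X)]


class TestBuildFeatures:
    def test_partition_sizes_use_largest_remainder(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        assert (len(f.idx_train), len(f.idx_val), len(f.idx_test)) == (154, 33, 33)
        # stratification: equal class counts in train
        assert f.y_train.sum() == 77

    def test_same_seed_gives_identical_partitions(self, default_cohort):
        a = build_features(default_cohort, seed=42)
        b = build_features(default_cohort, seed=42)
        assert np.array_equal(a.idx_train, b.idx_train)
        assert np.array_equal(a.idx_test, b.idx_test)
        assert np.array_equal(a.X, b.X)

    def test_label_shuffle_keeps_partition_sizes(self, default_cohort, rng):
        shuffled = default_cohort.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        f = build_features(shuffled, seed=42)
        assert (len(f.idx_train), len(f.idx_val), len(f.idx_test)) == (154, 33, 33)

    def test_train_columns_are_z_scored(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        assert np.abs(f.X_train.mean(axis=0)).max() < 1e-9
        assert np.abs(f.X_train.std(axis=0) - 1).max() < 1e-9

    def test_scaler_fit_ignores_validation_and_test_rows(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        tampered = default_cohort.copy()
        non_train = np.concatenate([f.idx_val, f.idx_test])
        tampered.loc[tampered.index[non_train], ["lc_fd", "rc_fd"]] += 10.0
        g = build_features(tampered, seed=42)
        assert np.array_equal(f.scaler_mean, g.scaler_mean)
        assert np.array_equal(f.scaler_sd, g.scaler_sd)

    def test_missing_fields_name_offending_subjects(self, default_cohort):
        broken = default_cohort.copy()
        broken.loc[3, "lc_fd"] = np.nan
        bad_id = broken.loc[3, "subject_id"]
        with pytest.raises(ValueError, match=bad_id):
            build_features(broken)

    def test_bad_split_fractions_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            build_features(default_cohort, fractions=(0.5, 0.5, 0.5))

    def test_stratified_split_covers_all_rows_once(self, rng):
        labels = rng.integers(0, 2, size=173)
        tr, va, te = stratified_split(labels, seed=1)
        combined = np.concatenate([tr, va, te])
        assert len(combined) == 173
        assert len(np.unique(combined)) == 173


class TestConfusionMetrics:
    def test_published_test_accuracy(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=49, tn=35, fp=5, fn=5))
        assert round(m.accuracy, 4) == 0.8936

    def test_control_positive_view_balances_precision_recall(self):
        cm = ConfusionMatrix(tp=49, tn=35, fp=5, fn=5).swapped()
        m = metrics_from_confusion(cm)
        assert m.precision == m.recall == m.f1 == pytest.approx(0.8750)
        assert cm.positive_label == "control"

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=10, tn=10, fp=0, fn=0))
        assert m.accuracy == m.precision == m.recall == m.f1 == 1.0

    def test_undefined_metrics_are_flagged_not_zero(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, tn=5, fp=0, fn=5))
        assert m.precision is None
        assert "precision" in m.undefined

    def test_f1_is_harmonic_mean(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=30, tn=20, fp=10, fn=4))
        assert m.f1 == pytest.approx(2 * m.precision * m.recall / (m.precision + m.recall))


class TestTraining:
    def test_all_models_fit_separable_data_perfectly(self):
        f = build_features(separable_cohort(), seed=42)
        models = train_models(f, seed=42)
        for name, model in models.items():
            acc = (model.predict(f.X_train) == f.y_train).mean()
            assert acc == 1.0, name

    def test_single_class_training_rejected(self, default_cohort):
        all_pat = default_cohort.copy()
        all_pat["group"] = "patient"
        f = build_features(all_pat, seed=42)
        with pytest.raises(ValueError):
            train_models(f)

    def test_same_seed_gives_identical_predictions(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        a = train_models(f, seed=42)
        b = train_models(f, seed=42)
        for name in a:
            assert np.array_equal(a[name].predict(f.X_test), b[name].predict(f.X_test)), name


class TestCrossValidation:
    def test_five_folds_on_220_rows(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        cv = cross_validate(make_models(42)["logistic_regression"], f, k=5, seed=42)
        assert all(len(v) == 5 for v in cv.values())

    def test_separable_data_reaches_auc_one(self):
        f = build_features(separable_cohort(), seed=42)
        cv = cross_validate(make_models(42)["logistic_regression"], f, k=5, seed=42)
        assert cv["roc_auc"].mean() == 1.0
        assert cv["roc_auc"].std(ddof=1) == 0.0

    def test_degenerate_folds_raise_with_guidance(self):
        f = build_features(separable_cohort(n_per_group=12), seed=42)
        with pytest.raises(ValueError, match="folds|stratif"):
            cross_validate(make_models(42)["logistic_regression"], f, k=30, seed=42)

    def test_benchmark_ranks_six_models(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        reports = benchmark(f, k=5, seed=42)
        assert len(reports) == 6
        assert [r.rank for r in reports] == list(range(1, 7))
        accs = [r.cv_mean("accuracy") for r in reports]
        assert accs == sorted(accs, reverse=True)
        table = report_table(reports)
        assert len(table) == 6 and "±" in table.loc[0, "accuracy"]


class TestCurves:
    def test_perfect_and_antiperfect_scores(self):
        y = np.array([0, 0, 1, 1])
        pts = roc_points(FixedScores([0.1, 0.2, 0.8, 0.9]), np.zeros((4, 1)), y)
        fpr, tpr, _ = zip(*pts)
        assert np.trapezoid(tpr, fpr) == pytest.approx(1.0)
        pts = roc_points(FixedScores([0.9, 0.8, 0.2, 0.1]), np.zeros((4, 1)), y)
        fpr, tpr, _ = zip(*pts)
        assert np.trapezoid(tpr, fpr) == pytest.approx(0.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=2000)
        scores = rng.random(2000)
        pts = roc_points(FixedScores(scores), np.zeros((2000, 1)), y)
        fpr, tpr, _ = zip(*pts)
        assert abs(np.trapezoid(tpr, fpr) - 0.5) < 0.05

    def test_trapezoid_auc_consistent_with_reported(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        model = train_models(f, seed=42)["logistic_regression"]
        pts = roc_points(model, f.X_test, f.y_test)
        fpr, tpr, _ = zip(*pts)
        direct = roc_auc_score(f.y_test, model.predict_proba(f.X_test)[:, 1])
        assert np.trapezoid(tpr, fpr) == pytest.approx(direct, abs=1e-9)

    def test_pr_points_monotone_recall(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        model = train_models(f, seed=42)["xgboost"]
        recall = [p[0] for p in pr_points(model, f.X_test, f.y_test)]
        assert all(a >= b for a, b in zip(recall, recall[1:]))


class TestFeatureImportance:
    def test_normalized_and_sorted(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        imp = feature_importance(train_models(f, seed=42)["xgboost"])
        values = [v for _, v in imp]
        assert sum(values) == pytest.approx(1.0, abs=1e-9)
        assert values == sorted(values, reverse=True)

    def test_label_driven_by_lc_fd_ranks_it_first(self):
        f = build_features(separable_cohort(), seed=42)
        imp = feature_importance(train_models(f, seed=42)["xgboost"])
        assert imp[0][0] == "lc_fd"

    def test_constant_feature_has_zero_importance(self):
        cohort = separable_cohort()
        cohort["gender"] = "male"  # constant column
        f = build_features(cohort, seed=42)
        imp = dict(feature_importance(train_models(f, seed=42)["random_forest"]))
        assert imp["gender"] == 0.0

    def test_scoreless_model_rejected(self, default_cohort):
        f = build_features(default_cohort, seed=42)
        knn = train_models(f, seed=42)["k_nearest_neighbors"]
        with pytest.raises(UnsupportedModelError):
            feature_importance(knn)


def test_null_features_calibrate_near_chance():
    """Pure-noise features: every family's CV AUC sits near 0.5."""
    rng = np.random.default_rng(21)
    cohort = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(200)],
            "age": rng.integers(18, 76, 200),
            "gender": rng.choice(["male", "female"], 200),
            "group": np.repeat(["patient", "control"], 100),
            "lc_fd": rng.normal(1.25, 0.08, 200),
            "rc_fd": rng.normal(1.25, 0.08, 200),
        }
    )
    f = build_features(cohort, seed=42)
    for name, model in make_models(42).items():
        cv = cross_validate(model, f, k=5, seed=42)
        assert abs(cv["roc_auc"].mean() - 0.5) < 0.15, name
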