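"""Tabular classifier benchmark for patient-vs-control discrimination.

Features are age, gender (male=0 / female=1), and the two condylar
fractal dimensions (lc_fd, rc_fd); the label is group (patient=1,
control=0 by default).  Rows are split 70/15/15 into train / validation
/ test partitions, stratified by label with largest-remainder rounding;
standardization parameters are fit on the training partition only.  Six
classifier families are benchmarked at their library defaults with
5-fold cross-validated metrics and held-out point metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "MODEL_NAMES",
    "FEATURE_COLUMNS",
    "FeatureMatrix",
    "ConfusionMatrix",
    "Metrics",
    "ClassifierReport",
    "UnsupportedModelError",
    "make_models",
    "build_features",
    "stratified_split",
    "metrics_from_confusion",
    "cross_validate",
    "train_models",
    "benchmark",
    "report_table",
    "roc_points",
    "pr_points",
    "feature_importance",
    "model_manifest",
]

FEATURE_COLUMNS = ("age", "gender", "lc_fd", "rc_fd")

MODEL_NAMES = (
    "random_forest",
    "logistic_regression",
    "support_vector_machine",
    "gradient_boosting",
    "k_nearest_neighbors",
    "xgboost",
)


class UnsupportedModelError(TypeError):
    """Raised when an operation needs a capability the model lacks."""


def make_models(seed: int = 42) -> dict:
    """The six classifier families at their library defaults.

    The seed is applied wherever the family is stochastic; every other
    hyperparameter stays at its implementation's documented default
    (serialize them with :func:`model_manifest`).
    """
    return {
        "random_forest": RandomForestClassifier(random_state=seed),
        "logistic_regression": LogisticRegression(random_state=seed),
        "support_vector_machine": SVC(probability=True, random_state=seed),
        "gradient_boosting": GradientBoostingClassifier(random_state=seed),
        "k_nearest_neighbors": KNeighborsClassifier(),
        "xgboost": XGBClassifier(random_state=seed, n_jobs=1),
    }


@dataclass(frozen=True)
class FeatureMatrix:
    """Standardized features with fixed train/validation/test partitions."""

    X: np.ndarray  # all rows, standardized with train-fit parameters
    y: np.ndarray  # patient=1, control=0 (by default)
    feature_names: tuple[str, ...]
    idx_train: np.ndarray
    idx_val: np.ndarray
    idx_test: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    positive_label: str = "patient"

    @property
    def X_train(self) -> np.ndarray:
        return self.X[self.idx_train]

    @property
    def y_train(self) -> np.ndarray:
        return self.y[self.idx_train]

    @property
    def X_val(self) -> np.ndarray:
        return self.X[self.idx_val]

    @property
    def y_val(self) -> np.ndarray:
        return self.y[self.idx_val]

    @property
    def X_test(self) -> np.ndarray:
        return self.X[self.idx_test]

    @property
    def y_test(self) -> np.ndarray:
        return self.y[self.idx_test]


def stratified_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 42,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label-stratified 3-way split with largest-remainder rounding.

    Global partition sizes follow largest-remainder rounding of
    n * fraction; within each class the same rule applies, with leftover
    slots steered to whichever partitions are still short.  Deterministic
    per seed.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    n = len(labels)
    rng = np.random.default_rng(seed)

    def largest_remainder(total: int, fracs) -> list[int]:
        quotas = [total * f for f in fracs]
        base = [int(np.floor(q)) for q in quotas]
        short = total - sum(base)
        order = np.argsort([-(q - b) for q, b in zip(quotas, base)], kind="stable")
        for j in order[:short]:
            base[j] += 1
        return base

    targets = largest_remainder(n, fractions)
    deficits = list(targets)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        quotas = [len(idx) * f for f in fractions]
        counts = [int(np.floor(q)) for q in quotas]
        extra = len(idx) - sum(counts)
        order = np.argsort([-(q - c) for q, c in zip(quotas, counts)], kind="stable")
        for j in order:
            if extra == 0:
                break
            if deficits[j] - counts[j] > 0:
                counts[j] += 1
                extra -= 1
        # Any residue goes to the partition that is still shortest.
        while extra > 0:
            j = int(np.argmax([d - c for d, c in zip(deficits, counts)]))
            counts[j] += 1
            extra -= 1
        pos = 0
        for j, c in enumerate(counts):
            parts[j].extend(idx[pos : pos + c].tolist())
            deficits[j] -= c
            pos += c
    return tuple(np.sort(np.asarray(p, dtype=int)) for p in parts)


def build_features(
    cohort: pd.DataFrame,
    seed: int = 42,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    positive_label: str = "patient",
) -> FeatureMatrix:
    """Encode, split, and standardize a cohort table.

    Standardization (z-scoring, population SD) is fit on the training
    partition only and applied unchanged to validation and test rows —
    the no-leakage contract.
    """
    required = set(FEATURE_COLUMNS) | {"group", "subject_id"}
    missing_cols = required - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort is missing columns: {sorted(missing_cols)}")
    bad = cohort[cohort[list(required)].isna().any(axis=1)]
    if len(bad):
        raise ValueError(
            f"cohort rows with missing fields for subjects: {bad['subject_id'].tolist()}"
        )
    gender = cohort["gender"].map({"male": 0.0, "female": 1.0})
    if gender.isna().any():
        raise ValueError("gender must be 'male' or 'female'")
    X = np.column_stack(
        [
            cohort["age"].to_numpy(dtype=float),
            gender.to_numpy(dtype=float),
            cohort["lc_fd"].to_numpy(dtype=float),
            cohort["rc_fd"].to_numpy(dtype=float),
        ]
    )
    y = (cohort["group"] == positive_label).to_numpy(dtype=int)
    idx_train, idx_val, idx_test = stratified_split(y, fractions, seed)
    mean = X[idx_train].mean(axis=0)
    sd = X[idx_train].std(axis=0)  # population SD, as StandardScaler does
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    return FeatureMatrix(
        X=(X - mean) / sd,
        y=y,
        feature_names=FEATURE_COLUMNS,
        idx_train=idx_train,
        idx_val=idx_val,
        idx_test=idx_test,
        scaler_mean=mean,
        scaler_sd=sd,
        positive_label=positive_label,
    )


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    positive_label: str = "patient"

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions viewed with the other class as positive."""
        other = "control" if self.positive_label == "patient" else "patient"
        return ConfusionMatrix(
            tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp, positive_label=other
        )


@dataclass(frozen=True)
class Metrics:
    """Point metrics from one confusion matrix.

    A metric whose denominator is zero is undefined: its value is None
    and its name appears in ``undefined`` — never silently 0.
    """

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    undefined: tuple[str, ...] = field(default_factory=tuple)


def metrics_from_confusion(cm: ConfusionMatrix) -> Metrics:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    undefined = []
    precision = recall = f1 = None
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        undefined.append("precision")
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        undefined.append("recall")
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f1")
    return Metrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        undefined=tuple(undefined),
    )


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    raise UnsupportedModelError(f"{type(model).__name__} emits no scores")


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive_label: str) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
        positive_label=positive_label,
    )


# ---------------------------------------------------------------------------
# Training and evaluation


@dataclass(frozen=True)
class ClassifierReport:
    """Cross-validated dispersion plus held-out point metrics for one model."""

    model_name: str
    cv_metrics: dict  # metric -> np.ndarray of per-fold values
    val_metrics: Metrics
    test_metrics: Metrics
    test_confusion: ConfusionMatrix
    test_roc_auc: float
    rank: int = 0

    def cv_mean(self, metric: str) -> float:
        return float(np.mean(self.cv_metrics[metric]))

    def cv_sd(self, metric: str) -> float:
        return float(np.std(self.cv_metrics[metric], ddof=1))


def train_models(features: FeatureMatrix, seed: int = 42) -> dict:
    """Fit all six families on the training partition."""
    y = features.y_train
    if len(np.unique(y)) < 2:
        raise ValueError("training partition contains a single class")
    models = make_models(seed)
    for model in models.values():
        model.fit(features.X_train, y)
    return models


def cross_validate(
    model,
    features: FeatureMatrix,
    k: int = 5,
    seed: int = 42,
) -> dict:
    """Per-fold accuracy/precision/recall/F1/ROC-AUC over all rows.

    Folds are stratified by label; each training fold refits a clone of
    ``model``.  Returns metric -> array of k per-fold values.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    X, y = features.X, features.y
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} rows < k={k}; "
            "stratified folding would leave single-class folds — "
            "use fewer folds or more data"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    out = {m: [] for m in ("accuracy", "precision", "recall", "f1", "roc_auc")}
    for tr, te in skf.split(X, y):
        est = clone(model)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        cm = _confusion(y[te], pred, features.positive_label)
        met = metrics_from_confusion(cm)
        out["accuracy"].append(met.accuracy)
        out["precision"].append(met.precision if met.precision is not None else np.nan)
        out["recall"].append(met.recall if met.recall is not None else np.nan)
        out["f1"].append(met.f1 if met.f1 is not None else np.nan)
        out["roc_auc"].append(roc_auc_score(y[te], _scores(est, X[te])))
    return {m: np.asarray(v, dtype=float) for m, v in out.items()}


def benchmark(features: FeatureMatrix, k: int = 5, seed: int = 42) -> list[ClassifierReport]:
    """Run the full six-model benchmark, ranked by CV accuracy then AUC."""
    models = train_models(features, seed)
    reports = []
    for name, model in models.items():
        cv = cross_validate(make_models(seed)[name], features, k=k, seed=seed)
        val_cm = _confusion(
            features.y_val, model.predict(features.X_val), features.positive_label
        )
        test_cm = _confusion(
            features.y_test, model.predict(features.X_test), features.positive_label
        )
        reports.append(
            ClassifierReport(
                model_name=name,
                cv_metrics=cv,
                val_metrics=metrics_from_confusion(val_cm),
                test_metrics=metrics_from_confusion(test_cm),
                test_confusion=test_cm,
                test_roc_auc=float(
                    roc_auc_score(features.y_test, _scores(model, features.X_test))
                ),
            )
        )
    order = sorted(
        range(len(reports)),
        key=lambda i: (-reports[i].cv_mean("accuracy"), -reports[i].cv_mean("roc_auc")),
    )
    ranked = []
    for rank, i in enumerate(order, start=1):
        r = reports[i]
        ranked.append(
            ClassifierReport(
                model_name=r.model_name,
                cv_metrics=r.cv_metrics,
                val_metrics=r.val_metrics,
                test_metrics=r.test_metrics,
                test_confusion=r.test_confusion,
                test_roc_auc=r.test_roc_auc,
                rank=rank,
            )
        )
    return ranked


def report_table(reports: list[ClassifierReport]) -> pd.DataFrame:
    """Benchmark summary, one row per model: CV mean ± SD per metric."""
    rows = []
    for r in reports:
        row = {"model": r.model_name, "rank": r.rank}
        for metric in ("accuracy", "precision", "recall", "f1", "roc_auc"):
            row[f"{metric}_mean"] = round(r.cv_mean(metric), 4)
            row[f"{metric}_sd"] = round(r.cv_sd(metric), 4)
            row[metric] = f"{r.cv_mean(metric):.2f} ± {r.cv_sd(metric):.2f}"
        rows.append(row)
    return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)


def roc_points(model, X: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """(fpr, tpr, threshold) triples on a monotone fpr grid."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("partition must contain both classes")
    fpr, tpr, thr = roc_curve(y, _scores(model, X))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def pr_points(model, X: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """(recall, precision, threshold) triples for the positive class."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("partition must contain both classes")
    precision, recall, thr = precision_recall_curve(y, _scores(model, X))
    thr = np.append(thr, np.inf)
    return list(zip(recall.tolist(), precision.tolist(), thr.tolist()))


def feature_importance(model, feature_names=FEATURE_COLUMNS) -> list[tuple[str, float]]:
    """Split-gain importances normalized to sum 1, descending."""
    if not hasattr(model, "feature_importances_"):
        raise UnsupportedModelError(
            f"{type(model).__name__} does not expose feature importances"
        )
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        raise ValueError("model reports all-zero importances")
    imp = imp / total
    order = np.argsort(-imp, kind="stable")
    return [(feature_names[i], float(imp[i])) for i in order]


def model_manifest(models: dict) -> dict:
    """Hyperparameters actually used, serialized for the run manifest."""
    out = {}
    for name, model in models.items():
        params = {}
        for key, val in model.get_params().items():
            if isinstance(val, (str, int, float, bool)) or val is None:
                params[key] = val
            else:
                params[key] = repr(val)
        out[name] = {"class": type(model).__name__, "params": params}
    return out
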