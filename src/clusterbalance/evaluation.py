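"""Metrics and the cross-validated experiment runner.

Confusion counts and the accuracy / precision / recall / F1 formulas are
implemented directly (positive class = 1; a 0/0 ratio is reported as 0), with
per-class weighted averaging as the default reporting mode — the convention
under which precision/recall/F1 can exceed accuracy on skewed test sets.
ROC/PR threshold sweeps are delegated to scikit-learn, with AUC by the
trapezoid rule.

Classifiers are not re-implemented: :class:`ClassifierSpec` binds the nine
reference configurations (AdaBoost, DT, ETC, KNN, LR, MLP, RF, SVM, XGB) to
scikit-learn / xgboost estimators through a minimal adapter interface
(``fit``, ``predict``, ``score`` -> class-1 score).  :func:`run_experiment`
wires everything leakage-safe: split, standardize on train, balance the
training side only, cross-validate for stability, report on the untouched
test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

from . import resamplers
from .cluster import cluster_balance
from .resamplers import ResampleConfig
from .tabular import LabeledTable, split, standardize


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Confusion matrix and summary metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise EvaluationError("y_true and y_pred length mismatch")
    for arr in (y_true, y_pred):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise EvaluationError("labels must be 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: ConfusionMatrix
    auc: float | None = None
    roc: list[tuple[float, float]] = field(default_factory=list, repr=False)
    pr: list[tuple[float, float]] = field(default_factory=list, repr=False)
    cv_accuracy_mean: float | None = None
    cv_accuracy_std: float | None = None


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def summary_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, average: str = "weighted"
) -> MetricsReport:
    """Accuracy and (binary or support-weighted) precision/recall/F1."""
    cm = confusion(y_true, y_pred)
    acc = (cm.tp + cm.tn) / cm.n if cm.n else 0.0
    if average == "binary":
        p, r, f = _prf(cm.tp, cm.fp, cm.fn)
    elif average == "weighted":
        # class 1 as positive, then class 0 as positive; weight by support
        p1, r1, f1_ = _prf(cm.tp, cm.fp, cm.fn)
        p0, r0, f0 = _prf(cm.tn, cm.fn, cm.fp)
        n1 = cm.tp + cm.fn
        n0 = cm.tn + cm.fp
        w1, w0 = n1 / cm.n, n0 / cm.n
        p = w1 * p1 + w0 * p0
        r = w1 * r1 + w0 * r0
        f = w1 * f1_ + w0 * f0
    else:
        raise EvaluationError("average must be 'binary' or 'weighted'")
    return MetricsReport(acc, p, r, f, cm)


def roc_and_auc(
    y_true: np.ndarray, scores: np.ndarray
) -> tuple[list[tuple[float, float]], float]:
    """ROC points from a threshold sweep (equal scores grouped) and
    trapezoid AUC."""
    y_true = np.asarray(y_true, int)
    if len(set(y_true.tolist())) < 2:
        raise EvaluationError("ROC needs both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def pr_curve(y_true: np.ndarray, scores: np.ndarray) -> list[tuple[float, float]]:
    """(recall, precision) points from a threshold sweep."""
    y_true = np.asarray(y_true, int)
    if len(set(y_true.tolist())) < 2:
        raise EvaluationError("PR curve needs both classes present")
    precision, recall, _ = skmetrics.precision_recall_curve(y_true, scores)
    return list(zip(recall.tolist(), precision.tolist()))


# ---------------------------------------------------------------------------
# Classifier adapters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)


def default_specs() -> dict[str, ClassifierSpec]:
    """The nine reference configurations shipped as fixed defaults."""
    grid = {
        "AdaBoost": {"n_estimators": 50, "learning_rate": 0.01, "random_state": 42},
        "DT": {"criterion": "gini", "splitter": "best", "random_state": 42},
        "ETC": {"n_estimators": 100, "random_state": 42},
        "KNN": {"n_neighbors": 5, "leaf_size": 30, "p": 2, "metric": "minkowski"},
        "LR": {
            "penalty": "l2",
            "C": 1.0,
            "solver": "liblinear",
            "max_iter": 100,
            "random_state": 42,
        },
        "MLP": {
            "hidden_layer_sizes": (100,),
            "activation": "relu",
            "solver": "adam",
            "alpha": 0.0001,
            "batch_size": "auto",
            "random_state": 42,
        },
        "RF": {"n_estimators": 100, "random_state": 42},
        "SVM": {
            "C": 1.0,
            "gamma": "scale",
            "kernel": "rbf",
            "probability": True,
            "random_state": 42,
        },
        "XGB": {
            "eval_metric": "mlogloss",
            "learning_rate": 0.1,
            "n_estimators": 100,
            "random_state": 42,
        },
    }
    return {name: ClassifierSpec(name, params) for name, params in grid.items()}


class SklearnAdapter:
    """fit/predict/score wrapper around an estimator with predict_proba or
    decision_function."""

    def __init__(self, estimator):
        self.estimator = estimator
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnAdapter":
        self.estimator.fit(X, y)
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise EvaluationError("adapter not fitted")
        return np.asarray(self.estimator.predict(X), int)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Class-1 score (probability where available)."""
        if not self._fitted:
            raise EvaluationError("adapter not fitted")
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)[:, 1]
        return self.estimator.decision_function(X)

    def clone(self) -> "SklearnAdapter":
        from sklearn.base import clone

        return SklearnAdapter(clone(self.estimator))


def build_adapter(spec: ClassifierSpec) -> SklearnAdapter:
    params = dict(spec.hyperparameters)
    name = spec.name
    if name == "AdaBoost":
        from sklearn.ensemble import AdaBoostClassifier

        est = AdaBoostClassifier(**params)
    elif name == "DT":
        from sklearn.tree import DecisionTreeClassifier

        est = DecisionTreeClassifier(**params)
    elif name == "ETC":
        from sklearn.ensemble import ExtraTreesClassifier

        est = ExtraTreesClassifier(**params)
    elif name == "KNN":
        from sklearn.neighbors import KNeighborsClassifier

        est = KNeighborsClassifier(**params)
    elif name == "LR":
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(**params)
    elif name == "MLP":
        from sklearn.neural_network import MLPClassifier

        est = MLPClassifier(**params)
    elif name == "RF":
        from sklearn.ensemble import RandomForestClassifier

        est = RandomForestClassifier(**params)
    elif name == "SVM":
        from sklearn.svm import SVC

        est = SVC(**params)
    elif name == "XGB":
        from xgboost import XGBClassifier

        est = XGBClassifier(**params)
    else:
        raise EvaluationError(f"no adapter registered for classifier spec {name!r}")
    return SklearnAdapter(est)


# ---------------------------------------------------------------------------
# Balancer registry
# ---------------------------------------------------------------------------

def _balance(name: str, train: LabeledTable, cfg: ResampleConfig) -> LabeledTable:
    if name == "none":
        return train
    if name == "smote":
        return resamplers.smote(train, cfg)
    if name == "nearmiss":
        return resamplers.nearmiss(train, cfg)
    if name == "smote-enn":
        return resamplers.smote_enn(train, cfg)
    if name == "smote-knn":
        return resamplers.smote_knn(train, cfg)
    if name == "kmeans-smote-enn":
        return cluster_balance(train, editor="enn", cfg=cfg)[0]
    if name == "kmeans-smote-knn":
        return cluster_balance(train, editor="knn", cfg=cfg)[0]
    raise EvaluationError(f"unknown balancer {name!r}")


BALANCERS = (
    "none",
    "smote",
    "nearmiss",
    "smote-enn",
    "smote-knn",
    "kmeans-smote-enn",
    "kmeans-smote-knn",
)


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

def run_experiment(
    data: LabeledTable,
    balancer: str = "kmeans-smote-enn",
    classifiers: Sequence[ClassifierSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
    ratio: float = 0.8,
    average: str = "weighted",
) -> tuple[pd.DataFrame, dict[str, MetricsReport]]:
    """Split, balance the training side only, cross-validate, report on test.

    Cross-validation (on the balanced training table) provides stability
    statistics only; the headline metrics come from the untouched held-out
    split.  Returns a per-classifier table plus full reports with curves.
    """
    if classifiers is None:
        classifiers = list(default_specs().values())
    pair = split(data, ratio=ratio, seed=seed)
    (train_s, test_s), _ = standardize(pair.train, pair.test)
    cfg = ResampleConfig(seed=seed)
    balanced = _balance(balancer, train_s, cfg)

    rows = []
    reports: dict[str, MetricsReport] = {}
    for spec in classifiers:
        adapter = build_adapter(spec)

        cv_scores = []
        if folds and folds > 1:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            for tr, va in skf.split(balanced.X, balanced.y):
                fold_adapter = adapter.clone()
                fold_adapter.fit(balanced.X[tr], balanced.y[tr])
                pred = fold_adapter.predict(balanced.X[va])
                cv_scores.append(float(np.mean(pred == balanced.y[va])))

        adapter.fit(balanced.X, balanced.y)
        y_pred = adapter.predict(test_s.X)
        report = summary_metrics(test_s.y, y_pred, average=average)
        scores = adapter.score(test_s.X)
        report.roc, report.auc = roc_and_auc(test_s.y, scores)
        report.pr = pr_curve(test_s.y, scores)
        if cv_scores:
            report.cv_accuracy_mean = float(np.mean(cv_scores))
            report.cv_accuracy_std = float(np.std(cv_scores))
        reports[spec.name] = report

        cm = report.confusion
        rows.append(
            {
                "model": spec.name,
                "accuracy": report.accuracy,
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
                "auc": report.auc,
                "recall_minority": cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0,
                "cv_accuracy_mean": report.cv_accuracy_mean,
                "cv_accuracy_std": report.cv_accuracy_std,
            }
        )
    return pd.DataFrame(rows).set_index("model"), reports
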