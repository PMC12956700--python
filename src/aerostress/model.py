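"""Base learners, stacked ensemble and 5-fold cross-validated evaluation.

Base learners are a Gini decision tree (depth 3), a Shannon-entropy random
forest (depth 8, 40 trees) and a gradient-boosted tree ensemble (XGBoost:
learning rate 0.12, depth 7, min child weight 3, L1 term 0.1).  The stack
trains a logistic-regression meta-learner on out-of-fold base class
probabilities (internal stratified 5-fold), then refits the bases on the
full training partition.  Evaluation pools per-fold confusion matrices
from a stratified k-fold and reports accuracy, precision, recall and F1
as percentages with "high stress" as the positive class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import FunctionTransformer
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

logger = logging.getLogger("aerostress")

POSITIVE_LABEL = "high"

#: Grid-search-selected hyperparameters for each base learner.
BASE_SPECS: dict[str, dict] = {
    "decision_tree": {"criterion": "gini", "max_depth": 3},
    "random_forest": {"criterion": "entropy", "max_depth": 8, "n_estimators": 40},
    "xgboost": {
        "learning_rate": 0.12,
        "max_depth": 7,
        "min_child_weight": 3,
        "reg_alpha": 0.1,
        "n_estimators": 100,
    },
}
MODEL_STRUCTURES = ["decision_tree", "random_forest", "xgboost", "stacking"]


def gini_impurity(proportions) -> float:
    """Gini impurity 1 − Σ p_i² of a class-proportion vector.

    Reference utility for cross-checking the tree library's splitting
    criterion; not used in training itself.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    return float(1.0 - np.sum(p**2))


@dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    yt = np.asarray(y_true) == POSITIVE_LABEL
    yp = np.asarray(y_pred) == POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int(np.sum(yt & yp)),
        tn=int(np.sum(~yt & ~yp)),
        fp=int(np.sum(~yt & yp)),
        fn=int(np.sum(yt & ~yp)),
    )


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, recall and F1 (percent) from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    precision = recall = f1 = math.nan
    if cm.tp + cm.fp > 0:
        precision = 100.0 * cm.tp / (cm.tp + cm.fp)
    else:
        logger.warning("no positive predictions: precision undefined")
    if cm.tp + cm.fn > 0:
        recall = 100.0 * cm.tp / (cm.tp + cm.fn)
    else:
        logger.warning("no positive samples: recall undefined")
    if not math.isnan(precision) and not math.isnan(recall) and precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


@dataclass
class CVReport:
    model_structure: str
    fold_matrices: list
    pooled: ConfusionMatrix
    metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_structure": self.model_structure,
            "folds": [m.to_dict() for m in self.fold_matrices],
            "pooled": self.pooled.to_dict(),
            "metrics": self.metrics,
        }


def make_base(kind: str, seed: int = 0, **overrides):
    """Instantiate a configured, seeded base learner."""
    if kind not in BASE_SPECS:
        raise ValueError(f"unknown base learner {kind!r}")
    params = BASE_SPECS[kind] | overrides
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    return XGBClassifier(
        random_state=seed, n_jobs=1, eval_metric="logloss",
        tree_method="exact", **params,
    )


def _log_odds(p: np.ndarray) -> np.ndarray:
    """Clipped logit of base-learner probabilities.

    Logistic regression combines classifiers most naturally on the
    log-odds scale (the model is then linear in each base's evidence);
    clipping keeps saturated tree probabilities finite.
    """
    q = np.clip(p, 1e-6, 1.0 - 1e-6)
    return np.log(q / (1.0 - q))


class IdentityMeta(ClassifierMixin, BaseEstimator):
    """Degenerate meta-learner: threshold the mean base probability at 0.5.

    With a single base learner the stack's predictions then equal that
    learner's own predictions exactly.
    """

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return self.classes_[(np.mean(X, axis=1) > 0.5).astype(int)]


def make_stacking(
    seed: int = 0,
    internal_folds: int = 5,
    base_kinds=None,
    meta: str = "logistic",
):
    """Stacked ensemble: out-of-fold base class probabilities feed the
    meta-learner (logistic regression on their log-odds by default);
    bases are refit on the full training data."""
    kinds = base_kinds or ["decision_tree", "random_forest", "xgboost"]
    if len(kinds) < 1:
        raise ValueError("stacking needs at least 1 base learner")
    if meta == "logistic":
        final = make_pipeline(
            FunctionTransformer(_log_odds),
            LogisticRegression(max_iter=1000, random_state=seed),
        )
    elif meta == "identity":
        final = IdentityMeta()
    else:
        raise ValueError(f"unknown meta-learner {meta!r}")
    estimators = [(k, make_base(k, seed=seed)) for k in kinds]
    return StackingClassifier(
        estimators=estimators,
        final_estimator=final,
        cv=StratifiedKFold(internal_folds, shuffle=True, random_state=seed),
        stack_method="predict_proba",
        n_jobs=1,
    )


def make_model(structure: str, seed: int = 0, **overrides):
    if structure == "stacking":
        return make_stacking(seed=seed, **overrides)
    return make_base(structure, seed=seed, **overrides)


def _xy(features: pd.DataFrame, selected: list[str]):
    X = features[selected].to_numpy(dtype=float)
    y = features["label"].to_numpy()
    if np.isnan(X).any():
        keep = ~np.isnan(X).any(axis=1)
        logger.info("dropping %d row(s) with missing features", int((~keep).sum()))
        X, y = X[keep], y[keep]
    return X, y


def train_base(kind: str, features: pd.DataFrame, selected: list[str], seed: int = 0):
    """Fit one base learner on the selected indicator columns."""
    X, y = _xy(features, selected)
    if len(set(y)) < 2:
        raise ValueError("training data contains a single class")
    model = make_base(kind, seed=seed)
    return model.fit(X, (y == POSITIVE_LABEL).astype(int))


def cross_validate(
    builder: Callable[[int], object],
    features: pd.DataFrame,
    selected: list[str],
    structure_name: str,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold evaluation with pooled confusion matrices."""
    X, y = _xy(features, selected)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation requires both classes")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class size {counts.min()}")
    y01 = (y == POSITIVE_LABEL).astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_matrices = []
    for train_idx, test_idx in skf.split(X, y01):
        model = builder(seed)
        model.fit(X[train_idx], y01[train_idx])
        pred = model.predict(X[test_idx])
        fold_matrices.append(
            confusion_from_predictions(
                np.where(y01[test_idx] == 1, POSITIVE_LABEL, "low"),
                np.where(pred == 1, POSITIVE_LABEL, "low"),
            )
        )
    pooled = sum(fold_matrices[1:], fold_matrices[0])
    return CVReport(
        model_structure=structure_name,
        fold_matrices=fold_matrices,
        pooled=pooled,
        metrics=compute_metrics(pooled),
    )


def evaluate_structures(
    features: pd.DataFrame,
    selected: list[str],
    structures=None,
    k: int = 5,
    seed: int = 0,
) -> dict[str, CVReport]:
    """Cross-validate every model structure on the same folds."""
    reports = {}
    for name in structures or MODEL_STRUCTURES:
        reports[name] = cross_validate(
            lambda s, n=name: make_model(n, seed=s),
            features, selected, structure_name=name, k=k, seed=seed,
        )
    return reports


def grid_search(
    kind: str,
    grid: list[dict],
    features: pd.DataFrame,
    selected: list[str],
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Exhaustive CV-accuracy grid search over hyperparameter dicts.

    Ties prefer the simpler model: fewer estimators first, then shallower
    trees.
    """
    if not grid:
        raise ValueError("empty grid")
    results = []
    for params in grid:
        report = cross_validate(
            lambda s, p=params: make_base(kind, seed=s, **p),
            features, selected, structure_name=kind, k=folds, seed=seed,
        )
        results.append((params, report.metrics["accuracy"]))
    best_acc = max(acc for _, acc in results)
    tied = [p for p, acc in results if acc == best_acc]
    tied.sort(
        key=lambda p: (
            p.get("n_estimators", BASE_SPECS[kind].get("n_estimators", 1)),
            p.get("max_depth", BASE_SPECS[kind].get("max_depth", math.inf)),
        )
    )
    return tied[0]


def reports_table(reports: dict[str, CVReport]) -> pd.DataFrame:
    """Model-by-metric summary (percent), one row per model structure."""
    rows = [
        {"model": name} | rep.metrics for name, rep in reports.items()
    ]
    return pd.DataFrame(rows)
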