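"""Bagged-decision-tree event classification.

The event classifier is a bootstrap-aggregated ensemble of axis-aligned
decision trees over the five-feature vector (blockage ratio, std, kurt,
skew, dwell). Trees need no feature scaling (splits are scale-invariant) and
absorb the multimodal feature distributions of saccharide classes, whose
multiple sub-states all carry the single analyte label. Validation follows
the original protocol: stratified 10-fold cross-validation, held-out test
confusion matrices with per-class TPR/FNR, and learning curves over
training-set size. ``compare_models`` benchmarks the ensemble against the
other standard classifier families on identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS, FeatureMatrix

__all__ = [
    "ClassifierModel",
    "EvaluationReport",
    "train_bagged_trees",
    "predict",
    "cross_validate",
    "confusion",
    "learning_curve",
    "compare_models",
    "MODEL_FAMILIES",
]


@dataclass
class ClassifierModel:
    """Trained ensemble with its class roster and training metadata."""

    estimator: BaggingClassifier
    classes: list[str]
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)


@dataclass
class EvaluationReport:
    """Accuracy, per-class TPR/FNR and confusion counts."""

    accuracy: float
    confusion_counts: pd.DataFrame   # rows = true class, cols = predicted
    tpr: pd.Series
    fnr: pd.Series


def _check_labeled(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    if matrix.labels is None:
        raise ValueError("labeled feature matrix required")
    X = matrix.values
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X, np.asarray(matrix.labels, dtype=object)


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sort rows by (label, features) so that bootstrap draws and fold
    assignment depend only on the data, not on row order."""
    keys = [X[:, i] for i in reversed(range(X.shape[1]))] + [y.astype(str)]
    return np.lexsort(keys)


def train_bagged_trees(
    train: FeatureMatrix, n_trees: int = 30, seed: int = 0
) -> ClassifierModel:
    """Fit the bagged-tree ensemble (default 30 bootstrap trees).

    Majority vote with ties broken toward the lexicographically first class;
    deterministic under ``seed``. Requires >= 2 classes with n >= 10 each.
    """
    X, y = _check_labeled(train)
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if counts.min() < 10:
        small = classes[counts < 10]
        raise ValueError(f"classes with fewer than 10 training events: {list(small)}")
    est = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=0),
        n_estimators=n_trees,
        random_state=seed,
    )
    est.fit(X, y)
    return ClassifierModel(
        estimator=est,
        classes=[str(c) for c in est.classes_],
        feature_names=list(FEATURE_COLUMNS),
        metadata={"seed": seed, "n_trees": n_trees, "n_per_class": dict(zip(classes, counts.tolist()))},
    )


def predict(model: ClassifierModel, matrix: FeatureMatrix) -> np.ndarray:
    """One roster label per row; empty input gives an empty label array."""
    if list(matrix.data.columns[: len(FEATURE_COLUMNS)]) != model.feature_names and list(
        FEATURE_COLUMNS
    ) != model.feature_names:
        raise ValueError("feature order does not match the trained model")
    if len(matrix) == 0:
        return np.array([], dtype=object)
    X = matrix.values
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return model.estimator.predict(X).astype(object)


def confusion(true_labels, pred_labels) -> EvaluationReport:
    """Confusion counts plus per-class TPR/FNR; rows sum to class sizes."""
    true_labels = np.asarray(true_labels, dtype=object)
    pred_labels = np.asarray(pred_labels, dtype=object)
    if true_labels.size != pred_labels.size:
        raise ValueError("label vectors differ in length")
    classes = sorted(set(true_labels) | set(pred_labels))
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true_labels, pred_labels):
        counts.loc[t, p] += 1
    row_sums = counts.sum(axis=1)
    diag = pd.Series(np.diag(counts.to_numpy()), index=classes, dtype=float)
    tpr = (diag / row_sums.replace(0, np.nan)).astype(float)
    accuracy = float(diag.sum() / true_labels.size) if true_labels.size else float("nan")
    return EvaluationReport(accuracy=accuracy, confusion_counts=counts, tpr=tpr, fnr=1.0 - tpr)


def cross_validate(matrix: FeatureMatrix, k: int = 10, seed: int = 0, n_trees: int = 30) -> EvaluationReport:
    """Stratified k-fold cross-validation; accuracy pooled over folds."""
    X, y = _check_labeled(matrix)
    order = _canonical_order(X, y)
    Xs, ys = X[order], y[order]
    _, counts = np.unique(ys, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) is below k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred_sorted = np.empty_like(ys)
    for tr, te in skf.split(Xs, ys):
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=0),
            n_estimators=n_trees,
            random_state=seed,
        )
        est.fit(Xs[tr], ys[tr])
        pred_sorted[te] = est.predict(Xs[te])
    pred = np.empty_like(y)
    pred[order] = pred_sorted
    return confusion(y, pred)


def learning_curve(
    matrix: FeatureMatrix,
    sizes: list[int],
    reps: int = 3,
    seed: int = 0,
    n_trees: int = 30,
) -> pd.DataFrame:
    """Validation/training accuracy versus training-set size.

    For each size, a stratified subsample is trained and validated on the
    held-out remainder; accuracies are averaged over ``reps`` repeats.
    Returns columns size, val_accuracy, train_accuracy.
    """
    X, y = _check_labeled(matrix)
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    n = len(y)
    n_classes = len(set(y))
    rows = []
    for size in sizes:
        if size > n:
            raise ValueError(f"size {size} exceeds available events ({n})")
        if size < 2 * n_classes:
            raise ValueError(f"size {size} too small for {n_classes} classes")
        val_acc, train_acc = [], []
        for rep in range(reps):
            rs = (seed * 1000 + size * 7 + rep) % (2**31 - 1)
            if size == n:
                Xtr, ytr, Xte, yte = X, y, X, y
            else:
                Xtr, Xte, ytr, yte = train_test_split(
                    X, y, train_size=size, stratify=y, random_state=rs
                )
            est = BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=0),
                n_estimators=n_trees,
                random_state=rs,
            )
            est.fit(Xtr, ytr)
            val_acc.append(float((est.predict(Xte) == yte).mean()))
            train_acc.append(float((est.predict(Xtr) == ytr).mean()))
        rows.append(
            {"size": size, "val_accuracy": np.mean(val_acc), "train_accuracy": np.mean(train_acc)}
        )
    return pd.DataFrame(rows)


def _family_estimator(name: str, seed: int):
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "discriminant":
        return LinearDiscriminantAnalysis()
    if name == "naive_bayes":
        return GaussianNB()
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(random_state=seed))
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    if name == "bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=0),
            n_estimators=30,
            random_state=seed,
        )
    if name == "neural_net":
        return make_pipeline(
            StandardScaler(), MLPClassifier(max_iter=800, random_state=seed)
        )
    raise ValueError(f"unknown model family {name!r}")


MODEL_FAMILIES = [
    "decision_tree",
    "discriminant",
    "naive_bayes",
    "svm",
    "knn",
    "bagged_trees",
    "neural_net",
]


def compare_models(
    matrix: FeatureMatrix,
    families: list[str] | None = None,
    seed: int = 0,
    k: int = 10,
    test: FeatureMatrix | None = None,
) -> pd.DataFrame:
    """Cross-validated accuracy of several classifier families on the same
    folds; optional held-out test accuracy."""
    families = list(families) if families is not None else list(MODEL_FAMILIES)
    X, y = _check_labeled(matrix)
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rows = []
    for fam in families:
        pred = np.empty_like(y)
        for tr, te in folds:
            est = _family_estimator(fam, seed)
            est.fit(X[tr], y[tr])
            pred[te] = est.predict(X[te])
        row = {"family": fam, "val_accuracy": float((pred == y).mean())}
        if test is not None:
            Xt, yt = _check_labeled(test)
            est = _family_estimator(fam, seed)
            est.fit(X, y)
            row["test_accuracy"] = float((est.predict(Xt) == yt).mean())
        rows.append(row)
    return pd.DataFrame(rows)
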