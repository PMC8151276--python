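"""Multiclass random-forest family classifier with repeated CV and controls.

Training tunes the features-per-split hyperparameter over a small grid
centered on sqrt(p) by mean accuracy under repeated stratified k-fold
cross-validation, then refits on the full training set. Evaluation reports
a K x K confusion matrix plus one-vs-rest accuracy, sensitivity and
specificity per family:

    accuracy    = (TP + TN) / (TP + FN + TN + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    cross_val_score,
    train_test_split,
)

from gpcrtracer.errors import ConfigurationError, SchemaError
from gpcrtracer.fingerprints import FeatureMask

DEFAULT_N_ESTIMATORS = 500


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    repeats: int = 10

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")


@dataclass
class FamilyClassifier:
    """Fitted ensemble plus the metadata needed to reuse it downstream."""

    model: RandomForestClassifier
    class_labels: tuple[str, ...]
    cv_config: CVConfig
    tuning: dict[int, float]
    seed: int
    feature_mask: FeatureMask | None = None

    def predict_proba(self, matrix) -> np.ndarray:
        proba = self.model.predict_proba(np.asarray(matrix))
        # guard the contract downstream modules rely on
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        return proba


def _mtry_grid(n_features: int) -> list[int]:
    center = max(1, int(round(np.sqrt(n_features))))
    grid = {max(1, center // 2), center, min(n_features, 2 * center)}
    return sorted(grid)


def train(
    matrix,
    labels,
    cv_config: CVConfig = CVConfig(),
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    feature_mask: FeatureMask | None = None,
) -> FamilyClassifier:
    """Tune features-per-split by repeated-CV accuracy and refit on all rows."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ConfigurationError("training requires at least 2 classes")
    if counts.min() < cv_config.folds:
        small = classes[counts.argmin()]
        raise ConfigurationError(
            f"class {small!r} has {counts.min()} members, fewer than "
            f"{cv_config.folds} folds"
        )

    cv = RepeatedStratifiedKFold(
        n_splits=cv_config.folds, n_repeats=cv_config.repeats, random_state=seed
    )
    tuning: dict[int, float] = {}
    for mtry in _mtry_grid(X.shape[1]):
        est = RandomForestClassifier(
            n_estimators=n_estimators, max_features=mtry, random_state=seed
        )
        scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
        tuning[mtry] = float(scores.mean())

    best = max(tuning, key=lambda m: (tuning[m], -m))
    final = RandomForestClassifier(
        n_estimators=n_estimators, max_features=best, random_state=seed
    ).fit(X, y)
    return FamilyClassifier(
        model=final,
        class_labels=tuple(str(c) for c in final.classes_),
        cv_config=cv_config,
        tuning=tuning,
        seed=seed,
        feature_mask=feature_mask,
    )


def predict_top_family(clf: FamilyClassifier, matrix) -> np.ndarray:
    """Argmax family per row; ties break to the first label in class order."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != clf.model.n_features_in_:
        raise SchemaError(
            f"matrix has {X.shape[1]} columns, model expects "
            f"{clf.model.n_features_in_}"
        )
    proba = clf.predict_proba(X)
    return np.asarray(clf.class_labels)[np.argmax(proba, axis=1)]


def binary_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy/sensitivity/specificity (percent) from one-vs-rest counts."""
    total = tp + fn + tn + fp
    acc = 100.0 * (tp + tn) / total if total else float("nan")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


@dataclass
class ConfusionCounts:
    """K x K confusion matrix with one-vs-rest per-family tallies."""

    matrix: pd.DataFrame  # rows = true family, cols = predicted family
    per_family: pd.DataFrame  # tp, fp, tn, fn, accuracy, sensitivity, specificity
    overall_accuracy: float  # percent, trace / total

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())


def confusion_from_predictions(
    true_labels, predicted_labels, class_labels
) -> ConfusionCounts:
    """Tally a confusion matrix and per-family one-vs-rest metrics."""
    labels = [str(c) for c in class_labels]
    y_true = np.asarray([str(v) for v in true_labels])
    y_pred = np.asarray([str(v) for v in predicted_labels])
    unknown = set(y_true) - set(labels)
    if unknown:
        raise SchemaError(f"labels outside the class list: {sorted(unknown)}")

    index = {c: i for i, c in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1

    rows = []
    total = mat.sum()
    for i, fam in enumerate(labels):
        tp = int(mat[i, i])
        fn = int(mat[i, :].sum() - tp)
        fp = int(mat[:, i].sum() - tp)
        tn = int(total - tp - fn - fp)
        rows.append({"family": fam, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                     **binary_metrics(tp, fp, tn, fn)})
    per_family = pd.DataFrame(rows).set_index("family")
    overall = 100.0 * np.trace(mat) / total if total else float("nan")
    matrix = pd.DataFrame(mat, index=labels, columns=labels)
    return ConfusionCounts(matrix=matrix, per_family=per_family, overall_accuracy=overall)


def evaluate(clf: FamilyClassifier, test_matrix, test_labels) -> ConfusionCounts:
    """Confusion matrix and per-family metrics on held-out data."""
    predicted = predict_top_family(clf, test_matrix)
    return confusion_from_predictions(test_labels, predicted, clf.class_labels)


def randomized_label_control(
    matrix,
    labels,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    test_fraction: float = 0.30,
) -> float:
    """Held-out top-1 accuracy (fraction) after a uniform label permutation.

    Expected to land near 1/K for K classes; serves as the negative control
    for the trained model's accuracy.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray([str(v) for v in labels])
    rng = np.random.default_rng(seed)
    permuted = y[rng.permutation(len(y))]
    X_train, X_test, y_train, y_test = train_test_split(
        X, permuted, test_size=test_fraction, stratify=permuted,
        random_state=seed,
    )
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed
    ).fit(X_train, y_train)
    return float((model.predict(X_test) == y_test).mean())
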