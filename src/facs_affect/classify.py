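"""Leave-one-out linear-SVM discrimination of intervention vs control clips.

Each clip is represented by the per-code frequency and/or maximum duration
of a chosen code set (feature blocks ordered frequency first, codes sorted
within a block; absent codes contribute zeros). Following the original
protocol, features are built on the raw event stream *without* ear-flicker
merging.

Evaluation is leave-one-out: for every held-out clip, features are
standardized on the remaining clips only, the regularization parameter C is
chosen from a decade grid by stratified 5-fold cross-validation on those
clips (accuracy criterion, ties resolved toward the smaller C, i.e. the
stronger regularization), and a linear SVM with class weights inversely
proportional to class frequencies predicts the held-out clip. Collated
predictions yield precision and recall with intervention as the positive
class, and overall accuracy. Standardization and tuning live entirely
inside each fold, so no information from the held-out clip leaks into
training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .events_io import ClipRecord, INTERVENTIONS

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class FeatureMatrix:
    """Per-clip feature matrix with intervention/control labels."""

    X: np.ndarray
    y: np.ndarray  # 1 = intervention, 0 = control
    feature_names: list[str]
    clip_ids: list[str]


@dataclass
class ClassReport:
    """Collated leave-one-out results (percent scales)."""

    precision: float
    recall: float
    accuracy: float
    predictions: np.ndarray
    clip_ids: list[str]
    c_values: list[float] = field(default_factory=list)
    seed: int = 0


def build_features(
    summary: pd.DataFrame,
    clips: Sequence[ClipRecord],
    codes: Sequence[str] | None = None,
    mode: str = "both",
    intervention: Sequence[str] = INTERVENTIONS,
    control: Sequence[str] = ("baseline",),
) -> FeatureMatrix:
    """Assemble the clip-by-feature matrix from a per-clip summary.

    ``codes=None`` uses every code present in the summary. ``mode`` is
    ``frequency``, ``max_duration`` or ``both`` (frequency block first).
    """
    if mode not in ("frequency", "max_duration", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    if codes is None:
        codes = sorted(summary["code"].unique())
    else:
        codes = sorted(codes)
    if not codes:
        raise ValueError("empty code set")
    pool = {"intervention": set(intervention), "control": set(control)}
    labeled = [
        (c, 1 if c.condition in pool["intervention"] else 0)
        for c in clips
        if c.condition in pool["intervention"] | pool["control"]
    ]
    clip_ids = [c.video_id for c, _ in labeled]
    y = np.array([lab for _, lab in labeled], dtype=int)

    measures = ["frequency", "max_duration"] if mode == "both" else [mode]
    blocks, names = [], []
    for measure in measures:
        pivot = (
            summary.pivot(index="video_id", columns="code", values=measure)
            .reindex(index=clip_ids, columns=codes)
            .fillna(0.0)
        )
        blocks.append(pivot.to_numpy(dtype=float))
        suffix = "freq" if measure == "frequency" else "maxdur"
        names.extend(f"{code}_{suffix}" for code in codes)
    return FeatureMatrix(np.hstack(blocks), y, names, clip_ids)


def fit_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float, class_weight="balanced"
) -> SVC:
    """Fit the soft-margin linear SVM used at every stage."""
    clf = SVC(kernel="linear", C=C, class_weight=class_weight)
    clf.fit(X, y)
    return clf


def select_c(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    folds: int = 5,
) -> float:
    """Pick C by stratified k-fold CV accuracy; ties go to the smaller C.

    The fold count shrinks to the minority class size when needed so every
    training fold contains both classes; should a split still lose a class,
    folds are re-drawn with an incremented seed.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    n_splits = min(folds, counts.min())
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=seed + attempt)
        splits = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
    best_c, best_acc = None, -1.0
    for c in sorted(c_grid):
        correct = total = 0
        for tr, te in splits:
            scaler = StandardScaler().fit(X[tr])
            clf = fit_linear_svm(scaler.transform(X[tr]), y[tr], c)
            pred = clf.predict(scaler.transform(X[te]))
            correct += int((pred == y[te]).sum())
            total += len(te)
        acc = correct / total
        if acc > best_acc:
            best_acc, best_c = acc, c
    return best_c


def loo_evaluate(
    features: FeatureMatrix,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    global_c: float | None = None,
    cv_folds: int = 5,
) -> ClassReport:
    """Leave-one-out evaluation with per-fold standardization and C tuning.

    ``global_c`` bypasses the nested CV and uses one fixed C in every fold
    (the alternative reading of a globally tuned regularizer).
    """
    X, y = features.X, features.y
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need >=2 clips per class")
    const = X.std(axis=0) == 0
    if const.any():
        dropped = [n for n, c in zip(features.feature_names, const) if c]
        warnings.warn(f"dropping constant feature(s): {', '.join(dropped)}")
        X = X[:, ~const]
    n = len(y)
    preds = np.empty(n, dtype=int)
    c_values: list[float] = []
    for i in range(n):
        tr = np.arange(n) != i
        X_tr, y_tr = X[tr], y[tr]
        c = global_c if global_c is not None else select_c(
            X_tr, y_tr, c_grid, seed=seed, folds=cv_folds
        )
        scaler = StandardScaler().fit(X_tr)
        clf = fit_linear_svm(scaler.transform(X_tr), y_tr, c)
        preds[i] = clf.predict(scaler.transform(X[i:i + 1]))[0]
        c_values.append(c)
    return ClassReport(
        precision=100.0 * precision_score(y, preds, pos_label=1, zero_division=0),
        recall=100.0 * recall_score(y, preds, pos_label=1, zero_division=0),
        accuracy=100.0 * accuracy_score(y, preds),
        predictions=preds,
        clip_ids=features.clip_ids,
        c_values=c_values,
        seed=seed,
    )
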