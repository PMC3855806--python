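"""Linear SVM training and repeated stratified cross-validation.

Performance is summarized by recall = TP/(TP+FN), precision = TP/(TP+FP)
and the area under the recall–precision curve. Cross-validation pools
confusion counts over folds within each repeat (micro-averaging) and
standardizes features with training-fold statistics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "CVMetrics",
    "LinearModel",
    "recall",
    "precision",
    "train",
    "cross_validate",
    "pr_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def recall(counts: ConfusionCounts) -> float:
    """TP/(TP+FN); 0 with a warning when no positives were evaluated."""
    denom = counts.tp + counts.fn
    if denom == 0:
        warnings.warn("recall undefined (tp+fn=0); returning 0", stacklevel=2)
        return 0.0
    return counts.tp / denom


def precision(counts: ConfusionCounts) -> float:
    """TP/(TP+FP); 0 with a warning when nothing was predicted positive."""
    denom = counts.tp + counts.fp
    if denom == 0:
        warnings.warn("precision undefined (tp+fp=0); returning 0", stacklevel=2)
        return 0.0
    return counts.tp / denom


@dataclass
class LinearModel:
    """Weights and bias of a trained linear decision function."""

    weights: np.ndarray
    bias: float
    feature_names: list[str] | None = None

    def decision_function(self, X) -> np.ndarray:
        X = _matrix(X)
        return X @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= 0, 1, -1)


@dataclass
class CVMetrics:
    """Repeated-CV performance distribution and grand means."""

    recall_per_repeat: np.ndarray
    precision_per_repeat: np.ndarray
    recall: float
    precision: float
    pr_curve: np.ndarray = field(default=None)  # (k, 2) recall, precision
    pr_auc: float = float("nan")
    oof_scores: np.ndarray = field(default=None)  # first repeat, sample order
    oof_predictions: np.ndarray = field(default=None)


def _matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _check_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    Xm = _matrix(X)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("exactly two classes required")
    if not np.isfinite(Xm).all():
        raise ValueError("features must be finite")
    return Xm, y


def train(X, y, C: float = 1.0) -> LinearModel:
    """Fit a soft-margin linear SVM; prediction is the sign of w·x + b."""
    Xm, y = _check_xy(X, y)
    model = SVC(kernel="linear", C=C)
    model.fit(Xm, y)
    names = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else None
    return LinearModel(
        weights=np.asarray(model.coef_).ravel().copy(),
        bias=float(model.intercept_[0]),
        feature_names=names,
    )


def standardize_train_test(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale both splits using training statistics only."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X_train - mu) / sd, (X_test - mu) / sd


def cross_validate(
    X, y, folds: int = 10, repeats: int = 100, seed: int = 0, C: float = 1.0
) -> CVMetrics:
    """Repeated stratified k-fold CV of the linear SVM.

    Folds are reshuffled every repeat from a seeded generator; each repeat's
    out-of-fold predictions are pooled into one confusion table, and the
    grand mean over repeats is reported. The recall–precision curve and its
    AUC come from the first repeat's pooled decision scores.
    """
    Xm, y = _check_xy(X, y)
    pos_label = np.max(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= folds={folds}"
        )
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repeats)]

    recalls = np.empty(repeats)
    precisions = np.empty(repeats)
    oof_scores = np.empty(len(y))
    oof_pred = np.empty(len(y), dtype=y.dtype)
    curve = None
    auc = float("nan")
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seeds[rep])
        tp = fp = fn = tn = 0
        for tr, te in skf.split(Xm, y):
            Ztr, Zte = standardize_train_test(Xm[tr], Xm[te])
            model = SVC(kernel="linear", C=C)
            model.fit(Ztr, y[tr])
            pred = model.predict(Zte)
            if rep == 0:
                oof_scores[te] = model.decision_function(Zte)
                oof_pred[te] = pred
            truth = y[te] == pos_label
            hit = pred == pos_label
            tp += int(np.sum(truth & hit))
            fp += int(np.sum(~truth & hit))
            fn += int(np.sum(truth & ~hit))
            tn += int(np.sum(~truth & ~hit))
        cc = ConfusionCounts(tp, fp, fn, tn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recalls[rep] = recall(cc)
            precisions[rep] = precision(cc)
        if rep == 0:
            curve = _pr_curve(oof_scores, y == pos_label)
            auc = _auc_from_curve(curve)

    return CVMetrics(
        recall_per_repeat=recalls,
        precision_per_repeat=precisions,
        recall=float(recalls.mean()),
        precision=float(precisions.mean()),
        pr_curve=curve,
        pr_auc=auc,
        oof_scores=oof_scores,
        oof_predictions=oof_pred,
    )


def _pr_curve(scores: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """(recall, precision) at every distinct score threshold, descending."""
    n_pos = int(truth.sum())
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = truth[order]
    tp_cum = np.cumsum(t_sorted)
    pred_cum = np.arange(1, len(scores) + 1)
    # keep only the last index of each tied score block
    last = np.flatnonzero(np.diff(s_sorted, append=-np.inf) != 0)
    rec = tp_cum[last] / n_pos if n_pos else np.zeros(len(last))
    prec = tp_cum[last] / pred_cum[last]
    return np.column_stack([rec, prec])


def _auc_from_curve(curve: np.ndarray) -> float:
    rec = curve[:, 0]
    prec = curve[:, 1]
    prev = np.concatenate([[0.0], rec[:-1]])
    return float(np.sum((rec - prev) * prec))


def pr_auc(decision_scores, labels) -> float:
    """Area under the recall–precision curve by right-continuous steps.

    Thresholds sweep all distinct scores descending; AUC =
    Σ (recall_k − recall_{k−1}) · precision_k.
    """
    scores = np.asarray(decision_scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("decision scores must be finite")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    truth = y == classes.max()
    return _auc_from_curve(_pr_curve(scores, truth))
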