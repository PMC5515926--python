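"""Performance evaluation: confusion-matrix metrics, ROC/AUC, k-fold CV.

Metrics follow the usual definitions on TP/TN/FP/FN counts: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy, F-score and MCC.  Two
F-score variants are computed: the standard F1 = 2TP/(2TP+FP+FN), which
is the headline metric, and a historical variant 2TP/(2TP+FP+TN) kept
for comparability with prior printed formulas.  A zero denominator
leaves the metric undefined (NaN) and flags it, rather than silently
reporting 0.  AUC uses the Mann-Whitney form: the probability that a
random positive outscores a random negative, ties counted one half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, labels: np.ndarray, predicted: np.ndarray
    ) -> "ConfusionCounts":
        """Counts from +1/-1 true labels and +1/-1 calls."""
        labels = np.asarray(labels).ravel()
        predicted = np.asarray(predicted).ravel()
        pos, pred_pos = labels > 0, predicted > 0
        return cls(
            tp=int(np.sum(pos & pred_pos)),
            tn=int(np.sum(~pos & ~pred_pos)),
            fp=int(np.sum(~pos & pred_pos)),
            fn=int(np.sum(pos & ~pred_pos)),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass
class MetricsReport:
    """Threshold metrics plus AUC; NaN metrics are listed in ``undefined``."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    f_score: float
    f_score_as_printed: float
    mcc: float
    auc: Optional[float] = None
    undefined: tuple[str, ...] = ()
    per_fold: list["MetricsReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f_score": self.f_score,
            "f_score_as_printed": self.f_score_as_printed,
            "mcc": self.mcc,
            "undefined": list(self.undefined),
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from confusion counts (AUC left unset)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    accuracy = _safe_div(tp + tn, counts.total)
    f_score = _safe_div(2 * tp, 2 * tp + fp + fn)
    f_printed = _safe_div(2 * tp, 2 * tp + fp + tn)
    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    values = {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": accuracy,
        "f_score": f_score,
        "f_score_as_printed": f_printed,
        "mcc": mcc,
    }
    undefined = tuple(k for k, v in values.items() if np.isnan(v))
    return MetricsReport(counts=counts, undefined=undefined, **values)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = labels > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Empirical ROC curve as (fpr, tpr, threshold) rows for plotting."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel() > 0
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos, n_neg = labels.sum(), (~labels).sum()
    tps = np.cumsum(labels)
    fps = np.cumsum(~labels)
    # one point per distinct threshold
    distinct = np.append(np.diff(scores) != 0, True)
    rows = {
        "fpr": np.concatenate([[0.0], fps[distinct] / n_neg]),
        "tpr": np.concatenate([[0.0], tps[distinct] / n_pos]),
        "threshold": np.concatenate([[np.inf], scores[distinct]]),
    }
    return pd.DataFrame(rows)


def stratified_folds(
    labels: np.ndarray, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split (train_idx, test_idx) pairs.

    Falls back to plain k-fold when a class has fewer members than folds
    (e.g. leave-one-out on tiny data), where stratification is impossible.
    """
    labels = np.asarray(labels).ravel()
    _, class_counts = np.unique(labels, return_counts=True)
    if class_counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [
            (tr, te) for tr, te in splitter.split(np.zeros(len(labels)), labels)
        ]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(labels)))]


def cross_validate(
    matrix,
    config=None,
    k: int = 5,
    seed: int = 0,
    cutoff: float | None = None,
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the SVR classifier.

    ``matrix`` is a labeled FeatureMatrix (or an (X, y) tuple).  Scores
    of all held-out folds are pooled for the AUC; threshold metrics are
    reported both pooled and per fold.  A custom ``fit_predict(train_X,
    train_y, test_X) -> scores`` callable replaces the default SVR.
    """
    from .encoders import FeatureMatrix  # local to avoid import cycle

    if isinstance(matrix, FeatureMatrix):
        data, labels = matrix.data, matrix.labels
    else:
        data, labels = matrix
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels).ravel()
    if fit_predict is None:
        from .models import SVRConfig, predict_scores, train_svr

        config = config or SVRConfig()
        if cutoff is None:
            cutoff = config.cutoff

        def fit_predict(train_X, train_y, test_X):
            model = train_svr(train_X, train_y, config)
            return predict_scores(model, test_X)

    if cutoff is None:
        cutoff = 0.0
    folds = stratified_folds(labels, k=k, seed=seed)
    pooled_scores = np.empty(len(labels))
    per_fold: list[MetricsReport] = []
    for train_idx, test_idx in folds:
        assert len(np.intersect1d(train_idx, test_idx)) == 0
        scores = fit_predict(data[train_idx], labels[train_idx], data[test_idx])
        pooled_scores[test_idx] = scores
        calls = np.where(np.asarray(scores) > cutoff, 1, -1)
        fold_counts = ConfusionCounts.from_predictions(labels[test_idx], calls)
        per_fold.append(compute_metrics(fold_counts))
    calls = np.where(pooled_scores > cutoff, 1, -1)
    report = compute_metrics(ConfusionCounts.from_predictions(labels, calls))
    report.auc = roc_auc(pooled_scores, labels)
    report.per_fold = per_fold
    return report
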