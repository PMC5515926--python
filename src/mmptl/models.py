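"""SVR-as-classifier: RBF-kernel support vector regression on +1/-1 labels.

The regression score doubles as a confidence value; a cutoff (default 0)
turns it into a cleavage / non-cleavage call.  Hyperparameters c (cost)
and gamma (RBF width) are tuned by grid search under stratified k-fold
cross-validation maximizing AUC.  Features are standardized inside each
training fold only, so held-out rows never leak into the scaler.
"""

from __future__ import annotations

import base64
import hashlib
import io
import json
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .encoders import FeatureMatrix
from .evaluation import roc_auc, stratified_folds

#: LibSVM-convention default grids: c = 2^-5 .. 2^15, gamma = 2^-15 .. 2^3,
#: both in steps of x4
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class SVRConfig:
    """Hyperparameters for the SVR classifier."""

    c: float = 1.0
    gamma: float = 0.125
    epsilon: float = 0.1
    cutoff: float = 0.0
    cv_folds: int = 5
    seed: int = 0
    c_grid: tuple[float, ...] = field(default_factory=lambda: DEFAULT_C_GRID)
    gamma_grid: tuple[float, ...] = field(default_factory=lambda: DEFAULT_GAMMA_GRID)

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError("c and gamma must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def with_params(self, c: float, gamma: float) -> "SVRConfig":
        return replace(self, c=c, gamma=gamma)


@dataclass
class TrainedModel:
    """A fitted scaler+SVR pipeline bound to an ordered feature-name list."""

    feature_names: list[str]
    pipeline: Pipeline
    config: SVRConfig
    fingerprint: str

    def predict(self, matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
        return predict_scores(self, matrix)


def _as_array(
    matrix: FeatureMatrix | np.ndarray, feature_names: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, FeatureMatrix):
        if feature_names is not None and list(matrix.columns) != list(feature_names):
            matrix = matrix.subset(list(feature_names))
        return matrix.data, list(matrix.columns)
    data = np.asarray(matrix, dtype=float)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{j}" for j in range(data.shape[1])]
    )
    return data, names


def _fingerprint(data: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(data).tobytes())
    h.update(np.ascontiguousarray(labels).tobytes())
    return h.hexdigest()[:16]


def train_svr(
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    config: SVRConfig | None = None,
) -> TrainedModel:
    """Fit epsilon-SVR (RBF kernel) on standardized features.

    Labels must be +1/-1 and contain both classes; the regression target
    is the label itself.
    """
    config = config or SVRConfig()
    if isinstance(matrix, FeatureMatrix) and labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("labels are required")
    data, names = _as_array(matrix)
    labels = np.asarray(labels, dtype=float).ravel()
    if not np.isfinite(data).all():
        raise ValueError("feature matrix contains non-finite values")
    if not set(np.unique(labels)) <= {-1.0, 1.0}:
        raise ValueError("labels must be +1/-1")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data contains a single class")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svr", SVR(kernel="rbf", C=config.c, gamma=config.gamma, epsilon=config.epsilon)),
        ]
    )
    pipe.fit(data, labels)
    return TrainedModel(
        feature_names=names,
        pipeline=pipe,
        config=config,
        fingerprint=_fingerprint(data, labels),
    )


def predict_scores(
    model: TrainedModel, matrix: FeatureMatrix | np.ndarray
) -> np.ndarray:
    """Continuous cleavage scores, one per row; higher means more likely cleaved."""
    data, names = _as_array(matrix, model.feature_names)
    if names != model.feature_names:
        raise ValueError("feature names do not match the trained model")
    return model.pipeline.predict(data)


def classify(scores: np.ndarray, cutoff: float = 0.0) -> np.ndarray:
    """Threshold scores into +1/-1 calls; positive iff score > cutoff."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > cutoff, 1, -1)


def cv_auc(
    data: np.ndarray,
    labels: np.ndarray,
    config: SVRConfig,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Mean held-out AUC of an SVR with ``config`` over fixed CV folds."""
    aucs = []
    for train_idx, test_idx in folds:
        assert len(np.intersect1d(train_idx, test_idx)) == 0
        model = train_svr(data[train_idx], labels[train_idx], config)
        scores = predict_scores(model, data[test_idx])
        aucs.append(roc_auc(scores, labels[test_idx]))
    return float(np.mean(aucs))


def grid_search(
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    config: SVRConfig | None = None,
) -> tuple[float, float]:
    """Pick (c, gamma) maximizing mean CV AUC over the config's grids.

    Folds are stratified and seeded from the config; ties resolve to the
    smallest c, then the smallest gamma.
    """
    config = config or SVRConfig()
    if isinstance(matrix, FeatureMatrix) and labels is None:
        labels = matrix.labels
    data, _ = _as_array(matrix)
    labels = np.asarray(labels, dtype=float).ravel()
    folds = stratified_folds(labels, k=config.cv_folds, seed=config.seed)
    best = None
    best_auc = -np.inf
    for c in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            auc = cv_auc(data, labels, config.with_params(c, gamma), folds)
            if auc > best_auc:
                best_auc = auc
                best = (c, gamma)
    return best


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a model as JSON: readable header + base64-pickled SVR state."""
    payload = io.BytesIO()
    pickle.dump(model.pipeline, payload)
    doc = {
        "format": "mmptl-svr-model",
        "version": 1,
        "feature_names": model.feature_names,
        "config": {
            "c": model.config.c,
            "gamma": model.config.gamma,
            "epsilon": model.config.epsilon,
            "cutoff": model.config.cutoff,
            "cv_folds": model.config.cv_folds,
            "seed": model.config.seed,
        },
        "fingerprint": model.fingerprint,
        "scaler_mean": model.pipeline.named_steps["scale"].mean_.tolist(),
        "scaler_scale": model.pipeline.named_steps["scale"].scale_.tolist(),
        "payload": base64.b64encode(payload.getvalue()).decode("ascii"),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "mmptl-svr-model":
        raise ValueError(f"{path}: not a mmptl model file")
    pipeline = pickle.loads(base64.b64decode(doc["payload"]))
    config = SVRConfig(**doc["config"])
    return TrainedModel(
        feature_names=list(doc["feature_names"]),
        pipeline=pipeline,
        config=config,
        fingerprint=doc["fingerprint"],
    )
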