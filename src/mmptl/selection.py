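"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

The ranking is the greedy MID ("mutual information difference") scheme:
the first feature maximizes relevance I(f; y); each subsequent pick
maximizes I(f; y) - mean over already-selected s of I(f; s).  Mutual
information is the plug-in estimate in bits on discretized data;
continuous columns are binned into three states at mean +/- one standard
deviation, binary 0/1 columns pass through unchanged.  Ties break toward
the earlier column, so the ranking is deterministic and invariant to row
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoders import FeatureMatrix


@dataclass
class FeatureRanking:
    """Ordered feature names with relevance and selection-time mRMR scores."""

    names: list[str]
    relevance: np.ndarray  # I(f; y) in bits, per selected feature
    scores: np.ndarray  # MID objective value at the moment of selection

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names in ranking")
        self.relevance = np.asarray(self.relevance, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.names)

    def top(self, m: int) -> list[str]:
        return self.names[:m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.names) + 1),
                "feature": self.names,
                "relevance_bits": self.relevance,
                "mrmr_score": self.scores,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def discretize(matrix: np.ndarray) -> np.ndarray:
    """Discretize columns for mutual-information estimation.

    Binary columns (at most two distinct values, e.g. 0/1 one-hot
    features) are already discrete and pass through as codes; every
    other column is cut at mean +/- std into three states (below,
    within, above).  A constant column collapses to a single state.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
        squeeze = True
    else:
        squeeze = False
    out = np.empty(x.shape, dtype=np.int64)
    for j in range(x.shape[1]):
        col = x[:, j]
        uniq = np.unique(col)
        if len(uniq) <= 2:
            out[:, j] = np.searchsorted(uniq, col)
            continue
        mu, sd = col.mean(), col.std()
        states = np.ones(len(col), dtype=np.int64)
        states[col < mu - sd] = 0
        states[col > mu + sd] = 2
        out[:, j] = states
    return out[:, 0] if squeeze else out


def _to_codes(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary discrete values to dense codes 0..n_states-1."""
    _, codes = np.unique(x, return_inverse=True)
    return codes.astype(np.int64), int(codes.max()) + 1 if len(codes) else 0


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information in bits between two discrete vectors."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    cx, nx = _to_codes(x)
    cy, ny = _to_codes(y)
    return _mi_codes(cx, nx, cy, ny)


def _mi_codes(cx: np.ndarray, nx: int, cy: np.ndarray, ny: int) -> float:
    n = len(cx)
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log2(p[mask] / (px @ py)[mask])).sum())


def _state_onehot(codes: np.ndarray, n_states: int) -> np.ndarray:
    """Row-wise one-hot indicator, shape (n, n_states * p), feature-major.

    Counts between any discrete vector and every column then reduce to a
    single (dense) matrix product, which is what makes the greedy mRMR
    loop tractable on thousands of columns.
    """
    n, p = codes.shape
    onehot = np.zeros((n, p * n_states), dtype=np.float32)
    flat_cols = np.arange(p) * n_states + codes
    onehot[np.arange(n)[:, None], flat_cols] = 1.0
    return onehot


def _mi_one_vs_many(
    onehot: np.ndarray, n_states: int, cy: np.ndarray, ny: int
) -> np.ndarray:
    """MI in bits between every encoded column and the vector ``cy``.

    ``onehot`` is the indicator from :func:`_state_onehot`; empty states
    contribute nothing to the plug-in estimate, so padding is harmless.
    """
    n = onehot.shape[0]
    p = onehot.shape[1] // n_states
    yhot = np.zeros((n, ny), dtype=np.float32)
    yhot[np.arange(n), cy] = 1.0
    joint = (yhot.T @ onehot).reshape(ny, p, n_states).transpose(1, 2, 0)
    pj = joint.astype(np.float64) / n
    px = pj.sum(axis=2, keepdims=True)
    py = pj.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj * np.log2(pj / (px * py))
    return np.where(pj > 0, terms, 0.0).sum(axis=(1, 2))


def mrmr_rank(
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    m: int | None = None,
    column_names: Sequence[str] | None = None,
) -> FeatureRanking:
    """Greedy MID mRMR ranking of the top ``m`` features.

    Accepts a labeled :class:`FeatureMatrix`, or a plain array plus
    explicit ``labels`` (and optional ``column_names``).
    """
    if isinstance(matrix, FeatureMatrix):
        data = matrix.data
        names = list(matrix.columns)
        if labels is None:
            labels = matrix.labels
    else:
        data = np.asarray(matrix, dtype=float)
        names = (
            list(column_names)
            if column_names is not None
            else [f"f{j}" for j in range(data.shape[1])]
        )
    if labels is None:
        raise ValueError("labels are required")
    labels = np.asarray(labels).ravel()
    n, p = data.shape
    if m is None:
        m = p
    if m <= 0:
        raise ValueError("m must be positive")
    if m > p:
        raise ValueError(f"m={m} exceeds the number of columns ({p})")

    codes = discretize(data)  # every column lives in {0, 1, 2}
    n_states = 3
    cy, ny = _to_codes(labels)
    onehot = _state_onehot(codes, n_states)

    relevance = _mi_one_vs_many(onehot, n_states, cy, ny)

    selected: list[int] = []
    sel_scores: list[float] = []
    redundancy_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    for step in range(m):
        if step == 0:
            objective = relevance.copy()
        else:
            last = selected[-1]
            redundancy_sum += _mi_one_vs_many(
                onehot, n_states, codes[:, last], n_states
            )
            objective = relevance - redundancy_sum / len(selected)
        objective = np.where(available, objective, -np.inf)
        pick = int(np.argmax(objective))  # first max -> earlier column on ties
        selected.append(pick)
        sel_scores.append(float(objective[pick]))
        available[pick] = False
    return FeatureRanking(
        names=[names[j] for j in selected],
        relevance=relevance[selected],
        scores=np.asarray(sel_scores),
    )
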