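"""Knowledge-transfer model construction for a target protease.

The transfer protocol:

1. *Common knowledge*: pool the encoded windows of every source-domain
   protease and rank features with mRMR; the top 50 are the shared
   cleavage knowledge.
2. *Candidate list*: rank the top 100 features on the target domain
   alone, then append them after the common features, dropping
   duplicates — common features always come first.
3. *Forward selection*: for every prefix of the candidate list train an
   SVR and record its mean 5-fold CV AUC; the shortest prefix achieving
   the maximum AUC defines the final feature subset, and the final model
   is refitted on all target rows with that prefix.

The baseline alternative merges the windows of all proteases, takes the
plain mRMR top-100 on the merged data (no source/target distinction) and
evaluates the SVR on the target by cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoders import FeatureMatrix
from .evaluation import MetricsReport, cross_validate, roc_auc, stratified_folds
from .models import SVRConfig, TrainedModel, grid_search, train_svr
from .selection import FeatureRanking, mrmr_rank

DEFAULT_M_COMMON = 50
DEFAULT_M_TARGET = 100


@dataclass
class CommonKnowledge:
    """mRMR top features of the pooled source domains."""

    features: list[str]
    scores: np.ndarray
    source_names: list[str]

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in common knowledge")

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class TransferResult:
    """Outcome of forward selection on the transfer candidate list."""

    candidate_list: list[str]
    feature_origin: dict[str, str]  # feature -> "common" | "target_novel"
    auc_trace: np.ndarray  # mean CV AUC per prefix length 1..N
    auc_trace_sd: np.ndarray
    best_prefix_length: int
    model: TrainedModel
    config: SVRConfig

    @property
    def selected_features(self) -> list[str]:
        return self.candidate_list[: self.best_prefix_length]

    @property
    def best_auc(self) -> float:
        return float(self.auc_trace[self.best_prefix_length - 1])

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prefix_length": np.arange(1, len(self.auc_trace) + 1),
                "mean_auc": self.auc_trace,
                "sd_auc": self.auc_trace_sd,
            }
        )

    def export(self, trace_tsv: str | Path, summary_json: str | Path) -> None:
        self.trace_frame().to_csv(trace_tsv, sep="\t", index=False)
        summary = {
            "best_prefix_length": self.best_prefix_length,
            "best_auc": self.best_auc,
            "features": [
                {"name": f, "origin": self.feature_origin[f]}
                for f in self.selected_features
            ],
        }
        Path(summary_json).write_text(json.dumps(summary, indent=2))


def extract_common_knowledge(
    source_matrices: Sequence[FeatureMatrix],
    m_common: int = DEFAULT_M_COMMON,
    source_names: Sequence[str] | None = None,
) -> CommonKnowledge:
    """Pool all source-domain rows and return the mRMR top ``m_common``.

    ``m_common = 0`` yields empty knowledge (useful for ablation: the
    transfer pipeline then degenerates to pure target-domain selection).
    """
    if not source_matrices:
        raise ValueError("at least one source dataset is required")
    names = list(source_names) if source_names is not None else [
        f"source{i}" for i in range(len(source_matrices))
    ]
    if m_common == 0:
        return CommonKnowledge(features=[], scores=np.empty(0), source_names=names)
    pooled = (
        source_matrices[0]
        if len(source_matrices) == 1
        else FeatureMatrix.vstack(list(source_matrices))
    )
    if m_common > len(pooled.columns):
        raise ValueError(
            f"m_common={m_common} exceeds the feature universe "
            f"({len(pooled.columns)} columns)"
        )
    ranking = mrmr_rank(pooled, m=m_common)
    return CommonKnowledge(
        features=ranking.names, scores=ranking.scores, source_names=names
    )


def build_candidate_list(
    common: CommonKnowledge | Sequence[str],
    target_ranking: FeatureRanking | Sequence[str],
    m_target: int = DEFAULT_M_TARGET,
) -> list[str]:
    """Common features first (their order), then the target's top features
    not already present, in target-rank order."""
    common_feats = list(common.features if isinstance(common, CommonKnowledge) else common)
    target_feats = list(
        target_ranking.top(m_target)
        if isinstance(target_ranking, FeatureRanking)
        else list(target_ranking)[:m_target]
    )
    seen = set(common_feats)
    out = list(common_feats)
    for f in target_feats:
        if f not in seen:
            out.append(f)
            seen.add(f)
    return out


def forward_select(
    candidate_list: Sequence[str],
    target_matrix: FeatureMatrix,
    config: SVRConfig | None = None,
    feature_origin: Mapping[str, str] | None = None,
    per_prefix_grid: bool = False,
    do_grid_search: bool = True,
) -> TransferResult:
    """AUC-driven forward selection over prefixes of the candidate list.

    Each prefix is scored by mean stratified 5-fold CV AUC with fixed,
    seeded folds; the best prefix is the shortest one attaining the
    maximum.  By default (c, gamma) are tuned once by grid search on the
    full candidate list and reused for every prefix; ``per_prefix_grid``
    re-tunes at each prefix (much slower, stricter protocol).  The final
    model is refitted on all target rows with the winning prefix.
    """
    candidate_list = list(candidate_list)
    if not candidate_list:
        raise ValueError("candidate list is empty")
    config = config or SVRConfig()
    sub = target_matrix.subset(candidate_list)
    labels = np.asarray(target_matrix.labels, dtype=float).ravel()
    counts = np.unique(labels, return_counts=True)[1]
    if len(counts) < 2 or counts.min() < config.cv_folds:
        raise ValueError(
            "target dataset needs at least cv_folds members of each class"
        )
    folds = stratified_folds(labels, k=config.cv_folds, seed=config.seed)
    if do_grid_search and not per_prefix_grid:
        c, gamma = grid_search(sub, labels, config)
        config = config.with_params(c, gamma)
    means = np.empty(len(candidate_list))
    sds = np.empty(len(candidate_list))
    for n in range(1, len(candidate_list) + 1):
        data = sub.data[:, :n]
        cfg = config
        if per_prefix_grid and do_grid_search:
            c, gamma = grid_search(data, labels, config)
            cfg = config.with_params(c, gamma)
        fold_aucs = []
        for train_idx, test_idx in folds:
            model = train_svr(data[train_idx], labels[train_idx], cfg)
            fold_aucs.append(
                roc_auc(model.predict(data[test_idx]), labels[test_idx])
            )
        means[n - 1] = np.mean(fold_aucs)
        sds[n - 1] = np.std(fold_aucs, ddof=1)
    best_n = int(np.argmax(means)) + 1  # first max -> shortest prefix on ties
    final = train_svr(sub.subset(candidate_list[:best_n]), labels, config)
    origin = dict(feature_origin or {})
    for f in candidate_list:
        origin.setdefault(f, "target_novel")
    return TransferResult(
        candidate_list=candidate_list,
        feature_origin=origin,
        auc_trace=means,
        auc_trace_sd=sds,
        best_prefix_length=best_n,
        model=final,
        config=config,
    )


def run_transfer(
    matrices: Mapping[str, FeatureMatrix],
    target_name: str,
    config: SVRConfig | None = None,
    m_common: int = DEFAULT_M_COMMON,
    m_target: int = DEFAULT_M_TARGET,
    per_prefix_grid: bool = False,
    do_grid_search: bool = True,
) -> TransferResult:
    """Leave-one-protease-out transfer: every dataset except the target is
    a source domain; the target never contributes rows to the common
    knowledge."""
    if target_name not in matrices:
        raise KeyError(f"unknown target {target_name!r}")
    config = config or SVRConfig()
    source = [m for name, m in matrices.items() if name != target_name]
    source_names = [name for name in matrices if name != target_name]
    common = extract_common_knowledge(source, m_common, source_names)
    target = matrices[target_name]
    target_ranking = mrmr_rank(target, m=min(m_target, len(target.columns)))
    candidates = build_candidate_list(common, target_ranking, m_target)
    origin = {f: "common" for f in common.features}
    return forward_select(
        candidates,
        target,
        config,
        feature_origin=origin,
        per_prefix_grid=per_prefix_grid,
        do_grid_search=do_grid_search,
    )


def evaluate_transfer(
    result: TransferResult,
    target_matrix: FeatureMatrix,
    k: int = 5,
    seed: int | None = None,
) -> MetricsReport:
    """Cross-validated metrics of the selected feature subset on the target.

    Reporting uses fresh seeded folds (``seed`` defaults to the model's
    seed + 1) so the selection folds do not grade themselves.
    """
    seed = result.config.seed + 1 if seed is None else seed
    sub = target_matrix.subset(result.selected_features)
    sub.labels = target_matrix.labels
    return cross_validate(sub, config=result.config, k=k, seed=seed)


def train_baseline(
    matrices: Mapping[str, FeatureMatrix],
    target_name: str,
    m: int = DEFAULT_M_TARGET,
    config: SVRConfig | None = None,
    selection_corpus: str = "merged",
    do_grid_search: bool = True,
    eval_seed: int | None = None,
) -> tuple[TrainedModel, MetricsReport]:
    """Merged-data baseline: plain mRMR top-``m`` with no transfer step.

    Features are selected on the merged windows of all proteases
    (``selection_corpus="merged"``, the default) or on the target alone
    (``"target"``); the SVR is then evaluated on the target dataset by
    stratified cross-validation and refitted on all target rows.
    """
    if target_name not in matrices:
        raise KeyError(f"unknown target {target_name!r}")
    if selection_corpus not in ("merged", "target"):
        raise ValueError("selection_corpus must be 'merged' or 'target'")
    config = config or SVRConfig()
    target = matrices[target_name]
    corpus = (
        FeatureMatrix.vstack(list(matrices.values()))
        if selection_corpus == "merged" and len(matrices) > 1
        else target
    )
    ranking = mrmr_rank(corpus, m=min(m, len(corpus.columns)))
    sub = target.subset(ranking.names)
    sub.labels = target.labels
    if do_grid_search:
        c, gamma = grid_search(sub, sub.labels, config)
        config = config.with_params(c, gamma)
    seed = config.seed + 1 if eval_seed is None else eval_seed
    report = cross_validate(sub, config=config, k=config.cv_folds, seed=seed)
    model = train_svr(sub, sub.labels, config)
    return model, report
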