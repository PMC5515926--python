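"""Transfer algorithm: common knowledge, candidate lists, forward selection,
baseline, and leave-one-protease-out orchestration."""

import numpy as np
import pytest

from mmptl.encoders import FeatureMatrix
from mmptl.models import SVRConfig
from mmptl.selection import mrmr_rank
from mmptl.transfer import (
    CommonKnowledge,
    build_candidate_list,
    evaluate_transfer,
    extract_common_knowledge,
    forward_select,
    run_transfer,
    train_baseline,
)

FAST_CFG = SVRConfig(c=8.0, gamma=0.125, seed=0)


def _matrix(rng, n=40, p=6, informative=(), names=None, label_seed=None):
    """Random feature matrix; ``informative`` columns get a label bump."""
    y = np.repeat([1, -1], n // 2)
    if label_seed is not None:
        y = np.random.default_rng(label_seed).permutation(y)
    X = rng.normal(size=(n, p))
    for j in informative:
        X[:, j] += 1.5 * y
    return FeatureMatrix(
        row_ids=[f"r{i}" for i in range(n)],
        columns=names or [f"f{j}" for j in range(p)],
        data=X,
        labels=y,
    )


class TestCommonKnowledge:
    def test_single_source_reduces_to_plain_mrmr(self, rng):
        fm = _matrix(rng, informative=(2,))
        common = extract_common_knowledge([fm], m_common=3)
        assert common.features == mrmr_rank(fm, m=3).names

    def test_zero_m_common_is_empty(self, rng):
        common = extract_common_knowledge([_matrix(rng)], m_common=0)
        assert len(common) == 0

    def test_m_common_larger_than_universe_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_common_knowledge([_matrix(rng, p=4)], m_common=10)

    def test_feature_informative_in_all_sources_is_found(self):
        rng = np.random.default_rng(0)
        sources = [_matrix(rng, informative=(1,)) for _ in range(3)]
        common = extract_common_knowledge(sources, m_common=2)
        assert "f1" in common.features

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            extract_common_knowledge([], m_common=5)


class TestBuildCandidateList:
    def test_disjoint_sets_concatenate(self):
        common = [f"c{i}" for i in range(50)]
        target = [f"t{i}" for i in range(100)]
        out = build_candidate_list(common, target)
        assert len(out) == 150
        assert out[:50] == common

    def test_full_overlap_keeps_common_only(self):
        common = [f"c{i}" for i in range(10)]
        out = build_candidate_list(common, list(reversed(common)), m_target=100)
        assert out == common

    def test_single_shared_feature_deduplicated(self):
        common = [f"c{i}" for i in range(50)]
        target = [f"t{i}" for i in range(99)] + [common[7]]
        out = build_candidate_list(common, target)
        assert len(out) == 149
        assert out.index(common[7]) == 7  # kept at its common-list slot

    def test_m_target_truncates(self):
        out = build_candidate_list([], [f"t{i}" for i in range(30)], m_target=5)
        assert out == [f"t{i}" for i in range(5)]


class TestForwardSelect:
    def test_single_candidate(self, rng):
        fm = _matrix(rng, informative=(0,))
        res = forward_select(["f0"], fm, FAST_CFG, do_grid_search=False)
        assert res.best_prefix_length == 1
        assert len(res.auc_trace) == 1

    def test_noise_feature_excluded(self, rng):
        fm = _matrix(rng, n=60, p=2, informative=(0,))
        res = forward_select(["f0", "f1"], fm, FAST_CFG, do_grid_search=False)
        assert res.best_prefix_length == 1
        assert res.selected_features == ["f0"]
        # trace does not improve after the signal feature, within CV error
        assert res.auc_trace[1] <= res.auc_trace[0] + 1e-12

    def test_deterministic_trace(self, rng):
        fm = _matrix(rng, informative=(0, 2))
        a = forward_select(["f0", "f1", "f2"], fm, FAST_CFG, do_grid_search=False)
        b = forward_select(["f0", "f1", "f2"], fm, FAST_CFG, do_grid_search=False)
        assert np.array_equal(a.auc_trace, b.auc_trace)
        assert a.best_prefix_length == b.best_prefix_length

    def test_selected_is_prefix_of_candidates(self, rng):
        fm = _matrix(rng, n=60, p=5, informative=(1, 3))
        candidates = ["f3", "f0", "f1", "f4", "f2"]
        res = forward_select(candidates, fm, FAST_CFG, do_grid_search=False)
        assert res.candidate_list == candidates
        assert res.selected_features == candidates[: res.best_prefix_length]

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            forward_select([], _matrix(rng), FAST_CFG)

    def test_too_few_rows_per_class_rejected(self, rng):
        fm = _matrix(rng, n=6)
        with pytest.raises(ValueError, match="cv_folds"):
            forward_select(["f0"], fm, FAST_CFG)

    def test_export(self, rng, tmp_path):
        fm = _matrix(rng, informative=(0,))
        res = forward_select(["f0", "f1"], fm, FAST_CFG, do_grid_search=False)
        res.export(tmp_path / "trace.tsv", tmp_path / "summary.json")
        assert (tmp_path / "trace.tsv").read_text().startswith(
            "prefix_length\tmean_auc\tsd_auc"
        )
        assert '"best_prefix_length"' in (tmp_path / "summary.json").read_text()


class TestRunTransfer:
    def _matrices(self, seed=0, target_informative=(0, 2)):
        rng = np.random.default_rng(seed)
        mats = {
            f"SRC{i}": _matrix(rng, informative=(0,)) for i in range(2)
        }
        mats["TGT"] = _matrix(rng, informative=target_informative)
        return mats

    def test_common_features_flagged_and_first(self):
        mats = self._matrices()
        res = run_transfer(
            mats, "TGT", FAST_CFG, m_common=2, m_target=3, do_grid_search=False
        )
        common = [f for f in res.candidate_list if res.feature_origin[f] == "common"]
        assert res.candidate_list[: len(common)] == common
        assert 0 < len(common) <= 2

    def test_target_rows_do_not_shape_common_knowledge(self):
        # changing the target data must leave the common-flagged features
        # untouched (leave-one-protease-out invariant)
        a = self._matrices(target_informative=(0, 2))
        b = self._matrices(target_informative=(4,))
        ra = run_transfer(a, "TGT", FAST_CFG, m_common=2, m_target=2, do_grid_search=False)
        rb = run_transfer(b, "TGT", FAST_CFG, m_common=2, m_target=2, do_grid_search=False)
        ca = [f for f in ra.candidate_list if ra.feature_origin[f] == "common"]
        cb = [f for f in rb.candidate_list if rb.feature_origin[f] == "common"]
        assert ca == cb

    def test_zero_common_degenerates_to_target_selection(self):
        mats = self._matrices()
        res = run_transfer(
            mats, "TGT", FAST_CFG, m_common=0, m_target=4, do_grid_search=False
        )
        target_top = mrmr_rank(mats["TGT"], m=4).names
        assert res.candidate_list == target_top
        assert all(v == "target_novel" for v in res.feature_origin.values())

    def test_unknown_target_rejected(self):
        with pytest.raises(KeyError):
            run_transfer(self._matrices(), "nope", FAST_CFG)

    def test_evaluate_transfer_reports_auc(self):
        mats = self._matrices()
        res = run_transfer(
            mats, "TGT", FAST_CFG, m_common=2, m_target=3, do_grid_search=False
        )
        rep = evaluate_transfer(res, mats["TGT"])
        assert 0.0 <= rep.auc <= 1.0
        assert rep.counts.total == len(mats["TGT"].row_ids)


class TestBaseline:
    def test_single_dataset_reduces_to_plain_selection(self, rng):
        fm = _matrix(rng, n=60, informative=(1,))
        model, rep = train_baseline(
            {"only": fm}, "only", m=3, config=FAST_CFG, do_grid_search=False
        )
        assert model.feature_names == mrmr_rank(fm, m=3).names
        assert rep.auc > 0.8

    def test_target_corpus_flag(self, rng):
        mats = {
            "A": _matrix(rng, informative=(0,)),
            "B": _matrix(rng, informative=(3,)),
        }
        model, _ = train_baseline(
            mats, "B", m=2, config=FAST_CFG,
            selection_corpus="target", do_grid_search=False,
        )
        assert model.feature_names == mrmr_rank(mats["B"], m=2).names

    def test_deterministic(self, rng):
        mats = {
            "A": _matrix(rng, informative=(0,)),
            "B": _matrix(rng, informative=(0,)),
        }
        _, r1 = train_baseline(mats, "B", m=2, config=FAST_CFG, do_grid_search=False)
        _, r2 = train_baseline(mats, "B", m=2, config=FAST_CFG, do_grid_search=False)
        assert r1.auc == r2.auc

    def test_bad_corpus_rejected(self, rng):
        with pytest.raises(ValueError):
            train_baseline(
                {"A": _matrix(rng)}, "A", config=FAST_CFG, selection_corpus="x"
            )
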