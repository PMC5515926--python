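"""Feature encoders: dimensionalities, hand-constructed vectors, purity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mmptl.encoders import (
    FeatureMatrix,
    SCHEME_DIMS,
    TOTAL_DIM,
    encode_aaindex,
    encode_aapair,
    encode_all,
    encode_binary,
    encode_blosum,
    encode_charge_hyd,
    encode_cksaap,
    encode_dataset,
    encode_disopred,
    encode_pssm,
)
from mmptl.io_data import AA20, Substrate, extract_windows

windows_st = st.text(alphabet=AA20 + "X", min_size=16, max_size=16)


class TestBinary:
    def test_poly_alanine_hits_the_a_slots(self):
        block = encode_binary("A" * 16)
        assert len(block.values) == 336
        hot = np.flatnonzero(block.values)
        assert list(hot) == [21 * i for i in range(16)]

    def test_pads_use_only_the_nonstandard_slot(self):
        block = encode_binary("X" * 16)
        vec = block.values.reshape(16, 21)
        assert vec[:, :20].sum() == 0
        assert (vec[:, 20] == 1).all()

    @given(windows_st)
    def test_exactly_one_hot_per_position(self, window):
        vec = encode_binary(window).values.reshape(16, 21)
        assert (vec.sum(axis=1) == 1).all()


class TestAAindex:
    def test_default_table_dimension(self, resources):
        assert len(encode_aaindex("G" * 16, resources.aaindex).values) == 1024

    def test_repeated_residue_tiles_its_column(self, resources):
        block = encode_aaindex("W" * 16, resources.aaindex)
        col = resources.aaindex["W"].to_numpy()
        assert np.allclose(block.values.reshape(16, 64), np.tile(col, (16, 1)))

    def test_pad_imputed_with_column_means(self, resources):
        block = encode_aaindex("X" + "A" * 15, resources.aaindex)
        means = resources.aaindex[list(AA20)].to_numpy().mean(axis=1)
        assert np.allclose(block.values[:64], means)

    def test_nonstandard_table_size_changes_dimension(self):
        table = pd.DataFrame(
            np.ones((3, 20)), index=["i1", "i2", "i3"], columns=list(AA20)
        )
        assert len(encode_aaindex("A" * 16, table).values) == 16 * 3


class TestAAPair:
    def test_pure_composition(self):
        vals = dict(zip(*[encode_aapair("A" * 16).names, encode_aapair("A" * 16).values]))
        assert vals["AAPair:A"] == 1.0
        assert sum(vals.values()) == 1.0

    def test_half_and_half(self):
        block = encode_aapair("A" * 8 + "G" * 8)
        d = dict(zip(block.names, block.values))
        assert d["AAPair:A"] == d["AAPair:G"] == 0.5

    def test_all_pad_window_is_zero(self):
        assert encode_aapair("X" * 16).values.sum() == 0

    @given(windows_st.filter(lambda w: set(w) != {"X"}))
    def test_frequencies_sum_to_one(self, window):
        assert encode_aapair(window).values.sum() == pytest.approx(1.0, abs=1e-12)


class TestBLOSUM:
    def test_dimension(self, resources):
        assert len(encode_blosum("A" * 16, resources.blosum).values) == 336

    def test_tryptophan_self_score(self, resources):
        block = encode_blosum("W" * 16, resources.blosum)
        d = dict(zip(block.names, block.values))
        assert d["BLOSUM:P8:W"] == 11

    def test_deterministic(self, resources):
        a = encode_blosum("GPLGLWAQGPLGLWAQ", resources.blosum).values
        b = encode_blosum("GPLGLWAQGPLGLWAQ", resources.blosum).values
        assert (a == b).all()


class TestChargeHyd:
    def test_dimension(self):
        assert len(encode_charge_hyd("A" * 16).values) == 9

    def test_glycine_window_has_no_charge_or_aromatics(self):
        d = dict(zip(*[encode_charge_hyd("G" * 16).names, encode_charge_hyd("G" * 16).values]))
        assert all(v == 0 for k, v in d.items() if "charge" in k or "aromatic" in k)

    def test_basic_acidic_halves(self):
        block = encode_charge_hyd("K" * 8 + "D" * 8)
        d = dict(zip(block.names, block.values))
        assert d["CHARGE_Hyd:full:charge"] == 0
        assert d["CHARGE_Hyd:Nhalf:charge"] == 1
        assert d["CHARGE_Hyd:Chalf:charge"] == -1


class TestCKSAAP:
    def test_poly_alanine_adjacent_pairs(self):
        block = encode_cksaap("A" * 16, k_values=(0,))
        d = dict(zip(block.names, block.values))
        assert d["CKSAAP:k0:AA"] == 1.0
        assert sum(d.values()) == 1.0

    @pytest.mark.parametrize("k", range(6))
    def test_n_total_is_15_minus_k(self, k):
        # all-distinct residues: every observed pair occurs once, so each
        # nonzero frequency equals 1/N_Total
        window = "ACDEFGHIKLMNPQRS"
        block = encode_cksaap(window, k_values=(k,))
        nonzero = block.values[block.values > 0]
        assert len(nonzero) == 15 - k
        assert np.allclose(nonzero, 1.0 / (15 - k))

    def test_pad_pairs_excluded_and_total_adjusted(self):
        window = "X" * 5 + "A" * 11
        block = encode_cksaap(window, k_values=(0,))
        d = dict(zip(block.names, block.values))
        assert d["CKSAAP:k0:AA"] == 1.0  # 10 AA pairs / N_Total 10

    def test_full_dimension(self):
        assert len(encode_cksaap("A" * 16).values) == 2400

    @given(windows_st.filter(lambda w: "X" not in w))
    def test_per_k_sums_to_one_without_pads(self, window):
        vals = encode_cksaap(window).values.reshape(6, 400)
        assert np.allclose(vals.sum(axis=1), 1.0)


class TestProfileEncoders:
    def test_disopred_echoes_profile(self):
        prof = np.linspace(0, 1, 16)
        block = encode_disopred("A" * 16, prof)
        assert np.allclose(block.values, prof)

    def test_disopred_missing_profile(self):
        assert (encode_disopred("A" * 16).values == 0.5).all()

    def test_disopred_nan_slots_filled(self):
        prof = np.full(16, 0.9)
        prof[0] = np.nan
        vals = encode_disopred("A" * 16, prof).values
        assert vals[0] == 0.5 and (vals[1:] == 0.9).all()

    def test_pssm_logistic_midpoint(self):
        block = encode_pssm("A" * 16, np.zeros((16, 20)))
        assert (block.values == 0.5).all()

    def test_pssm_squashing_bounds(self):
        mat = np.full((16, 20), 10.0)
        vals = encode_pssm("A" * 16, mat).values
        assert ((vals > 0.99) & (vals < 1.0)).all()

    def test_pssm_missing_profile(self):
        block = encode_pssm("A" * 16)
        assert len(block.values) == 320
        assert (block.values == 0.5).all()


class TestEncodeAll:
    def test_scheme_dimensions_and_total(self, resources):
        block = encode_all("GPLGLWAQGPLGLWAQ", resources)
        assert len(block.values) == TOTAL_DIM
        for scheme, dim in SCHEME_DIMS.items():
            prefix = f"{scheme}:"
            assert sum(n.startswith(prefix) for n in block.names) == dim

    def test_column_names_unique(self, resources):
        block = encode_all("A" * 16, resources)
        assert len(set(block.names)) == len(block.names)

    def test_deterministic(self, resources):
        a = encode_all("GPLGLWAQGPLGLWAQ", resources).values
        b = encode_all("GPLGLWAQGPLGLWAQ", resources).values
        assert (a == b).all()

    def test_scheme_subset_order_is_canonical(self, resources):
        block = encode_all("A" * 16, resources, schemes=("CKSAAP", "AAPair"))
        # AAPair precedes CKSAAP regardless of the requested order
        assert block.names[0].startswith("AAPair:")
        assert len(block.values) == 20 + 2400

    def test_unknown_scheme_rejected(self, resources):
        with pytest.raises(ValueError):
            encode_all("A" * 16, resources, schemes=("Nope",))


class TestEncodeDataset:
    def test_profile_plumbing_reaches_feature_rows(self, resources):
        sub = Substrate(
            "s",
            "A" * 32,
            {16},
            disorder=np.full(32, 0.25),
            pssm=np.zeros((32, 20)),
        )
        windows = [w for w in extract_windows(sub) if w.p1_position == 16]
        fm = encode_dataset(
            windows, resources, substrates={"s": sub}, schemes=("DISOPRED", "PSSM")
        )
        row = dict(zip(fm.columns, fm.data[0]))
        assert row["DISOPRED:P1"] == 0.25
        assert row["PSSM:P1:A"] == 0.5

    def test_labels_and_row_ids(self, resources, tiny_scenario):
        ds = tiny_scenario.domain_datasets(seed=0)["TGT"]
        fm = encode_dataset(ds.windows, resources, schemes=("AAPair",))
        assert set(np.unique(fm.labels)) == {-1, 1}
        assert len(fm.row_ids) == len(ds.windows)

    def test_vstack_requires_matching_columns(self, resources):
        fm = encode_dataset(
            [extract_windows(Substrate("s", "A" * 20))[5]],
            resources,
            schemes=("AAPair",),
        )
        other = FeatureMatrix(["r"], ["x"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            FeatureMatrix.vstack([fm, other])
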