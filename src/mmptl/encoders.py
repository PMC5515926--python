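"""Eight feature-encoding schemes for 16-residue cleavage windows.

Every window is mapped to a fixed-dimension, named feature vector:

=========== ==== =========================================================
scheme       dim  content
=========== ==== =========================================================
AAindex     1024  64 physicochemical indices per residue (16 x 64)
AAPair        20  amino-acid composition of the window
Binary       336  one-hot residue identity per position (16 x 21)
BLOSUM       336  BLOSUM62 substitution row per position (16 x 21)
CHARGE_Hyd     9  net charge / aromaticity / charge:hydrophobicity ratio
                  for the full window and each half
CKSAAP      2400  k-spaced residue-pair frequencies, k = 0..5 (6 x 400)
DISOPRED      16  per-position disorder probability
PSSM         320  logistic-squashed PSSM log-odds per position (16 x 20)
=========== ==== =========================================================

The full concatenation, in the table's order, has 4461 columns.  All
encoders are pure functions of the window and the supplied resources.
Terminal pad characters ('X') encode as the non-standard slot in Binary,
the X row of BLOSUM62, the column mean in AAindex, and are excluded from
composition counts (AAPair, CKSAAP) and from the CHARGE_Hyd segment means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io_data import (
    AA20,
    PAD,
    POSITION_LABELS,
    WINDOW_LENGTH,
    CleavageWindow,
    Substrate,
    window_profile_slices,
)

SCHEME_ORDER = (
    "AAindex",
    "AAPair",
    "Binary",
    "BLOSUM",
    "CHARGE_Hyd",
    "CKSAAP",
    "DISOPRED",
    "PSSM",
)
SCHEME_DIMS = {
    "AAindex": 1024,
    "AAPair": 20,
    "Binary": 336,
    "BLOSUM": 336,
    "CHARGE_Hyd": 9,
    "CKSAAP": 2400,
    "DISOPRED": 16,
    "PSSM": 320,
}
TOTAL_DIM = 4461

#: Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
#: side-chain net charge at physiological pH (His partially protonated)
NET_CHARGE = {"K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0}
AROMATIC = frozenset("FWYH")
#: offset keeping the hydrophobicity denominator of the charge ratio positive
HYDROPHOBICITY_OFFSET = 5.0

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


@dataclass(frozen=True)
class FeatureBlock:
    """One encoding scheme's named feature vector for a single window."""

    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")


@dataclass
class FeatureMatrix:
    """Windows x named features, with optional +1/-1 labels."""

    row_ids: list[str]
    columns: list[str]
    data: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError("data shape does not match row_ids x columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.row_ids):
                raise ValueError("labels length mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, columns: Sequence[str]) -> "FeatureMatrix":
        idx = [self.columns.index(c) for c in columns]
        return FeatureMatrix(
            row_ids=list(self.row_ids),
            columns=list(columns),
            data=self.data[:, idx],
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, index=self.row_ids, columns=self.columns)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="window_id")

    @classmethod
    def vstack(cls, matrices: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        first = matrices[0]
        for m in matrices[1:]:
            if m.columns != first.columns:
                raise ValueError("cannot stack matrices with different columns")
        labels = None
        if all(m.labels is not None for m in matrices):
            labels = np.concatenate([m.labels for m in matrices])
        return cls(
            row_ids=[rid for m in matrices for rid in m.row_ids],
            columns=list(first.columns),
            data=np.vstack([m.data for m in matrices]),
            labels=labels,
        )


# ---------------------------------------------------------------------------
# resources


def load_aaindex_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a physicochemical index table (rows = indices, columns = AA20).

    The bundled default, ``aaindex64_synthetic.tsv``, is a synthetic
    stand-in for a curated 64-index selection: 64 z-scored pseudo-indices
    generated once with a fixed seed.  Any user table with the same layout
    is accepted; a table with a different number of indices changes the
    AAindex block dimension accordingly.
    """
    if path is None:
        ref = importlib_resources.files("mmptl.data") / "aaindex64_synthetic.tsv"
        with importlib_resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(AA20) - set(df.columns)
    if missing:
        raise ValueError(f"index table missing residues: {sorted(missing)}")
    return df[list(AA20)]


def _load_blosum62() -> np.ndarray:
    """BLOSUM62 as a (21, 21) array over AA20 + X, X row/column from the
    standard matrix."""
    m = substitution_matrices.load("BLOSUM62")
    letters = AA20 + PAD
    out = np.empty((21, 21))
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            out[i, j] = m[a, b]
    return out


@dataclass
class EncodingResources:
    """Shared lookup tables for the encoders."""

    aaindex: pd.DataFrame = field(default_factory=load_aaindex_table)
    blosum: np.ndarray = field(default_factory=_load_blosum62)
    k_values: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    charge: dict = field(default_factory=lambda: dict(NET_CHARGE))
    hydropathy: dict = field(default_factory=lambda: dict(KYTE_DOOLITTLE))


def _residues(window: CleavageWindow | str) -> str:
    seq = window.residues if isinstance(window, CleavageWindow) else window
    if len(seq) != WINDOW_LENGTH:
        raise ValueError(f"window must be {WINDOW_LENGTH} residues")
    return seq.upper()


# ---------------------------------------------------------------------------
# encoders


def encode_binary(window: CleavageWindow | str) -> FeatureBlock:
    """One-hot residue identity: 21 slots per position (AA20 + non-standard)."""
    seq = _residues(window)
    values = np.zeros(WINDOW_LENGTH * 21)
    names = []
    for i, pos in enumerate(POSITION_LABELS):
        names.extend(f"Binary:{pos}:{a}" for a in AA20)
        names.append(f"Binary:{pos}:nonstd")
        a = seq[i]
        if a in _AA_INDEX:
            values[i * 21 + _AA_INDEX[a]] = 1.0
        else:
            values[i * 21 + 20] = 1.0
    return FeatureBlock("Binary", tuple(names), values)


def encode_aaindex(
    window: CleavageWindow | str, index_table: pd.DataFrame
) -> FeatureBlock:
    """Physicochemical index values per residue; pads take the per-index
    mean over the 20 standard residues."""
    seq = _residues(window)
    table = index_table[list(AA20)].to_numpy(dtype=float)  # (n_idx, 20)
    col_means = table.mean(axis=1)
    n_idx = table.shape[0]
    values = np.empty(WINDOW_LENGTH * n_idx)
    names = []
    ids = list(index_table.index)
    for i, pos in enumerate(POSITION_LABELS):
        a = seq[i]
        vec = table[:, _AA_INDEX[a]] if a in _AA_INDEX else col_means
        values[i * n_idx : (i + 1) * n_idx] = vec
        names.extend(f"AAindex:{pos}:{idx}" for idx in ids)
    return FeatureBlock("AAindex", tuple(names), values)


def encode_aapair(window: CleavageWindow | str) -> FeatureBlock:
    """Amino-acid composition of the window; pads excluded from both the
    numerator and the denominator."""
    seq = _residues(window)
    counts = np.zeros(20)
    total = 0
    for a in seq:
        if a in _AA_INDEX:
            counts[_AA_INDEX[a]] += 1
            total += 1
    values = counts / total if total else counts
    names = tuple(f"AAPair:{a}" for a in AA20)
    return FeatureBlock("AAPair", names, values)


def encode_blosum(
    window: CleavageWindow | str, blosum: np.ndarray | None = None
) -> FeatureBlock:
    """BLOSUM62 substitution row per residue over AA20 + the X column."""
    if blosum is None:
        blosum = _load_blosum62()
    seq = _residues(window)
    values = np.empty(WINDOW_LENGTH * 21)
    names = []
    for i, pos in enumerate(POSITION_LABELS):
        a = seq[i]
        row = _AA_INDEX.get(a, 20)  # non-standard -> X row
        values[i * 21 : (i + 1) * 21] = blosum[row]
        names.extend(f"BLOSUM:{pos}:{b}" for b in AA20)
        names.append(f"BLOSUM:{pos}:nonstd")
    return FeatureBlock("BLOSUM", tuple(names), values)


def _segment_props(
    seq: str, charge: dict, hydropathy: dict
) -> tuple[float, float, float]:
    residues = [a for a in seq if a in _AA_INDEX]
    if not residues:
        return 0.0, 0.0, 0.0
    mean_charge = float(np.mean([charge.get(a, 0.0) for a in residues]))
    aromatic = float(np.mean([a in AROMATIC for a in residues]))
    mean_hyd = float(np.mean([hydropathy[a] for a in residues]))
    ratio = abs(mean_charge) / (mean_hyd + HYDROPHOBICITY_OFFSET)
    return mean_charge, aromatic, ratio


def encode_charge_hyd(
    window: CleavageWindow | str,
    charge: dict | None = None,
    hydropathy: dict | None = None,
) -> FeatureBlock:
    """Mean net charge, aromatic content, and charge:hydrophobicity ratio
    for three segments: the full window, the N-half (P8-P1) and the
    C-half (P1'-P8').

    Charge: K,R=+1, D,E=-1, H=+0.1.  Aromatic content: fraction of
    F,W,Y,H.  The ratio divides |mean charge| by the mean Kyte-Doolittle
    hydropathy shifted by +5 to stay positive.  Pads are excluded from
    the segment means.
    """
    charge = charge if charge is not None else NET_CHARGE
    hydropathy = hydropathy if hydropathy is not None else KYTE_DOOLITTLE
    seq = _residues(window)
    half = WINDOW_LENGTH // 2
    segments = {"full": seq, "Nhalf": seq[:half], "Chalf": seq[half:]}
    names, values = [], []
    for seg_name, seg in segments.items():
        c, arom, ratio = _segment_props(seg, charge, hydropathy)
        for prop, val in (("charge", c), ("aromatic", arom), ("charge_hyd_ratio", ratio)):
            names.append(f"CHARGE_Hyd:{seg_name}:{prop}")
            values.append(val)
    return FeatureBlock("CHARGE_Hyd", tuple(names), np.asarray(values))


def encode_cksaap(
    window: CleavageWindow | str, k_values: Iterable[int] = (0, 1, 2, 3, 4, 5)
) -> FeatureBlock:
    """Composition of k-spaced amino-acid pairs.

    For spacing k the window contributes pairs (i, i+k+1); a full 16-mer
    has N_Total = 15, 14, 13, 12, 11, 10 pairs at k = 0..5.  Pairs that
    involve a pad are dropped from the count and N_Total is reduced
    accordingly.
    """
    seq = _residues(window)
    k_values = tuple(k_values)
    if any(k < 0 or k > 5 for k in k_values):
        raise ValueError("k_values must lie in 0..5")
    names, values = [], []
    pair_names = [a + b for a in AA20 for b in AA20]
    for k in k_values:
        counts = np.zeros(400)
        n_total = 0
        for i in range(WINDOW_LENGTH - k - 1):
            a, b = seq[i], seq[i + k + 1]
            if a in _AA_INDEX and b in _AA_INDEX:
                counts[_AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1
                n_total += 1
        freqs = counts / n_total if n_total else counts
        values.append(freqs)
        names.extend(f"CKSAAP:k{k}:{p}" for p in pair_names)
    return FeatureBlock("CKSAAP", tuple(names), np.concatenate(values))


def encode_disopred(
    window: CleavageWindow | str, disorder_profile: np.ndarray | None = None
) -> FeatureBlock:
    """Per-position disorder probability; slots without a profile value
    (missing profile, or pad positions) are filled with 0.5."""
    _residues(window)  # length check
    if disorder_profile is None:
        vals = np.full(WINDOW_LENGTH, 0.5)
    else:
        vals = np.asarray(disorder_profile, dtype=float).copy()
        if vals.shape != (WINDOW_LENGTH,):
            raise ValueError("disorder profile must have 16 values")
        vals[np.isnan(vals)] = 0.5
    names = tuple(f"DISOPRED:{pos}" for pos in POSITION_LABELS)
    return FeatureBlock("DISOPRED", names, vals)


def encode_pssm(
    window: CleavageWindow | str, pssm_profile: np.ndarray | None = None
) -> FeatureBlock:
    """Logistic-squashed PSSM log-odds, 20 per position.

    Raw PSI-BLAST scores are mapped through 1/(1+e^-x) so every feature
    lies in (0, 1); missing rows (no profile, or pad slots) become 0.5,
    the squashed value of a zero score.
    """
    _residues(window)
    if pssm_profile is None:
        vals = np.full(WINDOW_LENGTH * 20, 0.5)
    else:
        mat = np.asarray(pssm_profile, dtype=float)
        if mat.shape != (WINDOW_LENGTH, 20):
            raise ValueError("pssm profile must be (16, 20)")
        squashed = 1.0 / (1.0 + np.exp(-mat))
        squashed[np.isnan(mat)] = 0.5
        vals = squashed.ravel()
    names = tuple(
        f"PSSM:{pos}:{a}" for pos in POSITION_LABELS for a in AA20
    )
    return FeatureBlock("PSSM", names, vals)


# ---------------------------------------------------------------------------
# full encoding


def encode_all(
    window: CleavageWindow | str,
    resources: EncodingResources | None = None,
    substrate: Substrate | None = None,
    schemes: Sequence[str] | None = None,
) -> FeatureBlock:
    """Concatenate the requested schemes (default: all eight, 4461 columns).

    ``substrate`` supplies the disorder/PSSM profiles for profile-based
    schemes; without it those blocks use their documented fill values.
    """
    resources = resources or EncodingResources()
    schemes = tuple(schemes) if schemes is not None else SCHEME_ORDER
    unknown = set(schemes) - set(SCHEME_ORDER)
    if unknown:
        raise ValueError(f"unknown schemes: {sorted(unknown)}")
    diso = pssm = None
    if substrate is not None and isinstance(window, CleavageWindow):
        diso, pssm = window_profile_slices(substrate, window)
    blocks = []
    for scheme in SCHEME_ORDER:
        if scheme not in schemes:
            continue
        if scheme == "AAindex":
            blocks.append(encode_aaindex(window, resources.aaindex))
        elif scheme == "AAPair":
            blocks.append(encode_aapair(window))
        elif scheme == "Binary":
            blocks.append(encode_binary(window))
        elif scheme == "BLOSUM":
            blocks.append(encode_blosum(window, resources.blosum))
        elif scheme == "CHARGE_Hyd":
            blocks.append(
                encode_charge_hyd(window, resources.charge, resources.hydropathy)
            )
        elif scheme == "CKSAAP":
            blocks.append(encode_cksaap(window, resources.k_values))
        elif scheme == "DISOPRED":
            blocks.append(encode_disopred(window, diso))
        elif scheme == "PSSM":
            blocks.append(encode_pssm(window, pssm))
    names = tuple(n for b in blocks for n in b.names)
    values = np.concatenate([b.values for b in blocks])
    return FeatureBlock("concat", names, values)


def encode_dataset(
    windows: Sequence[CleavageWindow],
    resources: EncodingResources | None = None,
    substrates: dict[str, Substrate] | None = None,
    schemes: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Encode a set of windows into a FeatureMatrix with +1/-1 labels."""
    resources = resources or EncodingResources()
    rows, names = [], None
    for w in windows:
        sub = substrates.get(w.substrate_id) if substrates else None
        block = encode_all(w, resources, substrate=sub, schemes=schemes)
        if names is None:
            names = list(block.names)
        rows.append(block.values)
    if names is None:
        raise ValueError("no windows to encode")
    return FeatureMatrix(
        row_ids=[w.row_id for w in windows],
        columns=names,
        data=np.vstack(rows),
        labels=np.array([w.y for w in windows]),
    )
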