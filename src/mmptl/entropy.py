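"""Per-position cleavage-entropy profiling of P8-P8' windows.

For each of the 16 window positions the Shannon entropy (bits) of the
residue distribution across all cleaved windows is computed:

    S_i = - sum_a p_a(i) * log2 p_a(i)

with plug-in frequencies over the 20 standard residues (pads excluded).
Low entropy at a position means the protease is stringent there; the
maximum, log2(20) ~ 4.32 bits, means no positional preference at all.
Because heat-map conventions differ, the inverted "specificity score"
log2(20) - S_i is also emitted, as is an optional normalized profile
S_i / log2(20).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_data import AA20, POSITION_LABELS, WINDOW_LENGTH, CleavageWindow

MAX_ENTROPY_BITS = float(np.log2(20))

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


@dataclass
class EntropyProfile:
    """Positional cleavage entropies of one protease's positive windows."""

    name: str
    entropy: np.ndarray  # 16 values, bits
    n_windows: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.entropy = np.asarray(self.entropy, dtype=float)
        if self.entropy.shape != (WINDOW_LENGTH,):
            raise ValueError("entropy profile must have 16 positions")

    @property
    def average(self) -> float:
        """Mean entropy over all 16 positions (the 'Avg' column)."""
        return float(self.entropy.mean())

    @property
    def specificity(self) -> np.ndarray:
        """Inverted profile log2(20) - S_i: high value = stringent position."""
        top = 1.0 if self.normalized else MAX_ENTROPY_BITS
        return top - self.entropy


def positional_counts(
    windows: Iterable[CleavageWindow | str],
) -> pd.DataFrame:
    """Residue counts per window position (rows AA20, columns P8..P8').

    Pads and non-standard residues are excluded.  This is the raw table
    behind the entropy profile and can be exported for sequence-logo
    plotting.
    """
    counts = np.zeros((20, WINDOW_LENGTH), dtype=int)
    n = 0
    for w in windows:
        seq = w.residues if isinstance(w, CleavageWindow) else w
        if len(seq) != WINDOW_LENGTH:
            raise ValueError("windows must have 16 residues")
        for i, a in enumerate(seq.upper()):
            if a in _AA_INDEX:
                counts[_AA_INDEX[a], i] += 1
        n += 1
    if n == 0:
        raise ValueError("at least one window is required")
    return pd.DataFrame(counts, index=list(AA20), columns=list(POSITION_LABELS))


def cleavage_entropy(
    positive_windows: Sequence[CleavageWindow | str],
    name: str = "",
    normalized: bool = False,
) -> EntropyProfile:
    """Shannon entropy (bits) of the residue distribution at each position.

    Only positive (cleaved) windows should be passed; pads are excluded
    per position.  ``normalized`` divides by log2(20) so values lie in
    [0, 1].
    """
    labeled = [w for w in positive_windows if isinstance(w, CleavageWindow)]
    if labeled and any(w.label != "positive" for w in labeled):
        raise ValueError("cleavage entropy is defined on positive windows only")
    counts = positional_counts(positive_windows).to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    entropy = np.zeros(WINDOW_LENGTH)
    for i in range(WINDOW_LENGTH):
        if totals[i] == 0:
            continue
        p = counts[:, i] / totals[i]
        p = p[p > 0]
        entropy[i] = -(p * np.log2(p)).sum()
    if normalized:
        entropy /= MAX_ENTROPY_BITS
    return EntropyProfile(
        name=name,
        entropy=entropy,
        n_windows=len(list(positive_windows)),
        normalized=normalized,
    )


def entropy_table(profiles: Sequence[EntropyProfile]) -> pd.DataFrame:
    """Heat-map data: one row per protease, 16 position columns plus Avg."""
    rows = {}
    for prof in profiles:
        rows[prof.name] = list(prof.entropy) + [prof.average]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(POSITION_LABELS) + ["Avg"]
    )


def export_entropy_table(
    profiles: Sequence[EntropyProfile], path: str | Path
) -> None:
    entropy_table(profiles).to_csv(path, sep="\t", index_label="protease")
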