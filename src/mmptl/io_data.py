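"""Substrate I/O, redundancy reduction, window extraction and negative sampling.

Substrates are protein sequences with 1-based cleavage-site annotations
(the P1 position of each scissile bond).  From every substrate a set of
16-residue windows (P8..P1 | P1'..P8') is extracted, one per peptide
bond; windows whose P1 position is annotated are positives, all others
are negative candidates.  Negative candidates are down-sampled to a 1:3
positive:negative ratio, preferring solvent-buried P1 residues when an
accessibility profile is available.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

PAD = "X"
#: the 20 standard residues, alphabetically by one-letter code
AA20 = "ACDEFGHIKLMNPQRSTVWY"
WINDOW_LENGTH = 16
#: slot labels P8..P1,P1'..P8' ("'" written as "p" so names stay file-safe)
POSITION_LABELS = tuple(f"P{8 - i}" for i in range(8)) + tuple(
    f"P{i + 1}p" for i in range(8)
)


@dataclass
class Substrate:
    """A substrate protein with cleavage annotations and optional profiles.

    ``cleavage_positions`` holds 1-based P1 indices: the scissile bond lies
    between residue ``p`` and residue ``p + 1``, so every position must
    satisfy ``1 <= p < len(sequence)``.  Optional per-residue profiles
    (accessibility class, disorder probability, PSSM log-odds in
    alphabetical residue order) must match the sequence length.
    """

    id: str
    sequence: str
    cleavage_positions: set[int] = field(default_factory=set)
    accessibility: Optional[str] = None  # 'b' (buried) / 'e' (exposed) per residue
    disorder: Optional[np.ndarray] = None  # probability in [0, 1] per residue
    pssm: Optional[np.ndarray] = None  # (L, 20) log-odds, columns in AA20 order

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for p in self.cleavage_positions:
            if not 1 <= p < n:
                raise ValueError(
                    f"substrate {self.id!r}: cleavage position {p} outside "
                    f"valid range 1..{n - 1}"
                )
        for name in ("accessibility", "disorder", "pssm"):
            prof = getattr(self, name)
            if prof is not None and len(prof) != n:
                raise ValueError(
                    f"substrate {self.id!r}: {name} profile length "
                    f"{len(prof)} != sequence length {n}"
                )


@dataclass(frozen=True)
class CleavageWindow:
    """A 16-residue window around one peptide bond.

    ``residues`` covers P8..P1 then P1'..P8'; the scissile bond sits between
    characters 8 and 9.  Positions that overrun a terminus are padded
    with ``'X'``.
    """

    substrate_id: str
    p1_position: int  # 1-based
    residues: str
    label: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_LENGTH:
            raise ValueError(
                f"window must have {WINDOW_LENGTH} residues, got "
                f"{len(self.residues)}"
            )
        if self.label not in ("positive", "negative"):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def row_id(self) -> str:
        return f"{self.substrate_id}:{self.p1_position}"

    @property
    def y(self) -> int:
        """Numeric label: +1 positive, -1 negative."""
        return 1 if self.label == "positive" else -1


@dataclass
class DomainDataset:
    """Labeled windows of one protease domain after negative sampling."""

    name: str
    windows: list[CleavageWindow]
    role: str = "source"  # "source" | "target"
    negative_shortage: bool = False

    @property
    def positives(self) -> list[CleavageWindow]:
        return [w for w in self.windows if w.label == "positive"]

    @property
    def negatives(self) -> list[CleavageWindow]:
        return [w for w in self.windows if w.label == "negative"]


# ---------------------------------------------------------------------------
# reading


def read_substrates(
    fasta_path: str | Path,
    annotation_path: str | Path,
    profile_dir: str | Path | None = None,
) -> list[Substrate]:
    """Read substrates from FASTA plus a cleavage-annotation TSV.

    The TSV has a header line ``substrate_id<TAB>p1_position`` and one row
    per cleavage site (1-based P1 index).  An annotation referencing an
    unknown sequence id, or a position outside ``1..L-1``, is a hard error.
    When ``profile_dir`` is given, files ``<id>.acc`` (NetSurfP-style
    accessibility), ``<id>.diso`` (DISOPRED-style disorder) and
    ``<id>.pssm`` (PSI-BLAST ASCII matrix) are attached when present.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    annotations: dict[str, set[int]] = {sid: set() for sid in records}
    with open(annotation_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and header[:1] and header[0] != "substrate_id":
            # headerless file: first line is data
            _consume_annotation_row(header, records, annotations)
        for row in reader:
            if row:
                _consume_annotation_row(row, records, annotations)

    substrates = []
    for sid, seq in records.items():
        acc = diso = pssm = None
        if profile_dir is not None:
            pdir = Path(profile_dir)
            acc_f = pdir / f"{sid}.acc"
            diso_f = pdir / f"{sid}.diso"
            pssm_f = pdir / f"{sid}.pssm"
            if acc_f.exists():
                acc = read_accessibility(acc_f)
            if diso_f.exists():
                diso = read_disorder(diso_f)
            if pssm_f.exists():
                pssm = read_pssm(pssm_f)
        substrates.append(
            Substrate(
                id=sid,
                sequence=seq,
                cleavage_positions=annotations[sid],
                accessibility=acc,
                disorder=diso,
                pssm=pssm,
            )
        )
    return substrates


def _consume_annotation_row(
    row: Sequence[str],
    records: dict[str, str],
    annotations: dict[str, set[int]],
) -> None:
    sid, pos_str = row[0].strip(), row[1].strip()
    if sid not in records:
        raise ValueError(f"annotation references unknown substrate id {sid!r}")
    pos = int(pos_str)
    if not 1 <= pos < len(records[sid]):
        raise ValueError(
            f"annotation for {sid!r}: P1 position {pos} outside valid "
            f"range 1..{len(records[sid]) - 1}"
        )
    annotations[sid].add(pos)


def read_accessibility(path: str | Path) -> str:
    """Parse a NetSurfP-style table into a per-residue 'b'/'e' string.

    Comment lines start with '#'; the class is the first whitespace field
    of each data row (case-insensitive B/E).
    """
    flags = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cls = line.split()[0].lower()
            if cls not in ("b", "e"):
                raise ValueError(f"{path}: bad accessibility class {cls!r}")
            flags.append(cls)
    return "".join(flags)


def read_disorder(path: str | Path) -> np.ndarray:
    """Parse a DISOPRED-style file: columns pos, residue, '*'/'.', probability."""
    probs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            probs.append(float(fields[3]))
    return np.asarray(probs, dtype=float)


# PSI-BLAST prints PSSM columns in this residue order
_PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def read_pssm(path: str | Path) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM; returns (L, 20) log-odds in AA20 order.

    The first 20 score columns are used; the residue order is taken from
    the header line of single-letter codes (PSI-BLAST's default order is
    A R N D C Q E G H I L K M F P S T W Y V).
    """
    order = _PSIBLAST_ORDER
    rows = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if all(f.isalpha() and len(f) == 1 for f in fields) and len(fields) >= 20:
                order = "".join(fields[:20])
                continue
            if fields[0].isdigit() and len(fields) >= 22:
                rows.append([int(x) for x in fields[2:22]])
    mat = np.asarray(rows, dtype=float)
    # reorder columns to alphabetical AA20
    perm = [order.index(a) for a in AA20]
    return mat[:, perm]


# ---------------------------------------------------------------------------
# redundancy reduction


def _identity(aligner: PairwiseAligner, a: str, b: str) -> float:
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / aln.length


def reduce_redundancy(
    substrates: Sequence[Substrate],
    identity_threshold: float = 0.70,
) -> list[Substrate]:
    """Greedy longest-first clustering at a global-identity threshold.

    Sequences are sorted by decreasing length (ties by id) and each is
    compared against the representatives kept so far; a sequence whose
    identity with any representative reaches the threshold joins that
    cluster, otherwise it becomes a new representative.  Identity is
    matches / alignment length of a global alignment scored match=1,
    mismatch=0, gap=-1.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    aligner = PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    ordered = sorted(substrates, key=lambda s: (-len(s.sequence), s.id))
    reps: list[Substrate] = []
    for sub in ordered:
        if not any(
            _identity(aligner, sub.sequence, rep.sequence) >= identity_threshold
            for rep in reps
        ):
            reps.append(sub)
    original = {s.id: i for i, s in enumerate(substrates)}
    reps.sort(key=lambda s: original[s.id])
    return reps


# ---------------------------------------------------------------------------
# window extraction


def extract_windows(
    substrate: Substrate, window_length: int = WINDOW_LENGTH
) -> list[CleavageWindow]:
    """One window per peptide bond; termini padded with 'X'.

    The P1 position runs over ``1..L-1``.  A window's first half ends at
    P1 and its second half starts at P1', so with ``window_length == 16``
    the 0-based slice is ``[p1-8, p1+8)``.
    """
    if window_length % 2 != 0:
        raise ValueError("window_length must be even")
    half = window_length // 2
    seq = substrate.sequence
    n = len(seq)
    windows = []
    for p1 in range(1, n):
        start = p1 - half
        chars = [
            seq[j] if 0 <= j < n else PAD for j in range(start, start + window_length)
        ]
        label = "positive" if p1 in substrate.cleavage_positions else "negative"
        windows.append(
            CleavageWindow(
                substrate_id=substrate.id,
                p1_position=p1,
                residues="".join(chars),
                label=label,
            )
        )
    return windows


def window_profile_slices(
    substrate: Substrate, window: CleavageWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Align a substrate's disorder and PSSM profiles to one window.

    Returns ``(disorder16, pssm16x20)`` with NaN at pad slots or when the
    corresponding profile is absent; encoders impute NaN with their
    documented fill value.
    """
    half = WINDOW_LENGTH // 2
    start = window.p1_position - half
    n = len(substrate.sequence)
    diso = np.full(WINDOW_LENGTH, np.nan)
    pssm = np.full((WINDOW_LENGTH, 20), np.nan)
    for slot in range(WINDOW_LENGTH):
        j = start + slot
        if 0 <= j < n:
            if substrate.disorder is not None:
                diso[slot] = substrate.disorder[j]
            if substrate.pssm is not None:
                pssm[slot] = substrate.pssm[j]
    return diso, pssm


# ---------------------------------------------------------------------------
# negative sampling


def sample_negatives(
    windows: Iterable[CleavageWindow],
    ratio: int = 3,
    seed: int = 0,
    name: str = "dataset",
    role: str = "source",
    accessibility: dict[str, str] | None = None,
    buried_weight: float = 3.0,
    exposed_weight: float = 1.0,
) -> DomainDataset:
    """Keep all positives and draw ``ratio`` negatives per positive.

    Candidates whose P1 residue is solvent-buried ('b' in the substrate's
    accessibility profile, passed as ``{substrate_id: flags}``) are drawn
    with ``buried_weight : exposed_weight`` preference (3:1 by default);
    without profiles the draw is uniform.  Sampling is without replacement
    and deterministic given ``seed``.  When fewer than ``ratio x positives``
    candidates exist, all are kept and the dataset is flagged.
    """
    windows = list(windows)
    positives = [w for w in windows if w.label == "positive"]
    candidates = [w for w in windows if w.label == "negative"]
    wanted = ratio * len(positives)
    rng = np.random.default_rng(seed)
    shortage = len(candidates) < wanted
    if shortage:
        chosen = candidates
        warnings.warn(
            f"{name}: only {len(candidates)} negative candidates for "
            f"{len(positives)} positives (wanted {wanted})",
            stacklevel=2,
        )
    else:
        weights = np.ones(len(candidates))
        if accessibility:
            for i, w in enumerate(candidates):
                flags = accessibility.get(w.substrate_id)
                if flags is not None:
                    flag = flags[w.p1_position - 1]
                    weights[i] = buried_weight if flag == "b" else exposed_weight
        idx = rng.choice(
            len(candidates), size=wanted, replace=False, p=weights / weights.sum()
        )
        chosen = [candidates[i] for i in sorted(idx)]
    return DomainDataset(
        name=name,
        windows=positives + chosen,
        role=role,
        negative_shortage=shortage,
    )


def build_domain_dataset(
    substrates: Sequence[Substrate],
    name: str,
    role: str = "source",
    ratio: int = 3,
    seed: int = 0,
    identity_threshold: float | None = 0.70,
    buried_weight: float = 3.0,
) -> DomainDataset:
    """Full preprocessing for one protease: redundancy reduction, window
    extraction and 1:3 negative sampling."""
    if identity_threshold is not None:
        substrates = reduce_redundancy(substrates, identity_threshold)
    windows: list[CleavageWindow] = []
    for sub in substrates:
        windows.extend(extract_windows(sub))
    accessibility = {
        s.id: s.accessibility for s in substrates if s.accessibility is not None
    }
    return sample_negatives(
        windows,
        ratio=ratio,
        seed=seed,
        name=name,
        role=role,
        accessibility=accessibility or None,
        buried_weight=buried_weight,
    )
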