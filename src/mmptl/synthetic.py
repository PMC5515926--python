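"""Seeded generator of synthetic substrate domains with planted motifs.

Stands in for curated protease-substrate data in all tests and demos.
Each scenario has several "source" protease domains and one "target"
domain.  Substrate sequences are drawn from a background distribution;
at each planted cleavage site the 16-residue window is overwritten by a
per-position mixture

    strength * preference(position) + (1 - strength) * background,

so planted effect sizes are analytically checkable.  A shared motif
(present in every domain) mimics the preferences observed around real
MMP cleavage sites — glycine enriched at P7, P4, P1, P3', P6', proline
at P3 and P5', leucine at P1' — while each domain additionally carries
two private preferred positions, giving the transfer pipeline genuinely
shared and domain-specific signal to separate.

What the generator does NOT emulate: real substrate homology structure
(sequences are i.i.d.), evolutionary conservation (synthetic PSSMs are
pseudo-counts derived from the planted mixture, flagged as such), and
the natural residue background of curated substrate databases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_data import (
    AA20,
    WINDOW_LENGTH,
    CleavageWindow,
    DomainDataset,
    Substrate,
    build_domain_dataset,
    extract_windows,
)

_AA_INDEX = {a: i for i, a in enumerate(AA20)}

#: window-slot index of each named position, P8..P1 then P1'..P8'
POSITION_SLOT = {f"P{8 - i}": i for i in range(8)}
POSITION_SLOT.update({f"P{i + 1}p": 8 + i for i in range(8)})

#: shared residue preferences mimicking MMP cleavage-site logos
SHARED_PREFERENCES = {
    "P7": {"G": 1.0},
    "P4": {"G": 1.0},
    "P1": {"G": 1.0},
    "P3p": {"G": 1.0},
    "P6p": {"G": 1.0},
    "P3": {"P": 1.0},
    "P5p": {"P": 1.0},
    "P1p": {"L": 1.0},
}


@dataclass
class MotifSpec:
    """Per-position residue preferences mixed against a background.

    ``preferences`` maps a position label (P8..P8') to residue weights.
    Weights summing to at most 1 leave their remainder spread uniformly
    over the unlisted residues (so ``{"G": 0.5}`` means half the
    preference mass on glycine); weights summing to more than 1 are
    normalized.  At sampling time the effective distribution is
    ``strength * preference + (1 - strength) * background``; positions
    absent from the map sample from the pure background.
    """

    preferences: dict[str, dict[str, float]] = field(default_factory=dict)
    background: Optional[np.ndarray] = None  # length 20 over AA20; uniform if None
    strength: float = 0.6

    def __post_init__(self) -> None:
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must lie in [0, 1]")
        for pos in self.preferences:
            if pos not in POSITION_SLOT:
                raise ValueError(f"unknown position label {pos!r}")
        if self.background is None:
            self.background = np.full(20, 1 / 20)
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    def position_distribution(self, pos: str) -> np.ndarray:
        """Effective residue distribution at one window position."""
        if pos not in self.preferences:
            return self.background
        pref = np.zeros(20)
        for a, w in self.preferences[pos].items():
            pref[_AA_INDEX[a]] = w
        total = pref.sum()
        if total > 1:
            pref /= total
        else:
            unlisted = pref == 0
            if unlisted.any():
                pref[unlisted] = (1 - total) / unlisted.sum()
        return self.strength * pref + (1 - self.strength) * self.background

    def merged_with(self, other: "MotifSpec") -> "MotifSpec":
        """Overlay another motif's preferences (other wins on clashes)."""
        prefs = {k: dict(v) for k, v in self.preferences.items()}
        prefs.update({k: dict(v) for k, v in other.preferences.items()})
        return MotifSpec(
            preferences=prefs, background=self.background, strength=self.strength
        )


@dataclass
class ScenarioSpec:
    """Full description of a synthetic multi-domain experiment."""

    n_source_domains: int = 5
    substrates_per_domain: tuple[int, int] = (23, 44)  # inclusive range
    sites_per_domain: tuple[int, int] = (85, 290)  # inclusive range
    substrate_length: tuple[int, int] = (150, 400)  # inclusive range
    shared_motif: MotifSpec = field(
        default_factory=lambda: MotifSpec(
            preferences={k: dict(v) for k, v in SHARED_PREFERENCES.items()}
        )
    )
    n_private_positions: int = 2
    seed: int = 0

    @property
    def domain_names(self) -> list[str]:
        return [f"SRC{i + 1}" for i in range(self.n_source_domains)] + ["TGT"]


@dataclass
class SyntheticScenario:
    """Generated substrates plus ground truth about the planted signal."""

    spec: ScenarioSpec
    substrates: dict[str, list[Substrate]]  # domain -> substrates
    motifs: dict[str, MotifSpec]  # effective (shared + private) motif per domain
    truth: dict

    @property
    def source_names(self) -> list[str]:
        return [n for n in self.substrates if n != "TGT"]

    def domain_datasets(
        self, ratio: int = 3, seed: int = 0, identity_threshold: float | None = None
    ) -> dict[str, DomainDataset]:
        """Preprocess every domain through the standard pipeline.

        Redundancy reduction is skipped by default: synthetic substrates
        are i.i.d. background draws, so no pair reaches real-world
        identity thresholds.
        """
        out = {}
        for i, (name, subs) in enumerate(self.substrates.items()):
            out[name] = build_domain_dataset(
                subs,
                name=name,
                role="target" if name == "TGT" else "source",
                ratio=ratio,
                seed=seed + i,
                identity_threshold=identity_threshold,
            )
        return out

    def write(self, out_dir: str | Path) -> None:
        """Write per-domain FASTA + annotation TSV, a manifest and the truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"domains": []}
        for name, subs in self.substrates.items():
            write_fasta(subs, out / f"{name}.fasta")
            write_annotations(subs, out / f"{name}.tsv")
            manifest["domains"].append(
                {
                    "name": name,
                    "role": "target" if name == "TGT" else "source",
                    "fasta": f"{name}.fasta",
                    "annotations": f"{name}.tsv",
                }
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2))


def write_fasta(substrates: Sequence[Substrate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in substrates:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), 60):
                fh.write(s.sequence[i : i + 60] + "\n")


def write_annotations(substrates: Sequence[Substrate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("substrate_id\tp1_position\n")
        for s in substrates:
            for p in sorted(s.cleavage_positions):
                fh.write(f"{s.id}\t{p}\n")


def _draw_sequence(rng: np.random.Generator, length: int, background: np.ndarray) -> list[str]:
    idx = rng.choice(20, size=length, p=background)
    return [AA20[i] for i in idx]


def _place_sites(
    rng: np.random.Generator, length: int, n_sites: int, min_gap: int = WINDOW_LENGTH
) -> list[int]:
    """Pick ``n_sites`` P1 positions with full windows inside the sequence
    and pairwise separation >= min_gap.

    Uses the gap-removal bijection: draw sorted distinct offsets from the
    compressed range, then re-insert ``min_gap - 1`` spacers, which makes
    every admissible configuration reachable.
    """
    half = WINDOW_LENGTH // 2
    lo, hi = half, length - half
    span = hi - lo + 1
    compressed = span - (n_sites - 1) * (min_gap - 1)
    if n_sites < 1 or compressed < n_sites:
        raise ValueError(
            f"cannot place {n_sites} cleavage sites in a sequence of "
            f"length {length} with gap {min_gap}"
        )
    offsets = np.sort(rng.choice(compressed, size=n_sites, replace=False))
    return [int(lo + u + i * (min_gap - 1)) for i, u in enumerate(offsets)]


def _overwrite_window(
    seq: list[str], p1: int, motif: MotifSpec, rng: np.random.Generator
) -> None:
    start = p1 - WINDOW_LENGTH // 2  # 0-based index of the P8 slot
    for pos, slot in POSITION_SLOT.items():
        dist = motif.position_distribution(pos)
        seq[start + slot] = AA20[rng.choice(20, p=dist)]


def _site_capacity(length: int, min_gap: int = WINDOW_LENGTH) -> int:
    span = length - WINDOW_LENGTH + 1
    if span < 1:
        return 0
    return 1 + (span - 1) // min_gap


def generate_scenario(spec: ScenarioSpec) -> SyntheticScenario:
    """Generate all domains of a scenario, fully deterministic given the seed.

    Returns the substrates per domain, the effective motif of each domain,
    and a truth record with the planted sites, the shared/private motif
    positions, and the one-hot ("Binary") feature columns that carry the
    shared signal.
    """
    rng = np.random.default_rng(spec.seed)
    substrates: dict[str, list[Substrate]] = {}
    motifs: dict[str, MotifSpec] = {}
    truth_domains: dict[str, dict] = {}
    shared = spec.shared_motif
    private_candidates = [p for p in POSITION_SLOT if p not in shared.preferences]
    # residues distinctive enough to act as private signal
    private_residues = [a for a in AA20 if a not in "GPL"]

    for name in spec.domain_names:
        private_pos = list(
            rng.choice(private_candidates, size=spec.n_private_positions, replace=False)
        )
        private_res = list(
            rng.choice(private_residues, size=spec.n_private_positions, replace=False)
        )
        private = MotifSpec(
            preferences={p: {r: 1.0} for p, r in zip(private_pos, private_res)},
            background=shared.background,
            strength=shared.strength,
        )
        motif = shared.merged_with(private)
        motifs[name] = motif

        n_sub = int(rng.integers(spec.substrates_per_domain[0], spec.substrates_per_domain[1] + 1))
        lengths = [
            int(rng.integers(spec.substrate_length[0], spec.substrate_length[1] + 1))
            for _ in range(n_sub)
        ]
        capacities = [_site_capacity(l) for l in lengths]
        lo = max(spec.sites_per_domain[0], n_sub)  # at least one site each
        hi = min(spec.sites_per_domain[1], sum(capacities))
        if lo > hi:
            raise ValueError("site budget incompatible with substrate capacities")
        n_sites_total = int(rng.integers(lo, hi + 1))
        # distribute: one site per substrate, then spread the remainder
        sites_per_sub = [1] * n_sub
        remaining = n_sites_total - n_sub
        while remaining > 0:
            j = int(rng.integers(n_sub))
            if sites_per_sub[j] < capacities[j]:
                sites_per_sub[j] += 1
                remaining -= 1

        subs = []
        site_truth = {}
        for j in range(n_sub):
            sid = f"{name}_S{j + 1:03d}"
            seq = _draw_sequence(rng, lengths[j], shared.background)
            positions = _place_sites(rng, lengths[j], sites_per_sub[j])
            for p1 in positions:
                _overwrite_window(seq, p1, motif, rng)
            subs.append(
                Substrate(
                    id=sid, sequence="".join(seq), cleavage_positions=set(positions)
                )
            )
            site_truth[sid] = positions
        substrates[name] = subs
        truth_domains[name] = {
            "n_substrates": n_sub,
            "n_sites": n_sites_total,
            "private_positions": {p: r for p, r in zip(private_pos, private_res)},
            "sites": site_truth,
        }

    shared_desc = {
        pos: max(w, key=w.get) for pos, w in shared.preferences.items()
    }
    truth = {
        "seed": spec.seed,
        "strength": shared.strength,
        "shared_positions": shared_desc,
        "shared_binary_columns": [
            f"Binary:{pos}:{res}" for pos, res in shared_desc.items()
        ],
        "domains": truth_domains,
    }
    return SyntheticScenario(spec=spec, substrates=substrates, motifs=motifs, truth=truth)


def default_mmp_like_spec(seed: int = 0, strength: float = 0.6) -> ScenarioSpec:
    """Five source domains plus one target at curated-dataset scale.

    Per-domain sizes are drawn within the ranges typical of curated MMP
    substrate sets (23-44 substrates, 85-290 cleavage sites); the shared
    motif follows the consensus cleavage preferences (G at P7/P4/P1/P3'/
    P6', P at P3/P5', L at P1') and every domain adds two private
    preferred positions.
    """
    return ScenarioSpec(
        n_source_domains=5,
        shared_motif=MotifSpec(
            preferences={k: dict(v) for k, v in SHARED_PREFERENCES.items()},
            strength=strength,
        ),
        seed=seed,
    )


def attach_synthetic_profiles(
    scenario: SyntheticScenario, seed: int = 0
) -> None:
    """Attach synthetic accessibility/disorder/PSSM profiles in place.

    These are stand-ins for predictor outputs: accessibility is an i.i.d.
    buried/exposed coin, disorder an i.i.d. uniform probability, and the
    PSSM a pseudo-count log-odds matrix that scores each planted window
    column by its mixture distribution (log2(p/background), doubled and
    rounded, the usual half-bit convention) and background columns as 0.
    """
    rng = np.random.default_rng(seed)
    for name, subs in scenario.substrates.items():
        motif = scenario.motifs[name]
        for sub in subs:
            n = len(sub.sequence)
            sub.accessibility = "".join(
                "b" if rng.random() < 0.5 else "e" for _ in range(n)
            )
            sub.disorder = rng.random(n)
            pssm = np.zeros((n, 20))
            for p1 in sub.cleavage_positions:
                start = p1 - WINDOW_LENGTH // 2
                for pos, slot in POSITION_SLOT.items():
                    dist = motif.position_distribution(pos)
                    with np.errstate(divide="ignore"):
                        scores = 2.0 * np.log2(dist / motif.background)
                    scores[np.isneginf(scores)] = -8.0
                    pssm[start + slot] = np.round(scores)
            sub.pssm = pssm
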