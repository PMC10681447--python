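"""Labeled synthetic peptides for end-to-end testing without downloads.

Positives are built on the helical-wheel geometry itself: with 100° per
residue, positions whose wheel angle falls inside a 160° arc get hydrophobic
residues (Leu-weighted, with Ile/Phe) and the opposite face gets
lysine/arginine interleaved with alanine, yielding a cationic amphipathic
helix former by construction. The generator then verifies its own guarantees
(uH ≥ 0.4, NCPR ≥ 0.1) with the package's calculators, redrawing
deterministically if a draw falls short.

Negative kinds each break one named criterion: ``short`` (< 18 residues),
``acidic`` (D/E face, NCPR < 0), ``scrambled`` (a permuted positive,
re-permuted until amphipathicity is destroyed) and ``low_uh`` (strict
hydrophobic/charged alternation, no face segregation). For ``scrambled``
and ``low_uh`` the rejection test requires *every* 18-residue window to fall
below the uH threshold — this bounds the windowed-mean moment of every
admissible substring, so the sliding-window region search cannot resurrect
the peptide either.

All randomness is owned by seeded generators; identical specs produce
identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .peptide_io import PeptideRecord, write_fasta
from .physchem import DEFAULT_SCALE, charge_profile, mean_windowed_moment


def _max_window_moment(h: np.ndarray, window: int = 18) -> float:
    """Largest per-residue moment over all helix windows (whole seq if shorter)."""
    n = len(h)
    phase = np.exp(1j * np.deg2rad(100.0) * np.arange(n))
    c = np.concatenate(([0.0 + 0.0j], np.cumsum(h * phase)))
    w = min(window, n)
    sums = c[w:] - c[:-w]
    return float(np.abs(sums).max() / w)

NEGATIVE_KINDS = ("short", "acidic", "scrambled", "low_uh")

#: Wheel arc (degrees either side of 0°) receiving hydrophobic residues.
HYDRO_ARC_HALF = 80.0

_HYDRO_CHOICES = ["L", "L", "L", "I", "F"]
_CATIONIC_CHOICES = ["K", "R"]


@dataclass
class SyntheticSpec:
    """Recipe for a labeled synthetic dataset."""

    n_positive: int = 100
    n_negative: int = 100
    length_range: tuple[int, int] = (18, 54)
    seed: int = 0
    negative_kinds: tuple[str, ...] = NEGATIVE_KINDS

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.length_range
        if not 1 <= lo <= hi <= 200:
            raise ValueError("length_range must lie within [1, 200]")
        unknown = set(self.negative_kinds) - set(NEGATIVE_KINDS)
        if unknown:
            raise ValueError(f"unknown negative kinds: {sorted(unknown)}")


def _face_sequence(length: int, rng: np.random.Generator,
                   charged_choices: list[str]) -> str:
    """Place hydrophobics in the wheel arc, charged/Ala on the other face."""
    seq = []
    for n in range(length):
        angle = (n * 100.0) % 360.0
        on_hydrophobic_face = angle <= HYDRO_ARC_HALF or angle >= 360.0 - HYDRO_ARC_HALF
        if on_hydrophobic_face:
            seq.append(_HYDRO_CHOICES[rng.integers(len(_HYDRO_CHOICES))])
        elif rng.random() < 0.6:
            seq.append(charged_choices[rng.integers(len(charged_choices))])
        else:
            seq.append("A")
    return "".join(seq)


def generate_positive(length: int, seed: int, len_min: int = 18, len_max: int = 54) -> PeptideRecord:
    """A cationic amphipathic helix former of the given length.

    Deterministic per (length, seed); guarantees uH ≥ 0.4 and NCPR ≥ 0.1 by
    redrawing until the package's own calculators confirm them.
    """
    if not len_min <= length <= len_max:
        raise ValueError(f"positive length must lie in [{len_min}, {len_max}]")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        seq = _face_sequence(length, rng, _CATIONIC_CHOICES)
        if mean_windowed_moment(seq) >= 0.4 and charge_profile(seq).ncpr >= 0.1:
            return PeptideRecord(id=f"pos_seed{seed}", sequence=seq, source="synthetic")
    raise RuntimeError("positive construction failed to meet guarantees")  # pragma: no cover


def generate_negative(kind: str, length: int, seed: int) -> PeptideRecord:
    """A peptide failing at least the criterion named by its kind."""
    if kind not in NEGATIVE_KINDS:
        raise ValueError(f"unknown negative kind {kind!r}")
    rng = np.random.default_rng(seed)
    if kind == "short":
        short_len = int(length) if length < 18 else int(rng.integers(5, 18))
        seq = _face_sequence(short_len, rng, _CATIONIC_CHOICES)
        return PeptideRecord(id=f"neg_short_seed{seed}", sequence=seq, source="synthetic")
    if kind == "acidic":
        for _ in range(1000):
            seq = _face_sequence(length, rng, ["D", "E"])
            if charge_profile(seq).ncpr < 0.0:
                return PeptideRecord(id=f"neg_acidic_seed{seed}", sequence=seq,
                                     source="synthetic")
        raise RuntimeError("acidic construction failed")  # pragma: no cover
    values = DEFAULT_SCALE.values
    if kind == "scrambled":
        letters = np.array(list(generate_positive(length, seed).sequence))
        h = np.array([values[a] for a in letters])
        for _ in range(200_000):
            idx = rng.permutation(length)
            if _max_window_moment(h[idx]) < 0.2:
                return PeptideRecord(id=f"neg_scrambled_seed{seed}",
                                     sequence="".join(letters[idx]), source="synthetic")
        raise RuntimeError("scrambling never destroyed amphipathicity")  # pragma: no cover
    # low_uh: strict alternation of hydrophobic and charged residues spreads
    # hydrophobicity evenly around the wheel.
    for _ in range(10_000):
        seq = "".join(
            _HYDRO_CHOICES[rng.integers(len(_HYDRO_CHOICES))] if n % 2 == 0
            else _CATIONIC_CHOICES[rng.integers(len(_CATIONIC_CHOICES))]
            for n in range(length)
        )
        if _max_window_moment(np.array([values[a] for a in seq])) < 0.2:
            return PeptideRecord(id=f"neg_low_uh_seed{seed}", sequence=seq,
                                 source="synthetic")
    raise RuntimeError("alternation construction failed")  # pragma: no cover


def generate_dataset(spec: SyntheticSpec) -> tuple[list[PeptideRecord], pd.DataFrame]:
    """Records plus a labels table (id, label, kind), reproducible per spec."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    lo_pos = max(lo, 18)
    records: list[PeptideRecord] = []
    labels = []
    for i in range(spec.n_positive):
        length = int(rng.integers(lo_pos, min(hi, 54) + 1))
        child = int(rng.integers(0, 2**31 - 1))
        rec = generate_positive(length, child)
        rec.id = f"pos_{i + 1:04d}"
        records.append(rec)
        labels.append({"id": rec.id, "label": "positive", "kind": "positive"})
    for i in range(spec.n_negative):
        kind = spec.negative_kinds[i % len(spec.negative_kinds)]
        length = int(rng.integers(lo_pos, min(hi, 54) + 1))
        child = int(rng.integers(0, 2**31 - 1))
        rec = generate_negative(kind, length, child)
        rec.id = f"neg_{i + 1:04d}"
        records.append(rec)
        labels.append({"id": rec.id, "label": "negative", "kind": kind})
    return records, pd.DataFrame(labels, columns=["id", "label", "kind"])


def write_dataset(records: list[PeptideRecord], labels: pd.DataFrame,
                  out_prefix: str | Path) -> tuple[Path, Path]:
    """Emit FASTA + labels TSV next to each other; returns the two paths."""
    out_prefix = Path(out_prefix)
    fasta = out_prefix.with_suffix(".fasta")
    tsv = out_prefix.with_suffix(".labels.tsv")
    write_fasta(records, fasta)
    labels.to_csv(tsv, sep="\t", index=False)
    return fasta, tsv


__all__ = [
    "NEGATIVE_KINDS", "SyntheticSpec", "generate_positive",
    "generate_negative", "generate_dataset", "write_dataset",
]
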