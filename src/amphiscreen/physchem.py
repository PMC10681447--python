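"""Hydrophobic dipole moment and Henderson–Hasselbalch charge calculations.

The hydrophobic dipole moment (uH) quantifies amphipathicity: per-residue
hydrophobicities are placed as vectors at 100° increments around the helical
axis and summed; a large resultant means hydrophobic residues cluster on one
helix face. The net charge per residue (NCPR) averages fractional
Henderson–Hasselbalch charges of all ionizable groups (side chains plus free
termini) over the sequence length.

Two moment statistics are provided. :func:`hydrophobic_moment` is the classic
closed-form per-residue moment of a whole sequence. The screening statistic,
:func:`mean_windowed_moment`, averages the moment over every 18-residue helix
window (one full window for shorter peptides), so that long peptides are
judged by the amphipathicity of helix-sized stretches rather than diluted by
their full length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

from .peptide_io import CANONICAL_AA, PeptideRecord


@dataclass
class HydrophobicityScale:
    """Per-residue hydrophobicity values plus the helical rotation angle."""

    name: str
    values: Mapping[str, float]
    delta_deg: float = 100.0

    def __post_init__(self) -> None:
        missing = CANONICAL_AA - set(self.values)
        if missing:
            raise ValueError(f"scale '{self.name}' missing residues: {sorted(missing)}")
        if not 0.0 < self.delta_deg < 360.0:
            raise ValueError("delta_deg must lie in (0, 360)")


#: Fauchère–Pliska octanol/water side-chain transfer free energies.
#: The package default: calibrated so that the windowed moment reproduces the
#: reference amphipathicity values of the case-study peptides.
FAUCHERE_PLISKA = HydrophobicityScale(
    "fauchere_pliska",
    {
        "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
        "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
        "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
        "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
    },
)

#: Eisenberg normalized consensus scale, provided as an alternative.
EISENBERG_CONSENSUS = HydrophobicityScale(
    "eisenberg_consensus",
    {
        "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
        "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
        "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
        "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    },
)

DEFAULT_SCALE = FAUCHERE_PLISKA


def _as_sequence(peptide: Union[str, PeptideRecord]) -> str:
    return peptide.sequence if isinstance(peptide, PeptideRecord) else peptide


def hydrophobic_moment(
    peptide: Union[str, PeptideRecord],
    scale: HydrophobicityScale = DEFAULT_SCALE,
) -> float:
    """Per-residue hydrophobic dipole moment of the whole sequence.

    Computes ``(1/N) * |sum_n H_n exp(i delta n)|`` with ``n = 0..N-1`` and
    ``delta`` the helical rotation per residue (100° for an ideal α-helix).
    Always ≥ 0.
    """
    seq = _as_sequence(peptide)
    if not seq:
        raise ValueError("sequence must be non-empty")
    try:
        h = np.array([scale.values[aa] for aa in seq], dtype=float)
    except KeyError as exc:
        raise KeyError(f"residue {exc} absent from scale '{scale.name}'") from None
    delta = math.radians(scale.delta_deg)
    angles = delta * np.arange(len(seq))
    return float(np.hypot((h * np.sin(angles)).sum(), (h * np.cos(angles)).sum()) / len(seq))


def mean_windowed_moment(
    peptide: Union[str, PeptideRecord],
    scale: HydrophobicityScale = DEFAULT_SCALE,
    window: int = 18,
) -> float:
    """Hydrophobic moment averaged over all helix-sized windows.

    For sequences of length ≤ ``window`` this equals
    :func:`hydrophobic_moment`; otherwise it is the mean of the moment over
    every contiguous window of ``window`` residues. This is the
    amphipathicity statistic used by the screening decision rule.
    """
    seq = _as_sequence(peptide)
    if len(seq) <= window:
        return hydrophobic_moment(seq, scale)
    vals = [hydrophobic_moment(seq[i : i + window], scale) for i in range(len(seq) - window + 1)]
    return float(np.mean(vals))


# --- charges -----------------------------------------------------------

BASIC_GROUPS = frozenset({"H", "K", "R", "N_term"})
ACIDIC_GROUPS = frozenset({"D", "E", "C", "Y", "C_term"})

#: Standard textbook pKa values for the ionizable groups.
DEFAULT_PKA: dict[str, float] = {
    "D": 3.65, "E": 4.25, "C": 8.30, "Y": 10.07, "H": 6.00,
    "K": 10.53, "R": 12.48, "N_term": 9.00, "C_term": 3.10,
}


@dataclass
class ChargeModel:
    """pKa table plus the pH at which fractional charges are evaluated."""

    pka: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    pH: float = 7.0

    def __post_init__(self) -> None:
        missing = (BASIC_GROUPS | ACIDIC_GROUPS) - set(self.pka)
        if missing:
            raise ValueError(f"pKa table missing groups: {sorted(missing)}")
        bad = {g: v for g, v in self.pka.items() if not 0.0 < v < 14.0}
        if bad:
            raise ValueError(f"pKa values outside (0, 14): {bad}")


@dataclass
class ChargeProfile:
    """Fractional charges of a peptide and their per-residue average."""

    per_residue: list[float]
    terminal_n: float
    terminal_c: float
    net: float
    ncpr: float


def fractional_charge(group: str, model: ChargeModel) -> float:
    """Henderson–Hasselbalch fractional charge of one ionizable group.

    Basic groups carry ``+1/(1+10^(pH-pKa))``, acidic groups
    ``-1/(1+10^(pKa-pH))``; at pH = pKa the magnitude is exactly 0.5.
    """
    try:
        pka = model.pka[group]
    except KeyError:
        raise KeyError(f"unknown ionizable group {group!r}") from None
    if group in BASIC_GROUPS:
        return 1.0 / (1.0 + 10.0 ** (model.pH - pka))
    if group in ACIDIC_GROUPS:
        return -1.0 / (1.0 + 10.0 ** (pka - model.pH))
    raise KeyError(f"unknown ionizable group {group!r}")


def charge_profile(
    record: Union[str, PeptideRecord],
    model: Optional[ChargeModel] = None,
) -> ChargeProfile:
    """Net charge and NCPR of a peptide at the model's pH.

    Side chains of D/E/C/Y (acidic) and H/K/R (basic) contribute fractional
    charges; the free N- and C-termini contribute as well unless the
    corresponding protection flag is set (acetylation/amidation). The NCPR
    denominator is the residue count; terminal groups add charge, not length.
    """
    model = model or ChargeModel()
    if isinstance(record, str):
        record = PeptideRecord(id="<anonymous>", sequence=record)
    if not record.sequence:
        raise ValueError("sequence must be non-empty")
    per_residue = [
        fractional_charge(aa, model) if aa in model.pka else 0.0
        for aa in record.sequence
    ]
    term_n = 0.0 if record.n_term_protected else fractional_charge("N_term", model)
    term_c = 0.0 if record.c_term_protected else fractional_charge("C_term", model)
    net = sum(per_residue) + term_n + term_c
    return ChargeProfile(per_residue, term_n, term_c, net, net / len(record.sequence))


def load_scale(path) -> HydrophobicityScale:
    """Load a hydrophobicity scale from a plain ``key value`` file.

    One ``RESIDUE value`` pair per line; optional ``delta_deg`` and ``name``
    keys; ``#`` starts a comment.
    """
    values: dict[str, float] = {}
    delta = 100.0
    name = "custom"
    for line in open(path):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, val = line.split(None, 1)
        if key == "delta_deg":
            delta = float(val)
        elif key == "name":
            name = val.strip()
        else:
            values[key.upper()] = float(val)
    return HydrophobicityScale(name, values, delta)


def load_pka(path) -> dict[str, float]:
    """Load a pKa table (``GROUP value`` pairs) from a plain key-value file."""
    pka = dict(DEFAULT_PKA)
    for line in open(path):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, val = line.split(None, 1)
        pka[key] = float(val)
    return pka


__all__ = [
    "HydrophobicityScale", "FAUCHERE_PLISKA", "EISENBERG_CONSENSUS",
    "DEFAULT_SCALE", "hydrophobic_moment", "mean_windowed_moment",
    "ChargeModel", "ChargeProfile", "DEFAULT_PKA", "BASIC_GROUPS",
    "ACIDIC_GROUPS", "fractional_charge", "charge_profile",
    "load_scale", "load_pka",
]
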