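"""α-helical propensity via a Lifson–Roig helix–coil transfer-matrix model.

The decision rule needs a percent-helicity estimate for monomeric peptides.
The built-in estimator is a single-sequence Lifson–Roig model: each residue
is in a helical (h) or coil (c) state; an h residue flanked by h on both
sides contributes a propagation weight ``w``, any other h residue a
nucleation weight ``v``, and c residues weight 1. Mean helicity is the
average probability of a residue being in the propagating (w) state, i.e.
inside a helical segment of at least three consecutive h residues —
multiplied by 100 to give percent.

Propagation weights come from a published experimental helix-propensity
table (free-energy differences relative to alanine), anchored at
w(Ala) = 1.61 at 278 K; temperature enters through van 't Hoff Boltzmann
weighting with a helix-formation enthalpy of −0.9 kcal/mol per residue, so
helicity decreases monotonically with temperature. Free termini destabilise
terminal helical residues; N-acetylation / C-amidation removes that penalty.

This model is a documented approximation, not a reimplementation of AGADIR:
pH and ionic strength are accepted for interface fidelity but ignored, and
published AGADIR scores are handled instead by the external-score adapter
(:func:`load_external_scores`, :class:`ExternalScores`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Protocol, Union

import numpy as np

from .peptide_io import PeptideRecord

R_KCAL = 1.9872041e-3  # gas constant, kcal/(mol*K)
T_REF = 278.0          # reference temperature for the propensity table, K

#: Helix-propensity differences ΔΔG (kcal/mol) relative to alanine, from a
#: published experimental consensus table. Larger = weaker helix former.
DELTA_DELTA_G: dict[str, float] = {
    "A": 0.00, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26,
    "Q": 0.39, "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50,
    "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61, "N": 0.65,
    "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.00, "P": 3.16,
}

W_ALA_REF = 1.61       # propagation weight of alanine at T_REF
V_NUCLEATION = 0.036   # Lifson-Roig nucleation weight (residue-independent)
DELTA_H_HELIX = -0.9   # van 't Hoff helix-formation enthalpy, kcal/mol/residue
FREE_TERMINUS_DG = 0.5  # destabilisation of a terminal h residue at a free terminus, kcal/mol


def propagation_weight(residue: str, temperature: float = T_REF) -> float:
    """Lifson–Roig propagation weight w of a residue at a temperature.

    ``w(T_ref) = w_Ala * exp(-ΔΔG / (R*T_ref))``; away from the reference the
    weight follows van 't Hoff with a fixed helix-formation enthalpy, which
    makes w strictly decreasing in temperature for every residue.
    """
    dg_ref = -R_KCAL * T_REF * math.log(W_ALA_REF) + DELTA_DELTA_G[residue]
    ds = (DELTA_H_HELIX - dg_ref) / T_REF
    dg = DELTA_H_HELIX - temperature * ds
    return math.exp(-dg / (R_KCAL * temperature))


@dataclass
class HelicityConfig:
    """Environmental parameters of the helicity estimator.

    ``pH`` and ``ionic_strength`` are accepted for interface compatibility
    with external helix predictors but have no effect on the built-in model.
    """

    temperature: float = 278.0
    ionic_strength: float = 0.1
    pH: float = 7.0
    n_term_protected: bool = False
    c_term_protected: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")


@dataclass
class HelicityScore:
    """Mean percent helicity plus optional per-residue probabilities."""

    value: float                      # percent, in [0, 100]
    source: str                       # "builtin" | "external"
    per_residue: Optional[list[float]] = None


def _weights(seq: str, config: HelicityConfig) -> tuple[np.ndarray, float, float, float]:
    w = np.array([propagation_weight(aa, config.temperature) for aa in seq])
    v = V_NUCLEATION
    rt = R_KCAL * config.temperature
    fn = 1.0 if config.n_term_protected else math.exp(-FREE_TERMINUS_DG / rt)
    fc = 1.0 if config.c_term_protected else math.exp(-FREE_TERMINUS_DG / rt)
    return w, v, fn, fc


# Transfer-matrix state order: (prev, cur) = cc, ch, hc, hh.
def _transfer(w_i: float, v: float) -> np.ndarray:
    return np.array(
        [
            [1.0, 1.0, 0.0, 0.0],   # from cc: cur=c, weight 1
            [0.0, 0.0, v, v],       # from ch: cur=h, prev=c -> v
            [1.0, 1.0, 0.0, 0.0],   # from hc: cur=c
            [0.0, 0.0, v, w_i],     # from hh: w if next=h else v
        ]
    )


def helix_content(
    record: Union[str, PeptideRecord],
    config: Optional[HelicityConfig] = None,
) -> HelicityScore:
    """Mean percent helicity from the Lifson–Roig partition function.

    Exact for the model (transfer matrices + forward–backward recursion);
    agrees with :func:`enumerate_helix_content` to floating-point accuracy.
    Peptides shorter than 3 residues score 0: no helical segment of the
    minimum length (3 consecutive h states) fits.
    """
    config = config or HelicityConfig()
    seq = record.sequence if isinstance(record, PeptideRecord) else record
    n = len(seq)
    if n == 0:
        raise ValueError("sequence must be non-empty")
    if n < 3:
        return HelicityScore(0.0, "builtin", [0.0] * n)
    w, v, fn, fc = _weights(seq, config)
    start = np.array([1.0, fn, 0.0, 0.0])     # (c, s1); penalty if s1 = h
    end = np.array([1.0, 0.0, fc, 0.0])       # (sN, c); penalty if sN = h
    mats = [_transfer(w[i], v) for i in range(n)]
    # forward[i] = start . T_1 ... T_i ; backward[i] = T_{i+1} ... T_N . end
    forward = np.empty((n + 1, 4))
    forward[0] = start
    for i in range(n):
        forward[i + 1] = forward[i] @ mats[i]
    backward = np.empty((n + 1, 4))
    backward[n] = end
    for i in range(n - 1, -1, -1):
        backward[i] = mats[i] @ backward[i + 1]
    z = float(forward[0] @ backward[0])
    # P(residue i in w state) isolates the hh->hh propagation entry of T_i.
    per = []
    for i in range(n):
        per.append(forward[i][3] * w[i] * backward[i + 1][3] / z)
    value = 100.0 * float(np.mean(per))
    return HelicityScore(value, "builtin", per)


def enumerate_helix_content(
    record: Union[str, PeptideRecord],
    config: Optional[HelicityConfig] = None,
) -> HelicityScore:
    """Brute-force oracle: explicit sum over all 2^N helix/coil states.

    Same contract as :func:`helix_content`; refuses sequences longer than 14
    residues. The all-coil state contributes weight 1, so the partition
    function is always ≥ 1.
    """
    config = config or HelicityConfig()
    seq = record.sequence if isinstance(record, PeptideRecord) else record
    n = len(seq)
    if n == 0:
        raise ValueError("sequence must be non-empty")
    if n > 14:
        raise ValueError("enumeration oracle limited to length <= 14")
    w, v, fn, fc = _weights(seq, config)
    z = 0.0
    counts = np.zeros(n)
    for mask in range(1 << n):
        states = [(mask >> i) & 1 for i in range(n)]
        weight = 1.0
        wstate = []
        for i, s in enumerate(states):
            if not s:
                continue
            left = states[i - 1] if i > 0 else 0
            right = states[i + 1] if i < n - 1 else 0
            if left and right:
                weight *= w[i]
                wstate.append(i)
            else:
                weight *= v
        if states[0]:
            weight *= fn
        if states[-1]:
            weight *= fc
        z += weight
        for i in wstate:
            counts[i] += weight
    per = list(counts / z)
    return HelicityScore(100.0 * float(np.mean(per)), "builtin", per)


# --- helicity sources --------------------------------------------------


class HelicitySource(Protocol):
    """Anything that can score a sequence's percent helicity."""

    def score(
        self,
        sequence: str,
        record_id: Optional[str] = None,
        n_term_protected: bool = False,
        c_term_protected: bool = False,
    ) -> float: ...


class BuiltinHelicity:
    """Score sequences with the built-in Lifson–Roig model."""

    def __init__(self, config: Optional[HelicityConfig] = None) -> None:
        self.config = config or HelicityConfig()

    def score(
        self,
        sequence: str,
        record_id: Optional[str] = None,
        n_term_protected: bool = False,
        c_term_protected: bool = False,
    ) -> float:
        cfg = HelicityConfig(
            temperature=self.config.temperature,
            ionic_strength=self.config.ionic_strength,
            pH=self.config.pH,
            n_term_protected=n_term_protected or self.config.n_term_protected,
            c_term_protected=c_term_protected or self.config.c_term_protected,
        )
        return helix_content(sequence, cfg).value


class ExternalScores:
    """Adapter for externally computed helicity scores (AGADIR-style).

    Looks up the record id first, then the exact sequence. When ``fallback``
    is None the external table is the sole helicity authority and unmatched
    queries score 0; pass a :class:`BuiltinHelicity` as fallback to mix the
    built-in model in for unmatched sequences (e.g. window scans).
    """

    def __init__(
        self,
        scores: Mapping[str, float],
        fallback: Optional[HelicitySource] = None,
    ) -> None:
        self.scores = dict(scores)
        self.fallback = fallback

    def score(
        self,
        sequence: str,
        record_id: Optional[str] = None,
        n_term_protected: bool = False,
        c_term_protected: bool = False,
    ) -> float:
        if record_id is not None and record_id in self.scores:
            return self.scores[record_id]
        if sequence in self.scores:
            return self.scores[sequence]
        if self.fallback is not None:
            return self.fallback.score(
                sequence, record_id, n_term_protected, c_term_protected
            )
        return 0.0


def load_external_scores(path: str | Path) -> dict[str, float]:
    """Read a 2-column delimited file of (id, percent helicity).

    Tabs, commas or whitespace delimit; ``#`` starts a comment. Rows with a
    missing or unparsable score are skipped with a warning.
    """
    import warnings

    scores: dict[str, float] = {}
    for lineno, line in enumerate(open(path), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            warnings.warn(f"{path}:{lineno}: no score column, row skipped")
            continue
        try:
            scores[parts[0]] = float(parts[1])
        except ValueError:
            warnings.warn(f"{path}:{lineno}: unparsable score {parts[1]!r}, row skipped")
    return scores


__all__ = [
    "HelicityConfig", "HelicityScore", "helix_content",
    "enumerate_helix_content", "propagation_weight", "HelicitySource",
    "BuiltinHelicity", "ExternalScores", "load_external_scores",
    "DELTA_DELTA_G", "V_NUCLEATION", "W_ALA_REF", "T_REF",
]
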