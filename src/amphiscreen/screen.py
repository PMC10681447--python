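"""Four-criterion decision rule and sliding-window inhibitory-region search.

A peptide is a positive hit when it simultaneously satisfies:

1. helicity — percent α-helical propensity ≥ ``helicity_min`` (default 1,
   deliberately user-variable: lowering it admits disordered peptides that
   may fold upon binding);
2. amphipathicity — mean windowed hydrophobic moment uH ≥ ``uh_min`` (0.2);
3. cationicity — at least one positively charged residue per
   ``positive_per_residues`` residues (default 18). A residue counts as
   positively charged when its Henderson–Hasselbalch fractional charge at
   the working pH exceeds +0.5 (K and R at pH 7; H only below its pKa).
   The fractional NCPR is computed and reported alongside;
4. length — between ``len_min`` (18 residues, five helical turns) and
   ``len_max`` (54 residues, fifteen turns).

When the full-length peptide is negative, every substring with admissible
length is evaluated and the longest passing one is reported as the
inhibitory region (ties broken toward the N-terminus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .helicity import BuiltinHelicity, HelicitySource
from .peptide_io import PeptideRecord, validate_record
from .physchem import ChargeModel, DEFAULT_PKA, DEFAULT_SCALE, HydrophobicityScale, charge_profile, mean_windowed_moment


@dataclass
class ScreenConfig:
    """All decision thresholds and environmental parameters of the screen."""

    helicity_min: float = 1.0
    uh_min: float = 0.2
    positive_per_residues: int = 18
    len_min: int = 18
    len_max: int = 54
    window: int = 18
    pH: float = 7.0

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min must not exceed len_max")
        for name in ("helicity_min", "uh_min", "positive_per_residues",
                     "len_min", "len_max", "window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def ncpr_min(self) -> float:
        """Positive-charge rate implied by ``positive_per_residues``."""
        return 1.0 / self.positive_per_residues


@dataclass
class PropertyResult:
    """Computed properties of one sequence plus per-criterion pass flags.

    ``pass_ncpr`` is the cationicity criterion: the count of predominantly
    protonated basic residues must reach one per ``positive_per_residues``
    residues. ``ncpr`` itself is the reported fractional net charge per
    residue.
    """

    length: int
    helicity: float
    uh: float
    ncpr: float
    basic_count: int
    pass_helicity: bool
    pass_uh: bool
    pass_ncpr: bool
    pass_length: bool

    @property
    def all_pass(self) -> bool:
        return self.pass_helicity and self.pass_uh and self.pass_ncpr and self.pass_length


@dataclass
class Region:
    """A detected inhibitory stretch, 1-based inclusive coordinates."""

    start: int
    end: int
    sequence: str
    properties: PropertyResult

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("region coordinates inconsistent with sequence length")


@dataclass
class ScreenResult:
    """Final decision for one peptide record."""

    record_id: str
    sequence: str
    full_length: PropertyResult
    decision: str                    # "positive_full" | "positive_region" | "negative"
    region: Optional[Region] = None
    invalid: bool = False
    note: Optional[str] = None


def evaluate(
    record: PeptideRecord,
    config: Optional[ScreenConfig] = None,
    helicity_source: Optional[HelicitySource] = None,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    pka: Optional[dict] = None,
) -> PropertyResult:
    """Compute length, helicity, uH and NCPR with their pass flags."""
    config = config or ScreenConfig()
    helicity_source = helicity_source or BuiltinHelicity()
    helicity = helicity_source.score(
        record.sequence,
        record_id=record.id,
        n_term_protected=record.n_term_protected,
        c_term_protected=record.c_term_protected,
    )
    return _properties(record, helicity, config, scale, pka)


def find_region(
    record: PeptideRecord,
    config: Optional[ScreenConfig] = None,
    helicity_source: Optional[HelicitySource] = None,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    pka: Optional[dict] = None,
) -> Optional[Region]:
    """Longest internal substring passing all four criteria, or None.

    Evaluates every substring with length in ``[len_min, min(L, len_max)]``,
    longest first; among equally long passing substrings the most N-terminal
    wins. Substrings inherit a terminal-protection flag only where they reach
    the corresponding end of the parent peptide. Records shorter than
    ``len_min`` yield None.
    """
    config = config or ScreenConfig()
    helicity_source = helicity_source or BuiltinHelicity()
    total = len(record.sequence)
    for length in range(min(total, config.len_max), config.len_min - 1, -1):
        for start0 in range(0, total - length + 1):
            sub = record.sequence[start0 : start0 + length]
            candidate = PeptideRecord(
                id=record.id,
                sequence=sub,
                n_term_protected=record.n_term_protected and start0 == 0,
                c_term_protected=record.c_term_protected and start0 + length == total,
            )
            # Window candidates are scored by sequence, never by parent id.
            helicity = helicity_source.score(
                sub,
                record_id=None,
                n_term_protected=candidate.n_term_protected,
                c_term_protected=candidate.c_term_protected,
            )
            props = _properties(candidate, helicity, config, scale, pka)
            if props.all_pass:
                return Region(start=start0 + 1, end=start0 + length,
                              sequence=sub, properties=props)
    return None


def _properties(
    record: PeptideRecord,
    helicity: float,
    config: ScreenConfig,
    scale: HydrophobicityScale,
    pka: Optional[dict],
) -> PropertyResult:
    uh = mean_windowed_moment(record.sequence, scale, window=config.window)
    model = ChargeModel(pka=pka or dict(DEFAULT_PKA), pH=config.pH)
    profile = charge_profile(record, model)
    basic_count = sum(1 for q in profile.per_residue if q > 0.5)
    length = len(record.sequence)
    return PropertyResult(
        length=length, helicity=helicity, uh=uh, ncpr=profile.ncpr,
        basic_count=basic_count,
        pass_helicity=helicity >= config.helicity_min,
        pass_uh=uh >= config.uh_min,
        pass_ncpr=basic_count >= length / config.positive_per_residues,
        pass_length=config.len_min <= length <= config.len_max,
    )


def screen_record(
    record: PeptideRecord,
    config: Optional[ScreenConfig] = None,
    helicity_source: Optional[HelicitySource] = None,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    pka: Optional[dict] = None,
) -> ScreenResult:
    """Screen one record: full-length evaluation, then region search."""
    config = config or ScreenConfig()
    helicity_source = helicity_source or BuiltinHelicity()
    report = validate_record(record)
    if not report.valid:
        empty = PropertyResult(len(record.sequence), 0.0, 0.0, 0.0, 0,
                               False, False, False, False)
        return ScreenResult(record.id, record.sequence, empty, "negative",
                            invalid=True, note=f"invalid: {report.reason}")
    full = evaluate(record, config, helicity_source, scale, pka)
    if full.all_pass:
        return ScreenResult(record.id, record.sequence, full, "positive_full")
    region = None
    if len(record.sequence) >= config.len_min:
        region = find_region(record, config, helicity_source, scale, pka)
    if region is not None:
        return ScreenResult(record.id, record.sequence, full,
                            "positive_region", region=region)
    return ScreenResult(record.id, record.sequence, full, "negative")


def screen_batch(
    records: list[PeptideRecord],
    config: Optional[ScreenConfig] = None,
    helicity_source: Optional[HelicitySource] = None,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    pka: Optional[dict] = None,
) -> list[ScreenResult]:
    """Screen a batch, one result per record, input order preserved.

    Invalid records are recorded as negative with ``invalid=True``; per-record
    failures never raise.
    """
    config = config or ScreenConfig()
    helicity_source = helicity_source or BuiltinHelicity()
    return [screen_record(r, config, helicity_source, scale, pka) for r in records]


__all__ = [
    "ScreenConfig", "PropertyResult", "Region", "ScreenResult",
    "evaluate", "find_region", "screen_record", "screen_batch",
]
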