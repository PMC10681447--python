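"""Reading, validating, deduplicating and writing peptide records.

Peptides enter as FASTA (or plain strings wrapped in :class:`PeptideRecord`)
and leave as a tab-separated results table. Coordinates are 1-based inclusive
throughout the package, matching the convention used for inhibitory regions
(e.g. ``16-DMARYYSALRHYINLITRQRY-36``).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .screen import ScreenResult

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PeptideRecord:
    """A single peptide sequence with terminal-modification flags.

    ``n_term_protected`` marks N-terminal acetylation and ``c_term_protected``
    C-terminal amidation; both remove the corresponding terminal charge and
    terminal helix destabilisation.
    """

    id: str
    sequence: str
    n_term_protected: bool = False
    c_term_protected: bool = False
    source: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ValidationReport:
    """Outcome of checking a record against the canonical alphabet."""

    record_id: str
    valid: bool
    offending_positions: list[int] = field(default_factory=list)
    reason: Optional[str] = None  # "non_natural_residue" | "empty" | "lowercase_normalized"


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read peptide records from a FASTA file.

    The header token before the first whitespace becomes the record id;
    sequences are uppercased. No alphabet validation happens here (see
    :func:`validate_record`); duplicate ids are preserved.

    Raises
    ------
    FastaParseError
        If a sequence line appears before any ``>`` header, naming the
        offending line number.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            break
        raise FastaParseError(
            f"{path}: sequence data before any FASTA header at line {lineno}"
        )
    records = []
    for entry in SeqIO.parse(_io.StringIO(text), "fasta"):
        records.append(PeptideRecord(id=entry.id, sequence=str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records as minimal single-line FASTA (round-trips with read_fasta)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def validate_record(record: PeptideRecord) -> ValidationReport:
    """Flag residues outside the 20 canonical one-letter codes.

    B, J, O, U, X, Z and any non-letter symbol are invalid; only peptides
    composed of natural amino acids are screened. Invalidity is data, not an
    exception. Offending positions are 1-based.
    """
    seq = record.sequence
    if not seq:
        return ValidationReport(record.id, valid=False, reason="empty")
    offending = [i for i, aa in enumerate(seq, start=1) if aa not in CANONICAL_AA]
    if offending:
        return ValidationReport(
            record.id, valid=False, offending_positions=offending,
            reason="non_natural_residue",
        )
    return ValidationReport(record.id, valid=True)


def deduplicate(
    records: list[PeptideRecord],
) -> tuple[list[PeptideRecord], int]:
    """Keep the first occurrence of each distinct sequence, preserving order.

    The dedup key is the exact sequence string; terminal-protection flags and
    ids of later duplicates are discarded. Returns ``(unique, n_removed)``.
    Idempotent.
    """
    seen: set[str] = set()
    unique: list[PeptideRecord] = []
    for rec in records:
        if rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        unique.append(rec)
    return unique, len(records) - len(unique)


RESULT_COLUMNS = [
    "id", "sequence", "length", "helicity_score", "uH", "NCPR",
    "decision", "region_start", "region_end", "region_sequence",
]


def write_results_table(results: list["ScreenResult"], path: str | Path) -> None:
    """Write screening results as a TSV with a fixed schema.

    Floating values are rendered with 2 decimal places; region columns are
    empty for full-length positives and for negatives.
    """
    rows = []
    for res in results:
        p = res.full_length
        row = {
            "id": res.record_id,
            "sequence": res.sequence,
            "length": p.length,
            "helicity_score": f"{p.helicity:.2f}",
            "uH": f"{p.uh:.2f}",
            "NCPR": f"{p.ncpr:.2f}",
            "decision": res.decision,
            "region_start": res.region.start if res.region else "",
            "region_end": res.region.end if res.region else "",
            "region_sequence": res.region.sequence if res.region else "",
        }
        rows.append(row)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Re-parse a results TSV written by :func:`write_results_table`."""
    df = pd.read_csv(
        path, sep="\t", dtype={"id": str, "sequence": str, "decision": str},
        keep_default_na=False,
    )
    for col in ("helicity_score", "uH", "NCPR"):
        df[col] = df[col].astype(float)
    return df


def validation_reports_table(reports: Iterable[ValidationReport], path: str | Path) -> None:
    """Dump validation reports as TSV on request."""
    df = pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "valid": r.valid,
                "offending_positions": ",".join(map(str, r.offending_positions)),
                "reason": r.reason or "",
            }
            for r in reports
        ]
    )
    df.to_csv(path, sep="\t", index=False)


__all__ = [
    "CANONICAL_AA", "PeptideRecord", "ValidationReport", "FastaParseError",
    "read_fasta", "write_fasta", "validate_record", "deduplicate",
    "write_results_table", "read_results_table", "validation_reports_table",
    "RESULT_COLUMNS",
]
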