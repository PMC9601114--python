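"""Reading, validating and writing coding sequences.

A coding sequence (CDS) is only admitted to the analysis if it looks
like a complete, translatable open reading frame: length a multiple of
three, a proper initiation codon, a terminal stop codon, no internal
stops, and no ambiguous bases.  Records failing any check are not
errors — they are reported in a :class:`QcReport` with a single reason
code each, so a QC table can be written alongside the results.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import ALT_START_CODONS, START_CODON, STOP_CODONS

logger = logging.getLogger(__name__)

MIN_LENGTH_NT = 6  # start codon + stop codon

# reason codes, in the fixed order checks are applied
AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
NOT_MULTIPLE_OF_3 = "NOT_MULTIPLE_OF_3"
TOO_SHORT = "TOO_SHORT"
BAD_START = "BAD_START"
INTERNAL_STOP = "INTERNAL_STOP"
BAD_STOP = "BAD_STOP"

REASON_CODES = (
    AMBIGUOUS_BASE,
    NOT_MULTIPLE_OF_3,
    TOO_SHORT,
    BAD_START,
    INTERNAL_STOP,
    BAD_STOP,
)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """One validated in-frame CDS."""

    id: str
    seq: str

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    @property
    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]


@dataclass
class QcReport:
    """Outcome of CDS validation: pass count plus per-record rejections."""

    n_input: int
    n_passed: int
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self, passed_ids: list[str] | None = None) -> pd.DataFrame:
        rows = [{"id": i, "status": "FAIL", "reason": r} for i, r in self.rejections]
        if passed_ids is not None:
            rows = [
                {"id": i, "status": "PASS", "reason": ""} for i in passed_ids
            ] + rows
        return pd.DataFrame(rows, columns=["id", "status", "reason"])


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) multi-FASTA into (id, sequence) pairs.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``; ids are
    the first whitespace-delimited header token, with duplicate ids
    disambiguated by a numeric suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            name = rec.id
            if name in seen:
                seen[name] += 1
                new = f"{name}_{seen[name]}"
                logger.warning("duplicate FASTA id %r renamed to %r", name, new)
                name = new
            else:
                seen[name] = 0
            records.append((name, str(rec.seq).upper().replace("U", "T")))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def validate_cds(
    records: list[tuple[str, str]],
    *,
    allow_alt_starts: bool = False,
    min_length: int = MIN_LENGTH_NT,
) -> tuple[list[CodingSequence], QcReport]:
    """Apply the CDS validity filters to raw records.

    Checks run in a fixed order and each rejection carries the first
    failing reason: ambiguous bases, length not a multiple of three,
    too short, bad start codon, internal stop, bad terminal stop.
    """
    starts = {START_CODON} | (ALT_START_CODONS if allow_alt_starts else set())
    passed: list[CodingSequence] = []
    rejections: list[tuple[str, str]] = []
    for name, seq in records:
        reason = _first_failure(seq, starts, min_length)
        if reason is None:
            passed.append(CodingSequence(id=name, seq=seq))
        else:
            rejections.append((name, reason))
    report = QcReport(n_input=len(records), n_passed=len(passed), rejections=rejections)
    return passed, report


def _first_failure(seq: str, starts: set[str], min_length: int) -> str | None:
    if set(seq) - _VALID_BASES:
        return AMBIGUOUS_BASE
    if len(seq) % 3 != 0:
        return NOT_MULTIPLE_OF_3
    if len(seq) < min_length:
        return TOO_SHORT
    if seq[:3] not in starts:
        return BAD_START
    internal = [seq[i : i + 3] for i in range(3, len(seq) - 3, 3)]
    if any(c in STOP_CODONS for c in internal):
        return INTERNAL_STOP
    if seq[-3:] not in STOP_CODONS:
        return BAD_STOP
    return None


def write_fasta(genes: list[CodingSequence], path: str | Path, width: int = 70) -> None:
    """Write validated CDS back to FASTA (round-trips with read/validate)."""
    recs = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genes]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(recs)


def write_qc_report(
    report: QcReport, passed: list[CodingSequence], path: str | Path
) -> None:
    report.to_frame([g.id for g in passed]).to_csv(path, sep="\t", index=False)
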