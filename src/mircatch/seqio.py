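"""Sequence containers and FASTA plumbing shared by the whole toolkit.

Conventions
-----------
* All user-facing coordinates are **1-based, inclusive**, matching the way
  capture-oligo positions are reported in probe-design tables
  (e.g. "328-352 bp" on the target mRNA).
* ``U`` and ``T`` are interchangeable on input.  Transcripts are stored as
  RNA (with ``U``); DNA oligos are stored with ``T``.  ``N`` is accepted in
  transcripts but disqualifies any oligo window that overlaps it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Interval",
    "Transcript",
    "FastaError",
    "SequenceError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "gc_content",
    "extract_region",
    "as_dna",
    "as_rna",
]

REGION_LABELS = ("5UTR", "CDS", "3UTR")

_DNA_CHARS = frozenset("ACGTN")
_RNA_CHARS = frozenset("ACGUN")
_DNA_RC = str.maketrans("ACGTN", "TGCAN")
_RNA_RC = str.maketrans("ACGUN", "UGCAN")


class SequenceError(ValueError):
    """Invalid sequence content (bad characters, empty sequence, ...)."""


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


def as_dna(seq: str) -> str:
    """Upper-case *seq* and convert U to T."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    """Upper-case *seq* and convert T to U."""
    return seq.upper().replace("T", "U")


def _validate_chars(seq: str, alphabet: str, context: str = "sequence") -> None:
    allowed = _DNA_CHARS if alphabet == "DNA" else _RNA_CHARS
    bad = set(seq) - allowed
    if bad:
        raise SequenceError(
            f"invalid {alphabet} character(s) {sorted(bad)} in {context}"
        )


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive interval; ``length == end - start + 1``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start}-{self.end}"


@dataclass
class Transcript:
    """A named nucleotide sequence with optional 5UTR/CDS/3UTR annotation.

    ``regions`` is a list of ``(label, start, end)`` with 1-based inclusive
    coordinates; regions must be non-overlapping and within the sequence.
    """

    id: str
    sequence: str
    alphabet: str = "RNA"
    regions: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        seq = self.sequence.upper()
        seq = seq.replace("T", "U") if self.alphabet == "RNA" else seq.replace("U", "T")
        if not seq:
            raise SequenceError(f"transcript {self.id!r}: empty sequence")
        _validate_chars(seq, self.alphabet, f"transcript {self.id!r}")
        self.sequence = seq
        if self.regions:
            last_end = 0
            for label, start, end in sorted(self.regions, key=lambda r: r[1]):
                if label not in REGION_LABELS:
                    raise ValueError(f"unknown region label {label!r}")
                if start < 1 or end > len(seq) or end < start:
                    raise ValueError(
                        f"region {label} {start}-{end} outside transcript "
                        f"{self.id!r} (length {len(seq)})"
                    )
                if start <= last_end:
                    raise ValueError(f"overlapping regions in transcript {self.id!r}")
                last_end = end

    def __len__(self) -> int:
        return len(self.sequence)

    def region_label(self, pos: int) -> str:
        """Label (5UTR/CDS/3UTR) of the 1-based position, or ``unknown``."""
        if self.regions:
            for label, start, end in self.regions:
                if start <= pos <= end:
                    return label
        return "unknown"


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[Transcript]:
    """Read a FASTA file into :class:`Transcript` records.

    IDs are the header token before the first whitespace; sequences are
    upper-cased.  ``alphabet`` may be ``DNA``, ``RNA``, or ``auto`` (RNA if
    the record contains U and no T, DNA otherwise).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected a '>' header line"
                    )
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")

    transcripts: list[Transcript] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FastaError(f"{path}: record {record.id!r} has an empty sequence")
        if alphabet == "auto":
            record_alphabet = "RNA" if ("U" in seq and "T" not in seq) else "DNA"
        else:
            record_alphabet = alphabet
        transcripts.append(Transcript(record.id, seq, alphabet=record_alphabet))
    if not transcripts:
        raise FastaError(f"{path}: no FASTA records found")
    return transcripts


def write_fasta(
    transcripts: Sequence[Transcript], path: str | Path, width: int = 70
) -> None:
    """Write records as FASTA with fixed line width (default 70)."""
    if not transcripts:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")


def reverse_complement(seq: str, alphabet: str = "DNA") -> str:
    """Reverse complement within one alphabet (DNA->DNA or RNA->RNA)."""
    seq = seq.upper()
    _validate_chars(seq, alphabet)
    table = _DNA_RC if alphabet == "DNA" else _RNA_RC
    return seq.translate(table)[::-1]


def gc_content(seq: str) -> float:
    """Percent G+C of a sequence (0-100)."""
    seq = seq.upper()
    if not seq:
        raise SequenceError("gc_content of an empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def extract_region(transcript: Transcript | str, interval: Interval) -> str:
    """Subsequence at a 1-based inclusive interval."""
    seq = transcript.sequence if isinstance(transcript, Transcript) else transcript
    if interval.end > len(seq):
        raise ValueError(
            f"interval {interval} outside sequence of length {len(seq)}"
        )
    return seq[interval.start - 1 : interval.end]
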