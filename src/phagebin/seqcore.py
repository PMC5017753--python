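"""Sequence primitives and standard-format I/O shared by all pipeline stages.

Coordinate convention
---------------------
All user-facing coordinates (:class:`Interval`, GFF3 output, match tables) are
1-based inclusive, following the EMBOSS/GFF3 convention.  Internally, plain
Python slices (0-based, half-open) are used; every conversion happens at the
dataclass boundary.

Alphabet
--------
Sequences are uppercased on ingest and every letter outside ``ACGT`` is
collapsed to the single unknown symbol ``N``.  Downstream stages (TNF windows,
CRISPR seeds) treat ``N`` as "cannot count / cannot seed".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DuplicateIdError(ValueError):
    """Raised when a FASTA file contains the same record id twice."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}; "
                "normalize with normalize_seq() first"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval on a named sequence, with strand."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.start}..{self.end} on {self.seq_id!r} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        """≥1 bp overlap on the same sequence (strand ignored)."""
        return self.seq_id == other.seq_id and self.start <= other.end and other.start <= self.end

    def slice(self, seq: str) -> str:
        """Extract this interval from a forward-strand sequence string."""
        sub = seq[self.start - 1 : self.end]
        return revcomp(sub) if self.strand == "-" else sub


def normalize_seq(raw: str) -> tuple[str, int]:
    """Uppercase and collapse non-ACGT letters to N.

    Returns the normalized string and the number of characters that were
    mapped to N (excluding letters that already were N).
    """
    up = raw.upper()
    out = []
    n_mapped = 0
    for ch in up:
        if ch in _VALID:
            out.append(ch)
        else:
            out.append("N")
            n_mapped += 1
    return "".join(out), n_mapped


def revcomp(seq: str) -> str:
    """Reverse complement over ACGTN (N is self-complementary)."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"revcomp: illegal characters {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA into normalized :class:`SequenceRecord` objects.

    Lowercase letters are uppercased and any letter outside ACGTN becomes N
    (total count logged).  Duplicate ids are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    total_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq, n_mapped = normalize_seq(str(rec.seq))
        total_mapped += n_mapped
        desc = rec.description[len(rec.id) :].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    if total_mapped:
        logger.info("read_fasta(%s): mapped %d non-ACGTN characters to N", path, total_mapped)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> Path:
    """Write records as wrapped FASTA; round-trips exactly through read_fasta."""
    path = Path(path)
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
    return path


def gff3_line(
    interval: Interval,
    source: str,
    feature_type: str,
    attributes: str,
    score: str = ".",
) -> str:
    """One GFF3 body line (1-based inclusive coordinates)."""
    return "\t".join(
        [
            interval.seq_id,
            source,
            feature_type,
            str(interval.start),
            str(interval.end),
            score,
            interval.strand,
            ".",
            attributes,
        ]
    )


def write_gff3(lines: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in lines:
            fh.write(line + "\n")
    return path


def to_biopython(rec: SequenceRecord) -> _BioSeqRecord:
    return _BioSeqRecord(Seq(rec.seq), id=rec.id, description=rec.description)
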