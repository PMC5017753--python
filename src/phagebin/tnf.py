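"""Canonical tetranucleotide frequency (TNF) profiling.

The compositional signature used for binning is the frequency vector of the
136 canonical tetramers: the 256 4-mers collapsed by reverse complementation,
each class represented by the lexicographically smaller member (A<C<G<T).
Counting every overlapping 4-mer window on one strand under this
canonicalization is equivalent to counting both strands, so profiles are
strand-invariant by construction.

Windows containing an N are excluded from both numerator and denominator, so
profiles remain comparable across contigs with ambiguity runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import SequenceRecord, revcomp

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_BASE = "ACGT"


class UnprofilableSequenceError(ValueError):
    """Sequence has no N-free 4-mer window."""


def canonical_tetramer(tet: str) -> str:
    """Lexicographic minimum of a tetramer and its reverse complement.

    Idempotent; rejects N and wrong lengths.
    """
    if len(tet) != 4:
        raise ValueError(f"tetramer must have length 4, got {tet!r}")
    if any(ch not in "ACGT" for ch in tet):
        raise ValueError(f"tetramer must be over ACGT, got {tet!r}")
    rc = revcomp(tet)
    return tet if tet <= rc else rc


def _all_tetramers() -> list[str]:
    return [
        a + b + c + d
        for a in _CODE_BASE
        for b in _CODE_BASE
        for c in _CODE_BASE
        for d in _CODE_BASE
    ]


def enumerate_canonical() -> list[str]:
    """Sorted list of the 136 canonical tetramer classes."""
    return sorted({canonical_tetramer(t) for t in _all_tetramers()})


CANONICAL_TETRAMERS: tuple[str, ...] = tuple(enumerate_canonical())
_CANONICAL_INDEX: dict[str, int] = {t: i for i, t in enumerate(CANONICAL_TETRAMERS)}

# maps the integer code of each of the 256 tetramers to its canonical class index
_CODE_TO_CANON = np.array(
    [_CANONICAL_INDEX[canonical_tetramer(t)] for t in _all_tetramers()], dtype=np.int64
)


@dataclass
class TetraProfile:
    """136-dimensional canonical tetramer frequency vector of one sequence."""

    seq_id: str
    source_label: str
    freqs: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (136,):
            raise ValueError("freqs must have length 136")


def tetramer_counts(seq: str) -> tuple[np.ndarray, int]:
    """Canonical-class counts over all N-free overlapping 4-mer windows."""
    if len(seq) < 4:
        raise ValueError(f"sequence shorter than 4 nt ({len(seq)})")
    codes = np.fromiter((_BASE_CODE[ch] for ch in seq), dtype=np.int64, count=len(seq))
    w = np.lib.stride_tricks.sliding_window_view(codes, 4)
    valid = (w < 4).all(axis=1)
    if not valid.any():
        raise UnprofilableSequenceError("no N-free 4-mer window in sequence")
    idx = w[valid] @ np.array([64, 16, 4, 1], dtype=np.int64)
    counts = np.bincount(_CODE_TO_CANON[idx], minlength=136).astype(np.int64)
    return counts, int(valid.sum())


def tnf_profile(record: SequenceRecord, source_label: str = "viral") -> TetraProfile:
    """Canonical TNF profile of one record (frequencies sum to 1)."""
    counts, n_windows = tetramer_counts(record.seq)
    return TetraProfile(
        seq_id=record.id,
        source_label=source_label,
        freqs=counts / n_windows,
        n_windows=n_windows,
    )


def fragment_genome(
    record: SequenceRecord, window: int = 5000, min_keep: int = 1000
) -> list[SequenceRecord]:
    """Cut a genome into consecutive non-overlapping windows.

    The final remainder shorter than ``window`` is kept iff its length is
    >= ``min_keep``.  Fragment ids encode the parent id and a 1-based ordinal.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(record.seq) == 0:
        raise ValueError(f"empty sequence {record.id!r}")
    frags: list[SequenceRecord] = []
    ordinal = 1
    for start in range(0, len(record.seq), window):
        piece = record.seq[start : start + window]
        if len(piece) < window and len(piece) < min_keep:
            break
        frags.append(
            SequenceRecord(id=f"{record.id}|frag{ordinal}", seq=piece, description="")
        )
        ordinal += 1
    return frags


@dataclass
class ProfileMatrix:
    """Stacked TNF profiles of viral contigs and reference-genome fragments."""

    profiles: list[TetraProfile]
    values: np.ndarray  # (n_rows, 136); standardized if `standardized`
    feature_order: tuple[str, ...] = CANONICAL_TETRAMERS
    standardized: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    @property
    def ids(self) -> list[str]:
        return [p.seq_id for p in self.profiles]

    @property
    def labels(self) -> list[str]:
        return [p.source_label for p in self.profiles]

    def __len__(self) -> int:
        return len(self.profiles)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_order))
        df.insert(0, "label", self.labels)
        df.insert(0, "seq_id", self.ids)
        return df

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    def to_lrn(self, path: str | Path) -> Path:
        """Databionic ESOM .lrn data file (header lines prefixed with %)."""
        path = Path(path)
        n, d = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"% {n}\n")
            fh.write(f"% {d + 1}\n")
            fh.write("% 9" + "\t1" * d + "\n")
            fh.write("% Key\t" + "\t".join(self.feature_order) + "\n")
            for i, row in enumerate(self.values, start=1):
                fh.write(str(i) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
        return path

    def to_cls(self, path: str | Path) -> Path:
        """Databionic ESOM .cls class file: one integer class per row."""
        path = Path(path)
        classes = sorted(set(self.labels))
        cls_of = {c: i + 1 for i, c in enumerate(classes)}
        with open(path, "w") as fh:
            fh.write(f"% {len(self.profiles)}\n")
            for c in classes:
                fh.write(f"% {cls_of[c]} {c}\n")
            for i, label in enumerate(self.labels, start=1):
                fh.write(f"{i}\t{cls_of[label]}\n")
        return path


def build_matrix(
    contigs: Sequence[SequenceRecord],
    references: Sequence[tuple[str, SequenceRecord]] = (),
    min_len: int = 1000,
    window: int = 5000,
    standardize: bool = True,
) -> ProfileMatrix:
    """Assemble the binning feature matrix.

    Contigs strictly longer than ``min_len`` are profiled with label
    ``"viral"``; each reference genome is fragmented into ``window``-nt pieces
    (remainder kept if >= ``min_len``) profiled under the genome's own label.
    With ``standardize`` each feature column is z-scored over all rows
    (constant columns are left at zero).
    """
    profiles: list[TetraProfile] = []
    n_dropped = 0
    for rec in contigs:
        if len(rec.seq) > min_len:
            profiles.append(tnf_profile(rec, source_label="viral"))
        else:
            n_dropped += 1
    for label, genome in references:
        for frag in fragment_genome(genome, window=window, min_keep=min_len):
            profiles.append(tnf_profile(frag, source_label=label))
    if not profiles:
        raise ValueError(
            f"no rows survive filtering (min_len={min_len}; {n_dropped} contigs dropped)"
        )
    values = np.vstack([p.freqs for p in profiles])
    means = sds = None
    if standardize:
        means = values.mean(axis=0)
        sds = values.std(axis=0)
        safe = np.where(sds > 0, sds, 1.0)
        values = (values - means) / safe
    return ProfileMatrix(
        profiles=profiles,
        values=values,
        standardized=standardize,
        means=means,
        sds=sds,
    )
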