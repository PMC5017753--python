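"""CRISPR array detection, spacer extraction, and repeat-based host labeling.

Detection is CRT-style: an exact k-mer (default k=8) recurring at admissible
spacings seeds a candidate array; repeat boundaries are then extended
column-by-column under a majority-rule consensus with a small per-instance
mismatch budget.  A locus is accepted only if it has at least ``min_repeats``
repeat instances with all spacer lengths inside the configured bounds.

Defaults follow the published CRISPRfinder defaults for direct-repeat length
(23-55 nt) with a pragmatic spacer window (17-72 nt).  The terminal repeat of
an array is allowed extra mismatches, since degenerate terminal repeats are
common in real arrays.

Manual curation of spurious calls is replaced by an explicit heuristic: an
array whose spacers are too similar to each other (>= 60% identity between
any pair) is flagged ``questionable`` — such loci are usually low-complexity
tandem repeats rather than true CRISPRs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqcore import Interval, SequenceRecord, gff3_line, revcomp, write_gff3
from .spacermatch import ScoringScheme, local_align, default_scheme


@dataclass
class CrisprParams:
    repeat_len: tuple[int, int] = (23, 55)
    spacer_len: tuple[int, int] = (17, 72)
    max_repeat_mismatch: int = 1
    terminal_extra_mismatch: int = 2
    min_repeats: int = 3
    seed_k: int = 8


@dataclass
class CrisprArray:
    """A detected repeat-spacer locus (coordinates 1-based inclusive)."""

    seq_id: str
    repeat_consensus: str
    repeat_intervals: list[Interval]
    spacers: list[tuple[Interval, str]]
    confidence: str = "confirmed"

    def __post_init__(self) -> None:
        if len(self.repeat_intervals) < 3:
            raise ValueError("array needs >= 3 repeat instances")
        if len(self.spacers) != len(self.repeat_intervals) - 1:
            raise ValueError("spacer count must be repeat count - 1")
        for a, b in zip(self.repeat_intervals, self.repeat_intervals[1:]):
            if a.end >= b.start:
                raise ValueError("repeats must be ordered and non-overlapping")
        for (iv, _), ra, rb in zip(
            self.spacers, self.repeat_intervals, self.repeat_intervals[1:]
        ):
            if not (ra.end < iv.start and iv.end < rb.start):
                raise ValueError("each spacer must lie strictly between its repeats")

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.repeat_intervals[0].start, self.repeat_intervals[-1].end


@dataclass
class Spacer:
    """One spacer sequence in a labeled database."""

    spacer_id: str
    seq: str
    host_label: str = "unknown"
    source_dataset: str = ""
    multiplicity: int = 1
    confidence: str = "confirmed"


def _consensus(columns: list[str]) -> str:
    """Majority base per column; ties resolved alphabetically."""
    out = []
    for col in columns:
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)


def _mismatches(seq: str, anchors: list[int], left: int, right: int) -> list[int]:
    """Per-instance mismatch counts against the majority consensus."""
    instances = [seq[a - left : a + right] for a in anchors]
    cons = _consensus(["".join(col) for col in zip(*instances)]) if instances[0] else ""
    return [sum(1 for x, y in zip(inst, cons) if x != y) for inst in instances]


def _budget_ok(mms: list[int], params: CrisprParams) -> bool:
    for idx, mm in enumerate(mms):
        budget = params.max_repeat_mismatch
        if idx == 0 or idx == len(mms) - 1:
            budget += params.terminal_extra_mismatch
        if mm > budget:
            return False
    return True


def _extend_candidate(
    seq: str, anchors: list[int], params: CrisprParams
) -> tuple[int, int] | None:
    """Greedily extend repeat boundaries around the seed k-mer.

    Returns (left, right) extents such that each repeat instance is
    ``seq[a-left : a+right]``, or None if no valid repeat length is reachable.
    Extension stops when a step would exceed a mismatch budget, leave the
    sequence bounds, exceed the repeat length bound, or squeeze a spacer
    below its minimum length.
    """
    k = params.seed_k
    left, right = 0, k
    rep_max = params.repeat_len[1]
    sp_min = params.spacer_len[0]
    gaps = [b - a for a, b in zip(anchors, anchors[1:])]

    def spacer_ok(l: int, r: int) -> bool:
        return all(g - (l + r) >= sp_min for g in gaps)

    progress = True
    while progress and (left + right) < rep_max:
        progress = False
        # try right
        if anchors[-1] + right + 1 <= len(seq) and spacer_ok(left, right + 1):
            mms = _mismatches(seq, anchors, left, right + 1)
            if _budget_ok(mms, params):
                right += 1
                progress = True
        if (left + right) >= rep_max:
            break
        # try left
        if anchors[0] - left - 1 >= 0 and spacer_ok(left + 1, right):
            mms = _mismatches(seq, anchors, left + 1, right)
            if _budget_ok(mms, params):
                left += 1
                progress = True
    # Final boundaries are the maximal *unanimous* run outward from the seed:
    # the mismatch budget tolerates degenerate instances while searching, but
    # a column that is not identical in every instance never becomes part of
    # the reported repeat.  This keeps exact repeats exactly recoverable and
    # pushes ambiguous columns into the flanking spacers instead.
    def unanimous(off: int) -> bool:
        chars = {seq[a + off] for a in anchors}
        return len(chars) == 1

    r = k
    while r < right and unanimous(r):
        r += 1
    right = r
    l = 0
    while l < left and unanimous(-(l + 1)):
        l += 1
    left = l
    if not (params.repeat_len[0] <= left + right <= rep_max):
        return None
    return left, right


def _chains(positions: list[int], dmin: int, dmax: int, min_repeats: int) -> list[list[int]]:
    """Maximal runs of positions whose successive gaps lie in [dmin, dmax]."""
    chains: list[list[int]] = []
    cur = [positions[0]]
    for p in positions[1:]:
        gap = p - cur[-1]
        if dmin <= gap <= dmax:
            cur.append(p)
        else:
            if len(cur) >= min_repeats:
                chains.append(cur)
            cur = [p]
    if len(cur) >= min_repeats:
        chains.append(cur)
    return chains


def find_arrays(
    record: SequenceRecord, params: CrisprParams | None = None
) -> list[CrisprArray]:
    """Detect CRISPR repeat-spacer loci on the input strand.

    Returns an empty list when nothing qualifies.  Overlapping candidates are
    resolved by keeping the one with more repeats (tie: longer repeat).
    """
    params = params or CrisprParams()
    seq = record.seq
    k = params.seed_k
    min_span = (
        params.min_repeats * params.repeat_len[0]
        + (params.min_repeats - 1) * params.spacer_len[0]
    )
    if len(seq) < min_span:
        return []
    dmin = params.repeat_len[0] + params.spacer_len[0]
    dmax = params.repeat_len[1] + params.spacer_len[1]

    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            kmer_pos[kmer].append(i)

    candidates: list[tuple[list[int], int, int]] = []
    seen_spans: set[tuple[int, int, int]] = set()
    for kmer, positions in kmer_pos.items():
        if len(positions) < params.min_repeats:
            continue
        for chain in _chains(positions, dmin, dmax, params.min_repeats):
            ext = _extend_candidate(seq, chain, params)
            if ext is None:
                continue
            left, right = ext
            rep_len = left + right
            # validate spacer lengths
            ok = True
            for a, b in zip(chain, chain[1:]):
                sp_len = (b - left) - (a + right)
                if not (params.spacer_len[0] <= sp_len <= params.spacer_len[1]):
                    ok = False
                    break
            if not ok:
                continue
            key = (chain[0] - left, chain[-1] + right, len(chain))
            if key in seen_spans:
                continue
            seen_spans.add(key)
            candidates.append((chain, left, right))

    # overlap resolution: more repeats first, then longer repeat
    candidates.sort(key=lambda c: (-len(c[0]), -(c[1] + c[2]), c[0][0] - c[1]))
    accepted: list[tuple[int, int]] = []
    arrays: list[CrisprArray] = []
    for chain, left, right in candidates:
        span = (chain[0] - left, chain[-1] + right)
        if any(span[0] < e and s < span[1] for s, e in accepted):
            continue
        accepted.append(span)
        rep_ivs = [
            Interval(record.id, a - left + 1, a + right) for a in chain
        ]
        instances = [seq[a - left : a + right] for a in chain]
        cons = _consensus(["".join(col) for col in zip(*instances)])
        spacers = []
        for a, b in zip(chain, chain[1:]):
            s0 = a + right  # 0-based start of spacer
            s1 = b - left  # 0-based end (exclusive)
            spacers.append((Interval(record.id, s0 + 1, s1), seq[s0:s1]))
        arrays.append(
            CrisprArray(
                seq_id=record.id,
                repeat_consensus=cons,
                repeat_intervals=rep_ivs,
                spacers=spacers,
            )
        )
    arrays.sort(key=lambda a: a.span[0])
    return arrays


def _pair_identity(a: str, b: str, scheme: ScoringScheme) -> float:
    """Local-alignment matches divided by the longer sequence length."""
    aln = local_align(a, b, scheme)
    return aln.n_matches / max(len(a), len(b))


def flag_questionable(arrays: Iterable[CrisprArray], threshold: float = 0.60) -> list[CrisprArray]:
    """Mark arrays whose spacers are mutually too similar as ``questionable``."""
    scheme = default_scheme()
    out = []
    for arr in arrays:
        seqs = [s for _, s in arr.spacers]
        questionable = any(
            _pair_identity(seqs[i], seqs[j], scheme) >= threshold
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        )
        out.append(replace(arr, confidence="questionable" if questionable else "confirmed"))
    return out


def extract_spacers(
    arrays: Sequence[CrisprArray],
    host_label: str = "unknown",
    source_dataset: str = "",
) -> list[Spacer]:
    """Emit spacers in array order, collapsing exact duplicates.

    Exact-duplicate spacer sequences within the returned database are merged
    into one entry whose ``multiplicity`` records the number of occurrences.
    Spacers inherit a ``questionable`` flag from the mutual-similarity check.
    """
    arrays = flag_questionable(arrays)
    by_seq: dict[str, Spacer] = {}
    counter = 0
    for arr in arrays:
        for _, s in arr.spacers:
            if s in by_seq:
                by_seq[s].multiplicity += 1
                if arr.confidence == "questionable":
                    by_seq[s].confidence = "questionable"
            else:
                counter += 1
                by_seq[s] = Spacer(
                    spacer_id=f"{host_label}-{source_dataset or 'db'}-SP-{counter}",
                    seq=s,
                    host_label=host_label,
                    source_dataset=source_dataset,
                    confidence=arr.confidence,
                )
    return list(by_seq.values())


def label_by_repeat(
    array: CrisprArray,
    known_repeats: Mapping[str, str],
    min_identity: float = 0.85,
    min_coverage: float = 0.80,
    scheme: ScoringScheme | None = None,
) -> str:
    """Label an array by its best repeat-consensus match to known host repeats.

    Both strands are tried; the label of the best hit is returned when its
    alignment identity is >= ``min_identity`` and it covers >= ``min_coverage``
    of the known repeat, else ``"unknown"``.
    """
    if not known_repeats:
        raise ValueError("empty known-repeat set")
    scheme = scheme or default_scheme()
    best_label = "unknown"
    best_key = (-1.0, -1.0)
    for label, rep in known_repeats.items():
        for query in (array.repeat_consensus, revcomp(array.repeat_consensus)):
            aln = local_align(query, rep, scheme)
            if aln.n_columns == 0:
                continue
            cov = (aln.s_end - aln.s_start + 1) / len(rep)
            key = (aln.identity, cov)
            if aln.identity >= min_identity and cov >= min_coverage and key > best_key:
                best_key = key
                best_label = label
    return best_label


def arrays_to_gff3(arrays: Sequence[CrisprArray], path: str | Path) -> Path:
    """Arrays as GFF3 with repeat_unit / CRISPR_spacer features."""
    lines = []
    for n, arr in enumerate(arrays, start=1):
        for i, iv in enumerate(arr.repeat_intervals, start=1):
            lines.append(
                gff3_line(iv, "phagebin", "repeat_unit", f"ID=array{n}.repeat{i};Parent=array{n}")
            )
        for i, (iv, s) in enumerate(arr.spacers, start=1):
            lines.append(
                gff3_line(
                    iv,
                    "phagebin",
                    "CRISPR_spacer",
                    f"ID=array{n}.spacer{i};Parent=array{n};seq={s};confidence={arr.confidence}",
                )
            )
    return write_gff3(lines, path)


def spacers_to_fasta(spacers: Sequence[Spacer], fasta_path: str | Path, tsv_path: str | Path | None = None):
    """Spacer database as FASTA plus an optional TSV sidecar."""
    from .seqcore import SequenceRecord, write_fasta

    recs = [SequenceRecord(id=sp.spacer_id, seq=sp.seq) for sp in spacers]
    write_fasta(recs, fasta_path)
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("spacer_id\thost\tdataset\tmultiplicity\tconfidence\n")
            for sp in spacers:
                fh.write(
                    f"{sp.spacer_id}\t{sp.host_label}\t{sp.source_dataset}\t"
                    f"{sp.multiplicity}\t{sp.confidence}\n"
                )
    return Path(fasta_path)
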