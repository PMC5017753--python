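"""Spacer-to-protospacer matching by local alignment.

The matcher plays the role BLASTN plays at survey scale: every spacer is
aligned against every contig on both strands with an affine-gap
Smith-Waterman, scored with a blastn-like scheme (+1 match, -2 mismatch,
gap open -5, gap extend -2), and retained under one of two threshold regimes:

* ``strict``  — identity >= 0.90 and e-value <= 1e-5 (host attribution)
* ``survey``  — identity >= 0.70 and spacer coverage >= 0.85 (divergence survey)

Conventions
-----------
* A gap of length L scores ``gap_open + (L-1) * gap_extend`` (gap_open is the
  score of the first gap column).
* Identity = matched columns / total alignment columns, gap columns included
  in the denominator.
* Coverage = aligned query (spacer) positions / spacer length.
* E = K * m * n * exp(-lambda * S) with the ungapped Karlin-Altschul pair
  (lambda solved exactly; K estimated once per scheme, see ScoringScheme).
* N aligns as a mismatch against everything, including N.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .seqcore import Interval, SequenceRecord, revcomp

_EULER_GAMMA = 0.5772156649015329

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _sw_fill(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), -(10**9), dtype=np.int64)
    F = np.full((m + 1, n + 1), -(10**9), dtype=np.int64)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


@njit(cache=False)
def _sw_ungapped_max(q, s, match, mismatch):  # pragma: no cover - numba
    m = q.shape[0]
    n = s.shape[0]
    best = 0
    prev = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        qi = q[i - 1]
        cur = np.zeros(n + 1, dtype=np.int64)
        for j in range(1, n + 1):
            sub = match if qi == s[j - 1] else mismatch
            h = prev[j - 1] + sub
            if h < 0:
                h = 0
            cur[j] = h
            if h > best:
                best = h
        prev = cur
    return best


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_ENC[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"illegal character in sequence: {exc}") from exc


def solve_lambda(match: int, mismatch: int, p: float = 0.25) -> float:
    """Karlin-Altschul lambda: the positive root of sum p_i p_j exp(l*s_ij) = 1.

    Under uniform base frequencies the sum is p*exp(l*match) +
    (1-p)*exp(l*mismatch).
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 > mismatch")
    if p * match + (1 - p) * mismatch >= 0:
        raise ValueError("expected score per aligned pair must be negative")

    def f(lam: float) -> float:
        return p * math.exp(lam * match) + (1 - p) * math.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-9, hi, xtol=1e-12, rtol=1e-14))


@functools.lru_cache(maxsize=8)
def _calibrate_k(match: int, mismatch: int) -> float:
    """Estimate Karlin-Altschul K for the ungapped scheme.

    Gumbel-location fit: for random pairs, E[S_max] ~ (ln(K m n) + gamma) /
    lambda.  A fixed internal seed makes the estimate deterministic; accuracy
    is order-of-magnitude, which is what e-value thresholding needs here.
    """
    lam = solve_lambda(match, mismatch)
    rng = np.random.default_rng(1701)
    m = n = 400
    n_pairs = 400
    scores = np.empty(n_pairs, dtype=float)
    for t in range(n_pairs):
        q = rng.integers(0, 4, size=m).astype(np.int8)
        s = rng.integers(0, 4, size=n).astype(np.int8)
        scores[t] = _sw_ungapped_max(q, s, match, mismatch)
    k = math.exp(lam * scores.mean() - _EULER_GAMMA) / (m * n)
    return float(k)


@dataclass
class ScoringScheme:
    """Blastn-like scoring with precomputed Karlin-Altschul constants."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lambda_u: float = field(init=False)
    k_u: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap scores must be <= 0")
        self.lambda_u = solve_lambda(self.match, self.mismatch)
        self.k_u = _calibrate_k(self.match, self.mismatch)


@dataclass
class Alignment:
    """One optimal local alignment (coordinates 1-based inclusive)."""

    score: int
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    n_matches: int = 0
    n_columns: int = 0
    n_gap_columns: int = 0
    n_gap_opens: int = 0
    aligned_query: str = ""
    aligned_subject: str = ""

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0

    def coverage(self, query_len: int) -> float:
        if self.n_columns == 0:
            return 0.0
        q_aligned = self.q_end - self.q_start + 1
        return q_aligned / query_len


def _traceback(q: str, s: str, H, E, F, i: int, j: int, scheme: ScoringScheme) -> Alignment:
    score = int(H[i, j])
    aq: list[str] = []
    asub: list[str] = []
    state = "H"
    qi, sj = i, j
    while True:
        if state == "H":
            h = H[qi, sj]
            if h == 0:
                break
            sub = scheme.match if (q[qi - 1] == s[sj - 1] and q[qi - 1] != "N") else scheme.mismatch
            if qi > 0 and sj > 0 and h == H[qi - 1, sj - 1] + sub:
                aq.append(q[qi - 1])
                asub.append(s[sj - 1])
                qi -= 1
                sj -= 1
            elif h == E[qi, sj]:
                state = "E"
            elif h == F[qi, sj]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
        elif state == "E":  # gap in query, consume subject
            aq.append("-")
            asub.append(s[sj - 1])
            if E[qi, sj] == E[qi, sj - 1] + scheme.gap_extend:
                sj -= 1
            else:
                sj -= 1
                state = "H"
        else:  # state F: gap in subject, consume query
            aq.append(q[qi - 1])
            asub.append("-")
            if F[qi, sj] == F[qi - 1, sj] + scheme.gap_extend:
                qi -= 1
            else:
                qi -= 1
                state = "H"
    aqs = "".join(reversed(aq))
    asubs = "".join(reversed(asub))
    n_cols = len(aqs)
    n_matches = sum(1 for a, b in zip(aqs, asubs) if a == b and a != "-" and a != "N")
    n_gap_cols = sum(1 for a, b in zip(aqs, asubs) if a == "-" or b == "-")
    n_gap_opens = 0
    in_gap = False
    for a, b in zip(aqs, asubs):
        gap = a == "-" or b == "-"
        if gap and not in_gap:
            n_gap_opens += 1
        in_gap = gap
    return Alignment(
        score=score,
        q_start=qi + 1,
        q_end=i,
        s_start=sj + 1,
        s_end=j,
        n_matches=n_matches,
        n_columns=n_cols,
        n_gap_columns=n_gap_cols,
        n_gap_opens=n_gap_opens,
        aligned_query=aqs,
        aligned_subject=asubs,
    )


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None) -> Alignment:
    """Optimal affine-gap Smith-Waterman local alignment.

    Among equal-scoring alignments, the one with the smaller subject start,
    then smaller query start, is returned (end cells enumerated in
    subject-major order; traceback prefers diagonal over gaps).
    """
    if not query or not subject:
        raise ValueError("empty sequence in local_align")
    scheme = scheme or default_scheme()
    qv = _encode(query)
    sv = _encode(subject)
    H, E, F = _sw_fill(qv, sv, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    best = int(H.max())
    if best == 0:
        return Alignment(score=0)
    ii, jj = np.nonzero(H == best)
    order = np.lexsort((ii, jj))  # subject-end-major, then query end
    candidates = []
    for idx in order[:16]:
        candidates.append(_traceback(query, subject, H, E, F, int(ii[idx]), int(jj[idx]), scheme))
    candidates.sort(key=lambda a: (a.s_start, a.q_start))
    return candidates[0]


def evalue(score: int, query_len: int, subject_total_len: int, scheme: ScoringScheme) -> float:
    """Ungapped Karlin-Altschul expect value E = K m n exp(-lambda S)."""
    if query_len <= 0 or subject_total_len <= 0:
        raise ValueError("lengths must be positive")
    return scheme.k_u * query_len * subject_total_len * math.exp(-scheme.lambda_u * score)


@dataclass
class SpacerMatch:
    """A retained spacer-to-contig alignment."""

    spacer_id: str
    contig_id: str
    contig_interval: Interval
    identity: float
    aln_len: int
    coverage: float
    score: int
    evalue: float
    n_mismatches: int = 0
    n_gap_opens: int = 0
    q_start: int = 0
    q_end: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity out of [0,1]")
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage out of (0,1]")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")


MODES = ("strict", "survey")


def match_spacers(
    spacers: Sequence,
    contigs: Sequence[SequenceRecord],
    mode: str = "strict",
    scheme: ScoringScheme | None = None,
    strict_identity: float = 0.90,
    strict_evalue: float = 1e-5,
    survey_identity: float = 0.70,
    survey_coverage: float = 0.85,
) -> list[SpacerMatch]:
    """Align every spacer to every contig on both strands and filter by mode.

    ``spacers`` may be :class:`~phagebin.crispr.Spacer` objects or any objects
    with ``spacer_id``/``seq`` attributes.  All retained matches are reported.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if not spacers:
        raise ValueError("empty spacer set")
    scheme = scheme or default_scheme()
    n_total = sum(len(c.seq) for c in contigs)
    out: list[SpacerMatch] = []
    for sp in spacers:
        sp_id = getattr(sp, "spacer_id", None) or getattr(sp, "id")
        sp_seq = sp.seq
        for contig in contigs:
            for strand in ("+", "-"):
                q = sp_seq if strand == "+" else revcomp(sp_seq)
                aln = local_align(q, contig.seq, scheme)
                if aln.score == 0:
                    continue
                ident = aln.identity
                cov = aln.coverage(len(sp_seq))
                ev = evalue(aln.score, len(sp_seq), n_total, scheme)
                if mode == "strict":
                    keep = ident >= strict_identity and ev <= strict_evalue
                else:
                    keep = ident >= survey_identity and cov >= survey_coverage
                if not keep:
                    continue
                out.append(
                    SpacerMatch(
                        spacer_id=sp_id,
                        contig_id=contig.id,
                        contig_interval=Interval(contig.id, aln.s_start, aln.s_end, strand),
                        identity=ident,
                        aln_len=aln.n_columns,
                        coverage=cov,
                        score=aln.score,
                        evalue=ev,
                        n_mismatches=aln.n_columns - aln.n_matches - aln.n_gap_columns,
                        n_gap_opens=aln.n_gap_opens,
                        q_start=aln.q_start,
                        q_end=aln.q_end,
                    )
                )
    return out


def attribute_contig_hosts(
    matches: Iterable[SpacerMatch], spacer_hosts: Mapping[str, str]
):
    """Per-contig host vote table: counts of matching spacers per host label.

    Contigs without matches are absent; multi-host contigs keep all labels.
    Returns a pandas DataFrame (contig_id, host, n_matches).
    """
    import pandas as pd

    rows: dict[tuple[str, str], int] = {}
    for m in matches:
        host = spacer_hosts.get(m.spacer_id, "unknown")
        key = (m.contig_id, host)
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [(c, h, n) for (c, h), n in sorted(rows.items())],
        columns=["contig_id", "host", "n_matches"],
    )
    return df


def matches_to_outfmt6(matches: Iterable[SpacerMatch], path: str | Path) -> Path:
    """TSV mirroring BLAST outfmt 6 column order (score in the bitscore slot)."""
    path = Path(path)
    with open(path, "w") as fh:
        for m in matches:
            iv = m.contig_interval
            if iv.strand == "+":
                s_start, s_end = iv.start, iv.end
            else:
                s_start, s_end = iv.end, iv.start
            fh.write(
                "\t".join(
                    [
                        m.spacer_id,
                        m.contig_id,
                        f"{100 * m.identity:.2f}",
                        str(m.aln_len),
                        str(m.n_mismatches),
                        str(m.n_gap_opens),
                        str(m.q_start),
                        str(m.q_end),
                        str(s_start),
                        str(s_end),
                        f"{m.evalue:.2e}",
                        str(m.score),
                    ]
                )
                + "\n"
            )
    return path


@functools.lru_cache(maxsize=1)
def default_scheme() -> ScoringScheme:
    return ScoringScheme()
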