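"""Local alignment, e-values, and threshold regimes, checked against a
brute-force dynamic-programming oracle written independently of the
implementation (same scoring convention: a length-L gap costs
open + (L-1)*extend; local alignment may start/end anywhere)."""

import math

import numpy as np
import pytest

from conftest import random_dna
from phagebin import synth
from phagebin.crispr import Spacer
from phagebin.seqcore import SequenceRecord, revcomp
from phagebin.spacermatch import (
    ScoringScheme,
    default_scheme,
    evalue,
    local_align,
    match_spacers,
    solve_lambda,
)

NEG_INF = float("-inf")


def brute_force_score(q, s, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Plain-Python affine-gap Smith-Waterman best score (oracle)."""
    m, n = len(q), len(s)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    F = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


class TestLocalAlign:
    def test_identical_sequences_perfect(self):
        scheme = ScoringScheme(match=2, mismatch=-3)
        q = random_dna(np.random.default_rng(0), 36)
        aln = local_align(q, q, scheme)
        assert aln.score == 72
        assert aln.identity == 1.0
        assert (aln.q_start, aln.q_end) == (1, 36)

    def test_three_substitutions_identity(self):
        rng = np.random.default_rng(1)
        q = random_dna(rng, 36)
        s = list(q)
        for pos in (5, 15, 25):
            s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
        s = "".join(s)
        aln = local_align(q, s, default_scheme())
        # gapless optimum spans the full 36 columns with 33 matches
        assert aln.n_columns == 36
        assert aln.n_matches == 33
        assert aln.identity == pytest.approx(33 / 36)
        assert aln.score == brute_force_score(q, s)

    def test_no_positive_pair_gives_empty(self):
        aln = local_align("AAAA", "CCCC", default_scheme())
        assert aln.score == 0
        assert aln.n_columns == 0
        assert aln.identity == 0.0

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_oracle_equivalence_200_random_pairs(self):
        """Exact score agreement with the brute-force DP on 200 pairs <= 60 nt."""
        rng = np.random.default_rng(42)
        scheme = default_scheme()
        for _ in range(200):
            q = random_dna(rng, int(rng.integers(5, 61)))
            s = random_dna(rng, int(rng.integers(5, 61)))
            assert local_align(q, s, scheme).score == brute_force_score(q, s)


class TestScoringScheme:
    def test_lambda_matches_closed_form(self):
        """For +1/-2 under uniform bases, exp(lambda) solves x^3-4x^2+3=0."""
        lam = solve_lambda(1, -2)
        assert lam == pytest.approx(math.log((3 + math.sqrt(21)) / 2), abs=1e-9)
        scheme = ScoringScheme()
        assert scheme.lambda_u == pytest.approx(lam)
        # lambda satisfies its defining equation
        p = 0.25
        assert p * math.exp(lam * 1) + (1 - p) * math.exp(lam * -2) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=-1, mismatch=-2)
        with pytest.raises(ValueError):
            ScoringScheme(match=1, mismatch=1)


class TestEvalue:
    def test_linear_in_subject_length(self):
        scheme = default_scheme()
        e1 = evalue(30, 36, 10_000, scheme)
        e2 = evalue(30, 36, 20_000, scheme)
        assert e2 == pytest.approx(2 * e1)

    def test_decreasing_in_score(self):
        scheme = default_scheme()
        es = [evalue(s, 36, 10_000, scheme) for s in range(10, 40)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_positive_length_required(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, default_scheme())


class TestMatchSpacers:
    def _contig_with_protospacer(self, rng, spacer, minus=False, flank=400):
        insert = revcomp(spacer) if minus else spacer
        seq = random_dna(rng, flank) + insert + random_dna(rng, flank)
        return SequenceRecord(id="c1", seq=seq), flank + 1, flank + len(spacer)

    def test_minus_strand_exact_match(self):
        rng = np.random.default_rng(7)
        spacer = Spacer(spacer_id="sp1", seq=random_dna(rng, 36), host_label="H")
        contig, start, end = self._contig_with_protospacer(rng, spacer.seq, minus=True)
        matches = match_spacers([spacer], [contig], mode="strict")
        exact = [m for m in matches if m.identity == 1.0 and m.coverage == 1.0]
        assert len(exact) == 1
        m = exact[0]
        assert m.contig_interval.strand == "-"
        assert (m.contig_interval.start, m.contig_interval.end) == (start, end)

    def test_divergent_spacer_rejected_in_both_modes(self):
        rng = np.random.default_rng(8)
        base = random_dna(rng, 36)
        mutated = list(base)
        for pos in rng.choice(36, size=11, replace=False):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        contig = SequenceRecord(id="c", seq=random_dna(rng, 300) + "".join(mutated) + random_dna(rng, 300))
        spacer = Spacer(spacer_id="s", seq=base, host_label="H")
        for mode in ("strict", "survey"):
            for m in match_spacers([spacer], [contig], mode=mode):
                # 25/36 identity fails both regimes; anything retained must be
                # a chance hit satisfying its mode's thresholds
                if mode == "strict":
                    assert m.identity >= 0.90 and m.evalue <= 1e-5
                else:
                    assert m.identity >= 0.70 and m.coverage >= 0.85

    def test_absent_spacer_no_matches(self):
        rng = np.random.default_rng(9)
        spacer = Spacer(spacer_id="s", seq=random_dna(rng, 36), host_label="H")
        contig = SequenceRecord(id="c", seq=random_dna(np.random.default_rng(10), 800))
        assert match_spacers([spacer], [contig], mode="strict") == []

    def test_unknown_mode_and_empty_spacers(self):
        with pytest.raises(ValueError):
            match_spacers([], [], mode="strict")
        rng = np.random.default_rng(11)
        sp = Spacer(spacer_id="s", seq=random_dna(rng, 36))
        with pytest.raises(ValueError):
            match_spacers([sp], [], mode="blast")

    def test_strand_symmetry(self):
        """Matching s on strand '-' equals matching revcomp(s) on strand '+'."""
        rng = np.random.default_rng(12)
        spacer_seq = random_dna(rng, 36)
        contig, *_ = self._contig_with_protospacer(rng, spacer_seq, minus=True)
        fwd = match_spacers([Spacer(spacer_id="a", seq=revcomp(spacer_seq))], [contig], mode="strict")
        rev = match_spacers([Spacer(spacer_id="a", seq=spacer_seq)], [contig], mode="strict")
        assert {(m.contig_interval.start, m.contig_interval.end, m.score) for m in fwd} == {
            (m.contig_interval.start, m.contig_interval.end, m.score) for m in rev
        }

    def test_thresholds_never_violated(self):
        rng = np.random.default_rng(13)
        spacers = [Spacer(spacer_id=f"s{i}", seq=random_dna(rng, 36)) for i in range(5)]
        contigs = [SequenceRecord(id=f"c{i}", seq=random_dna(rng, 600)) for i in range(3)]
        # plant one exact protospacer
        contigs[0] = SequenceRecord(id="c0", seq=contigs[0].seq + spacers[0].seq)
        for mode in ("strict", "survey"):
            for m in match_spacers(spacers, contigs, mode=mode):
                if mode == "strict":
                    assert m.identity >= 0.90 and m.evalue <= 1e-5
                else:
                    assert m.identity >= 0.70 and m.coverage >= 0.85

    def test_planted_recovery_mutation_sweep(self):
        """Strict recall is 1.0 without mutation; survey recall >= strict with 5% divergence."""
        n_strict0 = n_total = 0
        strict_hits_mut = survey_hits_mut = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            spacer_seq = random_dna(rng, 36)
            contig = SequenceRecord(
                id="c", seq=random_dna(rng, 150) + spacer_seq + random_dna(rng, 150)
            )
            sp = Spacer(spacer_id="s", seq=spacer_seq)
            n_total += 1
            if any(
                m.identity == 1.0 for m in match_spacers([sp], [contig], mode="strict")
            ):
                n_strict0 += 1
            mutated = synth.mutate(spacer_seq, 0.05, seed=rep)
            contig_mut = SequenceRecord(
                id="c", seq=contig.seq.replace(spacer_seq, mutated)
            )
            strict_hits_mut += bool(match_spacers([sp], [contig_mut], mode="strict"))
            survey_hits_mut += bool(match_spacers([sp], [contig_mut], mode="survey"))
        assert n_strict0 == n_total
        assert survey_hits_mut >= strict_hits_mut
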