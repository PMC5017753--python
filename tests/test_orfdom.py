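"""Six-frame ORF calling vs a brute-force oracle; domtblout ingestion; architectures."""

import numpy as np
import pytest

from conftest import DOMTBLOUT_HEADER, domtblout_row, random_dna
from phagebin.orfdom import (
    DomainHit,
    ToolUnavailableError,
    catalog_role,
    domain_architecture,
    find_orfs,
    parse_domtblout,
    run_hmmsearch_wrapper,
)
from phagebin.seqcore import SequenceRecord, revcomp

_CODON = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_orfs(seq: str, minsize: int = 300) -> set[tuple[int, int, str]]:
    """Brute-force six-frame stop-to-stop ORFs as (start, end, strand) 1-based."""
    out = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        L = len(s)
        for off in range(3):
            codons = [s[i : i + 3] for i in range(off, L - 2, 3)]
            run_start = 0  # codon index where current stop-free run begins
            i = 0
            for i, codon in enumerate(codons + ["TAA"]):  # sentinel stop at end
                aa = _CODON.get(codon, "X") if len(codon) == 3 else "*"
                if aa == "*":
                    n = i - run_start
                    if 3 * n >= minsize:
                        nt_start0 = off + 3 * run_start
                        nt_end0 = off + 3 * i
                        if strand == "+":
                            out.add((nt_start0 + 1, nt_end0, "+"))
                        else:
                            out.add((L - nt_end0 + 1, L - nt_start0, "-"))
                    run_start = i + 1
    return out


class TestFindOrfs:
    def test_poly_a_six_frames(self):
        orfs = find_orfs(SequenceRecord(id="p", seq="A" * 1000))
        assert len(orfs) == 6
        assert sorted(o.nt_len for o in orfs) == [996, 996, 999, 999, 999, 999]

    def test_constructed_stop_bounded_orf(self):
        rng = np.random.default_rng(50)
        middle = "".join(
            rng.choice([c for c, aa in _CODON.items() if aa != "*"]) for _ in range(100)
        )
        seq = "TAA" + middle + "TAG"
        orfs = [o for o in find_orfs(SequenceRecord(id="c", seq=seq)) if o.frame == 1]
        assert len(orfs) == 1
        assert orfs[0].nt_len == 300
        assert (orfs[0].interval.start, orfs[0].interval.end) == (4, 303)

    def test_below_minsize_yields_nothing(self):
        seq = "AAA" * 99 + "TT"  # 299 stop-free nt in frame 1, shorter elsewhere
        orfs = find_orfs(SequenceRecord(id="c", seq=seq[:299]), minsize=300)
        assert orfs == []

    def test_invariants(self):
        rng = np.random.default_rng(51)
        orfs = find_orfs(SequenceRecord(id="c", seq=random_dna(rng, 3000)), minsize=150)
        for o in orfs:
            assert o.nt_len % 3 == 0
            assert o.nt_len == 3 * len(o.protein)
            assert "*" not in o.protein

    def test_oracle_equivalence_100_random_contigs(self):
        """Exact agreement with the brute-force six-frame oracle on 2 kb contigs."""
        rng = np.random.default_rng(52)
        for i in range(100):
            seq = random_dna(rng, 2000)
            got = {
                (o.interval.start, o.interval.end, o.interval.strand)
                for o in find_orfs(SequenceRecord(id=f"c{i}", seq=seq), minsize=300)
            }
            assert got == oracle_orfs(seq, minsize=300)

    def test_strand_mirror(self):
        rng = np.random.default_rng(53)
        seq = random_dna(rng, 1500)
        L = len(seq)
        fwd = {
            (o.interval.start, o.interval.end, o.interval.strand)
            for o in find_orfs(SequenceRecord(id="a", seq=seq), minsize=150)
        }
        rev = {
            (L - e + 1, L - s + 1, "+" if st == "-" else "-")
            for s, e, st in (
                (o.interval.start, o.interval.end, o.interval.strand)
                for o in find_orfs(SequenceRecord(id="b", seq=revcomp(seq)), minsize=150)
            )
        }
        assert fwd == rev


class TestDomtblout:
    def test_parse_well_formed_rows(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(
            DOMTBLOUT_HEADER
            + domtblout_row("orf1", "Glyco_hydro_108", "PF05838.10")
            + domtblout_row("orf2", "Methyltransf_26", "PF13659.9")
        )
        hits = parse_domtblout(p)
        assert len(hits) == 2
        assert hits[0].role == "catalytic"
        assert hits[1].role == "other"
        assert hits[0].ali_interval == (5, 90)

    def test_truncated_row_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.domtblout"
        p.write_text(domtblout_row("orf1", "CHAP", "PF05257.19") + "orf2 - 200 CHAP\n")
        with pytest.raises(ValueError, match=":2"):
            parse_domtblout(p)

    def test_catalog_roles(self):
        assert catalog_role("Glyco_hydro_108") == "catalytic"
        assert catalog_role("PG_binding_3") == "binding"
        assert catalog_role("portal") == "control"
        assert catalog_role("Unknown_domain") == "other"
        # accession fallback
        assert catalog_role("someothername", "PF05838.10") == "catalytic"


class TestDomainArchitecture:
    def _hit(self, name, ali, score, orf="orf1"):
        return DomainHit(
            orf_id=orf,
            name=name,
            accession="-",
            score=score,
            evalue=1e-10,
            ali_interval=ali,
            role=catalog_role(name),
        )

    def test_canonical_catalytic_plus_binding(self):
        arch = domain_architecture(
            [self._hit("Glyco_hydro_108", (5, 60), 80), self._hit("PG_binding_3", (80, 140), 60)]
        )
        assert arch.string == "Glyco_hydro_108+PG_binding_3"
        assert arch.canonical_endolysin

    def test_single_catalytic_not_canonical(self):
        arch = domain_architecture([self._hit("Amidase_5", (10, 90), 70)])
        assert not arch.canonical_endolysin

    def test_overlap_resolved_by_score(self):
        arch = domain_architecture(
            [self._hit("CHAP", (10, 80), 40), self._hit("SLT", (50, 120), 60)]
        )
        assert arch.string == "SLT"

    def test_mixed_orfs_rejected(self):
        with pytest.raises(ValueError):
            domain_architecture(
                [self._hit("CHAP", (1, 50), 40), self._hit("SLT", (1, 50), 50, orf="orf2")]
            )


class TestHmmsearchWrapper:
    def test_tool_unavailable_contract(self, monkeypatch, tmp_path):
        rng = np.random.default_rng(60)
        orfs = find_orfs(SequenceRecord(id="c", seq=random_dna(rng, 2000)), minsize=150)
        monkeypatch.setenv("PATH", str(tmp_path))  # no executables here
        with pytest.raises(ToolUnavailableError, match="parse_domtblout"):
            run_hmmsearch_wrapper(orfs, tmp_path / "toy.hmm")

    def test_empty_orf_list_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="nothing to search"):
            run_hmmsearch_wrapper([], tmp_path / "toy.hmm")
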