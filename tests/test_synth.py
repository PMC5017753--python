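"""Synthetic community generator: determinism, signatures, planted truth."""

import numpy as np
import pytest

from conftest import random_dna
from phagebin import crispr, synth, tnf
from phagebin.seqcore import Interval, SequenceRecord


class TestMakeModel:
    def test_deterministic(self):
        a = synth.make_model(5)
        b = synth.make_model(5)
        assert (a.probs == b.probs).all()

    def test_bias_zero_is_near_uniform(self):
        m = synth.make_model(1, bias=0.0)
        assert np.abs(m.probs - 0.25).max() <= 1e-12

    def test_rows_are_distributions(self):
        m = synth.make_model(2, bias=0.9)
        assert np.allclose(m.probs.sum(axis=1), 1.0)
        assert (m.probs >= 0).all()

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            synth.make_model(1, order=0)


class TestGenGenome:
    def test_exact_length_and_determinism(self):
        m = synth.make_model(3)
        g1 = synth.gen_genome(m, 5000, seed=1)
        g2 = synth.gen_genome(m, 5000, seed=1)
        assert len(g1.seq) == 5000
        assert g1.seq == g2.seq
        assert synth.gen_genome(m, 5000, seed=2).seq != g1.seq

    def test_length_below_order_rejected(self):
        m = synth.make_model(3)
        with pytest.raises(ValueError):
            synth.gen_genome(m, 2, seed=0)

    def test_distinct_models_separate_in_tnf_space(self):
        """Between-host TNF distance of 5 kb fragments exceeds within-host."""
        mA, mB = synth.make_model(10, bias=0.8), synth.make_model(11, bias=0.8)
        fragsA = [synth.gen_genome(mA, 5000, seed=s, rec_id=f"a{s}") for s in range(6)]
        fragsB = [synth.gen_genome(mB, 5000, seed=s + 100, rec_id=f"b{s}") for s in range(6)]
        profA = np.vstack([tnf.tnf_profile(f).freqs for f in fragsA])
        profB = np.vstack([tnf.tnf_profile(f).freqs for f in fragsB])
        within = np.mean(
            [np.linalg.norm(profA[i] - profA[j]) for i in range(6) for j in range(i + 1, 6)]
        )
        between = np.mean(
            [np.linalg.norm(a - b) for a in profA for b in profB]
        )
        assert between > within


class TestMutate:
    def test_rate_zero_identity(self):
        s = random_dna(np.random.default_rng(0), 100)
        assert synth.mutate(s, 0.0, seed=1) == s

    def test_rate_one_changes_every_base(self):
        s = random_dna(np.random.default_rng(1), 200)
        mutated = synth.mutate(s, 1.0, seed=2)
        assert all(a != b for a, b in zip(s, mutated))

    def test_binomial_expectation_at_8pct(self):
        """Mean identity of mutated 36-mers is ~0.92 over 1000 replicates."""
        rng = np.random.default_rng(3)
        idents = []
        for rep in range(1000):
            s = random_dna(rng, 36)
            m = synth.mutate(s, 0.08, seed=rep)
            idents.append(sum(a == b for a, b in zip(s, m)) / 36)
        assert abs(np.mean(idents) - 0.92) <= 0.01

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            synth.mutate("ACGT", 1.5, seed=0)


class TestImplantCrispr:
    def _setup(self, rng):
        host = SequenceRecord(id="h", seq=random_dna(rng, 5000))
        phages = [SequenceRecord(id=f"p{i}", seq=random_dna(rng, 1500)) for i in range(3)]
        repeat = random_dna(rng, 30)
        return host, phages, repeat

    def test_locus_structure_and_detector_roundtrip(self):
        rng = np.random.default_rng(20)
        host, phages, repeat = self._setup(rng)
        modified, truth = synth.implant_crispr(host, phages, 3, repeat, seed=5)
        assert len(truth.spacers) == 3
        assert len(modified.seq) == len(host.seq) + 4 * 30 + 3 * 36
        (arr,) = crispr.find_arrays(modified)
        assert arr.n_repeats == 4
        assert [s for _, s in arr.spacers] == [t["seq"] for t in truth.spacers]

    def test_too_few_spacers_rejected(self):
        rng = np.random.default_rng(21)
        host, phages, repeat = self._setup(rng)
        with pytest.raises(ValueError):
            synth.implant_crispr(host, phages, 0, repeat, seed=0)
        with pytest.raises(ValueError):
            synth.implant_crispr(host, phages, 1, repeat, seed=0)

    def test_deterministic(self):
        rng = np.random.default_rng(22)
        host, phages, repeat = self._setup(rng)
        a, _ = synth.implant_crispr(host, phages, 3, repeat, seed=9)
        b, _ = synth.implant_crispr(host, phages, 3, repeat, seed=9)
        assert a.seq == b.seq


class TestMakeCommunity:
    def test_deterministic_and_structure(self, default_bundle):
        again = synth.make_community()
        assert [h.seq for h in again.hosts] == [h.seq for h in default_bundle.hosts]
        assert [c.seq for c in again.contigs] == [c.seq for c in default_bundle.contigs]
        cfg = default_bundle.config
        assert len(default_bundle.hosts) == cfg.n_hosts
        assert len(default_bundle.contigs) == cfg.n_hosts * cfg.n_phages_per_host + cfg.n_free_phages

    def test_free_phages_in_manifest(self, default_bundle):
        parents = {p["parent"] for p in default_bundle.manifest.phages}
        assert "free" in parents
        n_free = sum(1 for p in default_bundle.manifest.phages if p["parent"] == "free")
        assert n_free == default_bundle.config.n_free_phages

    def test_manifest_referential_integrity(self, default_bundle):
        """Every truth spacer equals its protospacer window on the phage (mutation 0)."""
        contig_by_id = {c.id: c for c in default_bundle.contigs}
        proto_by_spacer = {t["spacer_id"]: t for t in default_bundle.manifest.protospacers}
        assert set(proto_by_spacer) == {t["spacer_id"] for t in default_bundle.manifest.spacers}
        for t in default_bundle.manifest.spacers:
            proto = proto_by_spacer[t["spacer_id"]]
            phage = contig_by_id[proto["phage_id"]]
            window = Interval(phage.id, proto["start"], proto["end"]).slice(phage.seq)
            assert window == t["seq"]

    def test_manifest_round_trip(self, default_bundle, tmp_path):
        p = default_bundle.manifest.write(tmp_path / "truth.tsv")
        back = synth.TruthManifest.read(p)
        assert back.hosts == default_bundle.manifest.hosts
        assert back.spacers == default_bundle.manifest.spacers
        assert back.protospacers == default_bundle.manifest.protospacers

    def test_bundle_write(self, default_bundle, tmp_path):
        paths = default_bundle.write(tmp_path / "bundle")
        for key in ("hosts", "contigs", "manifest", "host_repeats"):
            assert paths[key].exists()


class TestSimulateReads:
    def test_mean_read_length(self):
        rng = np.random.default_rng(30)
        seqs = [SequenceRecord(id="g", seq=random_dna(rng, 50_000))]
        sim = synth.simulate_reads(seqs, mean_len=359, seed=1, reads_per_unit_depth=60.0)
        lengths = [len(r.seq) for r in sim.reads if len(r.seq) >= 40]
        assert len(lengths) > 5000
        # interior reads only (edge reads are truncated by the sequence end)
        assert abs(np.mean(lengths) - 359) / 359 < 0.05

    def test_sigma_zero_uniform_depth(self):
        rng = np.random.default_rng(31)
        seqs = [SequenceRecord(id="g", seq=random_dna(rng, 20_000))]
        sim = synth.simulate_reads(seqs, coverage_sigma=0.0, seed=2)
        depth = sim.window_depths["g"]
        assert depth.max() / depth.min() <= 1.5

    def test_deterministic(self):
        rng = np.random.default_rng(32)
        seqs = [SequenceRecord(id="g", seq=random_dna(rng, 10_000))]
        a = synth.simulate_reads(seqs, seed=3)
        b = synth.simulate_reads(seqs, seed=3)
        assert [r.seq for r in a.reads] == [r.seq for r in b.reads]
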