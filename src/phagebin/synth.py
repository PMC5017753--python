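"""Synthetic phage/host community generator with a machine-readable truth.

Host genomes are drawn from distinct order-3 Markov chains: an order-3 model
fixes the conditional probability of every base given its 3-mer context, and
therefore controls tetranucleotide statistics directly — exactly the feature
space the binner clusters on, which makes TNF separability tunable through a
single ``bias`` knob.  Host-derived phage contigs reuse their host's chain
(shared compositional signature); "free" phage contigs come from one extra
chain of their own and emulate a phage group with no sampled host.

CRISPR arrays are implanted into host genomes as repeat-(spacer-repeat)xN
loci whose spacers are exact copies of protospacer windows sampled from that
host's phage contigs; an optional per-base substitution rate then emulates
protospacer divergence.  Every coordinate is recorded in a TruthManifest so
each pipeline stage can be scored against planted truth.

All generators are pure functions of their seed: child seeds are spawned
deterministically from the community seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqcore import Interval, SequenceRecord, write_fasta

_BASES = "ACGT"


@dataclass
class MarkovModel:
    """Order-k Markov chain over ACGT."""

    order: int
    probs: np.ndarray  # (4**order, 4), rows sum to 1
    seed: int

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.probs.shape != (4**self.order, 4):
            raise ValueError("probs shape mismatch")
        if (self.probs < 0).any() or not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("rows must be probability distributions")


def make_model(seed: int, order: int = 3, bias: float = 0.75) -> MarkovModel:
    """Dirichlet-sampled conditionals blended towards uniform by (1 - bias).

    ``bias`` in [0, 1]: 0 gives the uniform chain, 1 a fully Dirichlet(1)
    sampled one; higher bias means a more distinctive signature.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not (0.0 <= bias <= 1.0):
        raise ValueError("bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dirichlet = rng.dirichlet(np.ones(4), size=4**order)
    probs = (1.0 - bias) * 0.25 + bias * dirichlet
    return MarkovModel(order=order, probs=probs, seed=seed)


def gen_genome(model: MarkovModel, length: int, seed: int, rec_id: str = "genome") -> SequenceRecord:
    """Sample a sequence of exactly ``length`` nt from the chain."""
    if length < model.order:
        raise ValueError(f"length {length} < order {model.order}")
    rng = np.random.default_rng(seed)
    k = model.order
    out = list(rng.integers(0, 4, size=k))
    ctx = 0
    for b in out:
        ctx = ctx * 4 + int(b)
    cum = model.probs.cumsum(axis=1)
    mod = 4 ** (k - 1)
    u = rng.random(length - k)
    for i in range(length - k):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        b = min(b, 3)
        out.append(b)
        ctx = (ctx % mod) * 4 + b
    seq = "".join(_BASES[b] for b in out)
    return SequenceRecord(id=rec_id, seq=seq)


def mutate(seq: str, rate: float, seed: int) -> str:
    """I.i.d. substitutions to a uniformly chosen *different* base."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0 or not seq:
        return seq
    rng = np.random.default_rng(seed)
    hit = rng.random(len(seq)) < rate
    out = list(seq)
    for i in np.nonzero(hit)[0]:
        old = out[i]
        choices = [b for b in _BASES if b != old]
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


@dataclass
class TruthManifest:
    """Ground truth of a generated community (TSV-sections text format)."""

    hosts: list[dict] = field(default_factory=list)
    phages: list[dict] = field(default_factory=list)
    protospacers: list[dict] = field(default_factory=list)
    spacers: list[dict] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        sections = [
            ("hosts", ["id", "model_seed", "genome_length", "array_start", "array_end"], self.hosts),
            ("phages", ["id", "parent", "length"], self.phages),
            ("protospacers", ["phage_id", "start", "end", "spacer_id"], self.protospacers),
            ("spacers", ["host_id", "spacer_id", "seq"], self.spacers),
        ]
        with open(path, "w") as fh:
            for name, cols, rows in sections:
                fh.write(f"#section {name}\n")
                fh.write("\t".join(cols) + "\n")
                for row in rows:
                    fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "TruthManifest":
        manifest = cls()
        section = None
        cols: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#section "):
                    section = line.split(" ", 1)[1]
                    cols = []
                    continue
                if not cols:
                    cols = line.split("\t")
                    continue
                row = dict(zip(cols, line.split("\t")))
                for key in ("model_seed", "genome_length", "array_start", "array_end", "length", "start", "end"):
                    if key in row:
                        row[key] = int(row[key])
                getattr(manifest, section).append(row)
        return manifest


def implant_crispr(
    host: SequenceRecord,
    phages: Sequence[SequenceRecord],
    n_spacers: int,
    repeat_seq: str,
    spacer_len: int = 36,
    position: int | None = None,
    seed: int = 0,
) -> tuple[SequenceRecord, TruthManifest]:
    """Insert a repeat-(spacer-repeat)xN locus sampling protospacers from phages.

    The locus carries ``n_spacers`` spacers and ``n_spacers + 1`` repeats.
    ``position`` is the 0-based insertion offset in the host sequence
    (default: seeded random).  Returns the modified host record and the truth
    entries (protospacer coordinates are 1-based inclusive on the phage).
    """
    if n_spacers < 2:
        raise ValueError("n_spacers must be >= 2 (a detectable array needs >= 3 repeats)")
    if not (23 <= len(repeat_seq) <= 55):
        raise ValueError("repeat length must lie within the detector bounds [23, 55]")
    usable = [p for p in phages if len(p.seq) >= spacer_len]
    if not usable:
        raise ValueError("no phage sequence long enough to sample protospacers")
    rng = np.random.default_rng(seed)
    truth = TruthManifest()
    # Resample until the spacer set leaves the repeat boundary unambiguous:
    # if every spacer started (or ended) with the same base, that conserved
    # column would genuinely belong to the repeat and any detector would
    # shift the boundary, so such degenerate sets are excluded.
    for _attempt in range(200):
        picks: list[tuple[SequenceRecord, int]] = []
        chosen: set[tuple[str, int]] = set()
        for _i in range(n_spacers):
            for _ in range(1000):
                phage = usable[int(rng.integers(0, len(usable)))]
                start0 = int(rng.integers(0, len(phage.seq) - spacer_len + 1))
                if (phage.id, start0) not in chosen:
                    chosen.add((phage.id, start0))
                    picks.append((phage, start0))
                    break
            else:  # pragma: no cover
                raise ValueError("could not sample distinct protospacer windows")
        seqs = [p.seq[s : s + spacer_len] for p, s in picks]
        if len({s[0] for s in seqs}) > 1 and len({s[-1] for s in seqs}) > 1:
            break
    else:  # pragma: no cover
        raise ValueError("could not sample a boundary-unambiguous spacer set")
    spacer_parts: list[str] = []
    for i, (phage, start0) in enumerate(picks):
        spacer = phage.seq[start0 : start0 + spacer_len]
        spacer_id = f"{host.id}-SP-{i + 1}"
        truth.protospacers.append(
            {"phage_id": phage.id, "start": start0 + 1, "end": start0 + spacer_len, "spacer_id": spacer_id}
        )
        truth.spacers.append({"host_id": host.id, "spacer_id": spacer_id, "seq": spacer})
        spacer_parts.append(spacer)
    locus = repeat_seq + "".join(s + repeat_seq for s in spacer_parts)
    if position is None:
        position = int(rng.integers(0, len(host.seq) + 1))
    if not (0 <= position <= len(host.seq)):
        raise ValueError("position outside host sequence")
    new_seq = host.seq[:position] + locus + host.seq[position:]
    truth.hosts.append(
        {
            "id": host.id,
            "model_seed": -1,
            "genome_length": len(new_seq),
            "array_start": position + 1,
            "array_end": position + len(locus),
        }
    )
    return SequenceRecord(id=host.id, seq=new_seq, description=host.description), truth


@dataclass
class CommunityConfig:
    """Study conditions for the default synthetic community."""

    n_hosts: int = 3
    n_phages_per_host: int = 60
    n_free_phages: int = 20
    host_genome_len: int = 60_000
    contig_len_range: tuple[int, int] = (1200, 4000)
    n_spacers: int = 5
    spacer_len: int = 36
    repeat_len: int = 30
    mutation_rate: float = 0.0
    order: int = 3
    bias: float = 0.75
    seed: int = 7

    def validate(self) -> None:
        if self.n_hosts < 1:
            raise ValueError("n_hosts must be >= 1")
        if self.contig_len_range[0] > self.contig_len_range[1]:
            raise ValueError("invalid contig_len_range")
        if self.contig_len_range[0] < self.spacer_len:
            raise ValueError("contigs shorter than a spacer")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate outside [0, 1]")
        if not (23 <= self.repeat_len <= 55):
            raise ValueError("repeat_len outside detector bounds")


@dataclass
class CommunityBundle:
    """Generated hosts, phage contigs, spacer truth, and manifest."""

    config: CommunityConfig
    hosts: list[SequenceRecord]
    contigs: list[SequenceRecord]
    manifest: TruthManifest
    host_repeats: dict[str, str]

    def truth_label(self, contig_id: str) -> str:
        for p in self.manifest.phages:
            if p["id"] == contig_id:
                return p["parent"]
        raise KeyError(contig_id)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hosts": write_fasta(self.hosts, outdir / "hosts.fasta"),
            "contigs": write_fasta(self.contigs, outdir / "contigs.fasta"),
            "manifest": self.manifest.write(outdir / "truth_manifest.tsv"),
        }
        with open(outdir / "host_repeats.tsv", "w") as fh:
            fh.write("host_id\trepeat_seq\n")
            for h, r in self.host_repeats.items():
                fh.write(f"{h}\t{r}\n")
        paths["host_repeats"] = outdir / "host_repeats.tsv"
        return paths


def _random_repeat(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=length))


def make_community(config: CommunityConfig | None = None) -> CommunityBundle:
    """Generate the full synthetic community under the given conditions."""
    config = config or CommunityConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # fixed layout: 0 misc, 1 free model, 2 free contigs, 3 mutation,
    # then 4 per host (model, genome, phage contigs, implant)
    n_children = 4 + 4 * config.n_hosts
    children = root.spawn(n_children)

    def child_seed(i: int) -> int:
        return int(children[i].generate_state(1)[0] % (2**31 - 1))

    manifest = TruthManifest()
    hosts: list[SequenceRecord] = []
    contigs: list[SequenceRecord] = []
    host_repeats: dict[str, str] = {}
    rng_misc = np.random.default_rng(child_seed(0))

    lo, hi = config.contig_len_range
    idx = 1
    host_phages: dict[str, list[SequenceRecord]] = {}
    for h in range(config.n_hosts):
        model_seed = child_seed(4 + 4 * h)
        genome_seed = child_seed(5 + 4 * h)
        phage_seed = child_seed(6 + 4 * h)
        model = make_model(model_seed, order=config.order, bias=config.bias)
        host_id = f"host{h + 1}"
        genome = gen_genome(model, config.host_genome_len, genome_seed, rec_id=host_id)
        prng = np.random.default_rng(phage_seed)
        phages = []
        for _ in range(config.n_phages_per_host):
            length = int(prng.integers(lo, hi + 1))
            phages.append(
                gen_genome(model, length, int(prng.integers(0, 2**31 - 1)), rec_id=f"NODE_{idx}")
            )
            idx += 1
        host_phages[host_id] = phages
        for p in phages:
            manifest.phages.append({"id": p.id, "parent": host_id, "length": len(p.seq)})
        hosts.append(genome)
        for m in [{"id": host_id, "model_seed": model_seed, "genome_length": len(genome.seq), "array_start": 0, "array_end": 0}]:
            manifest.hosts.append(m)
        contigs.extend(phages)

    free_model = make_model(child_seed(1), order=config.order, bias=config.bias)
    frng = np.random.default_rng(child_seed(2))
    for _ in range(config.n_free_phages):
        length = int(frng.integers(lo, hi + 1))
        p = gen_genome(free_model, length, int(frng.integers(0, 2**31 - 1)), rec_id=f"NODE_{idx}")
        idx += 1
        manifest.phages.append({"id": p.id, "parent": "free", "length": len(p.seq)})
        contigs.append(p)

    # implant arrays, then optionally diverge the phage protospacers
    new_hosts = []
    for h, genome in enumerate(hosts):
        host_id = genome.id
        repeat = _random_repeat(rng_misc, config.repeat_len)
        host_repeats[host_id] = repeat
        implant_seed = child_seed(7 + 4 * h)
        modified, truth = implant_crispr(
            genome,
            host_phages[host_id],
            n_spacers=config.n_spacers,
            repeat_seq=repeat,
            spacer_len=config.spacer_len,
            position=None,
            seed=implant_seed,
        )
        new_hosts.append(modified)
        manifest.protospacers.extend(truth.protospacers)
        manifest.spacers.extend(truth.spacers)
        for entry in manifest.hosts:
            if entry["id"] == host_id:
                entry["genome_length"] = truth.hosts[0]["genome_length"]
                entry["array_start"] = truth.hosts[0]["array_start"]
                entry["array_end"] = truth.hosts[0]["array_end"]

    if config.mutation_rate > 0:
        mrng = np.random.default_rng(child_seed(3))  # reserved mutation stream
        contigs = [
            SequenceRecord(
                id=c.id,
                seq=mutate(c.seq, config.mutation_rate, int(mrng.integers(0, 2**31 - 1))),
                description=c.description,
            )
            for c in contigs
        ]

    return CommunityBundle(
        config=config,
        hosts=new_hosts,
        contigs=contigs,
        manifest=manifest,
        host_repeats=host_repeats,
    )


@dataclass
class SimulatedReads:
    reads: list[SequenceRecord]
    window_depths: dict[str, np.ndarray]


def simulate_reads(
    seqs: Sequence[SequenceRecord],
    mean_len: float = 359.0,
    coverage_mu: float = 1.0,
    coverage_sigma: float = 1.0,
    seed: int = 0,
    window: int = 1000,
    reads_per_unit_depth: float = 1.0,
) -> SimulatedReads:
    """Reads with MDA-style lognormal per-window depth bias (optional stage).

    Read lengths ~ Normal(mean_len, 0.2 * mean_len) truncated at 40 nt; the
    number of reads starting in each ``window``-nt window is proportional to
    a lognormal(coverage_mu, coverage_sigma) depth.  Deterministic per seed.
    """
    if mean_len <= 40 or coverage_sigma < 0 or window <= 0:
        raise ValueError("invalid parameters")
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    depths: dict[str, np.ndarray] = {}
    n = 0
    for rec in seqs:
        n_windows = max(1, len(rec.seq) // window)
        if coverage_sigma == 0:
            depth = np.full(n_windows, np.exp(coverage_mu))
        else:
            depth = rng.lognormal(coverage_mu, coverage_sigma, size=n_windows)
        depths[rec.id] = depth
        for w in range(n_windows):
            w_start = w * window
            w_len = min(window, len(rec.seq) - w_start)
            n_reads = rng.poisson(depth[w] * w_len / mean_len * reads_per_unit_depth)
            for _ in range(n_reads):
                length = int(max(40, rng.normal(mean_len, 0.2 * mean_len)))
                start = w_start + int(rng.integers(0, w_len))
                piece = rec.seq[start : start + length]
                if len(piece) < 40:
                    continue
                n += 1
                reads.append(SequenceRecord(id=f"read{n}", seq=piece, description=f"src={rec.id}"))
    return SimulatedReads(reads=reads, window_depths=depths)
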