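"""End-to-end orchestration: config, staged runs, atomic outputs.

Stages run in a fixed order — TNF profiling, ESOM binning, CRISPR detection
on reference genomes, spacer-protospacer matching, ORF calling (plus domain
ingestion when a domtblout table is supplied), survey statistics — each
consuming only declared files/objects from the previous stage.  Every output
file is written atomically (temp file + rename) and a run manifest records
the config hash, seeds and package version, so a rerun with the same config
is bit-identical for the deterministic stages (all of them).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from . import binning, crispr, orfdom, spacermatch, survey, tnf
from .seqcore import read_fasta, write_fasta
from .synth import CommunityBundle, CommunityConfig, make_community

logger = logging.getLogger(__name__)


@dataclass
class TnfConfig:
    min_len: int = 1000
    window: int = 5000
    standardize: bool = True


@dataclass
class EsomConfig:
    rows: int | None = None
    cols: int | None = None
    epochs: int = 20
    seed: int = 0
    quantile: float = 0.4
    min_host_fragments: int = 5


@dataclass
class CrisprConfig:
    repeat_len: tuple[int, int] = (23, 55)
    spacer_len: tuple[int, int] = (17, 72)
    max_repeat_mismatch: int = 1
    min_repeats: int = 3
    seed_k: int = 8


@dataclass
class MatchConfig:
    mode: str = "strict"
    strict_identity: float = 0.90
    strict_evalue: float = 1e-5
    survey_identity: float = 0.70
    survey_coverage: float = 0.85
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class OrfConfig:
    minsize: int = 300


@dataclass
class PathsConfig:
    contigs: str = ""
    references: dict[str, str] = field(default_factory=dict)
    spacers: str | None = None
    domtblout: str | None = None


@dataclass
class RunConfig:
    tnf: TnfConfig = field(default_factory=TnfConfig)
    esom: EsomConfig = field(default_factory=EsomConfig)
    crispr: CrisprConfig = field(default_factory=CrisprConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    orf: OrfConfig = field(default_factory=OrfConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.match.mode not in spacermatch.MODES:
            raise ValueError(f"unknown match mode {self.match.mode!r}")
        if not (0.0 < self.esom.quantile < 1.0):
            raise ValueError("esom.quantile must be in (0, 1)")
        if self.orf.minsize < 3:
            raise ValueError("orf.minsize must be >= 3")
        if self.tnf.min_len < 0 or self.tnf.window <= 0:
            raise ValueError("invalid tnf lengths")


def _from_mapping(cls, data: Mapping[str, Any]):
    """Build a (nested) config dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        subcls = None
        if f.default_factory is not dataclasses.MISSING:
            probe = f.default_factory()
            if dataclasses.is_dataclass(probe):
                subcls = type(probe)
        if subcls is not None and isinstance(value, Mapping):
            kwargs[name] = _from_mapping(subcls, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected before any stage runs."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_mapping(RunConfig, data)
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@contextmanager
def atomic_write(path: Path):
    """Write to a temp file in the same directory, then rename into place."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    tmp = Path(tmp)
    try:
        yield tmp
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()


def _atomic_move(produced: Path, final: Path) -> None:
    os.replace(produced, final)


@dataclass
class RunResult:
    outdir: Path
    assignments: list[binning.BinAssignment]
    cluster_hosts: dict[int, str]
    n_clusters: int
    matches: list[spacermatch.SpacerMatch]
    n_orfs: int
    counters: dict[str, int]


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunResult:
    """Run all stages on the configured inputs and write the output bundle."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    counters: dict[str, int] = {}

    contigs = read_fasta(config.paths.contigs)
    references = []
    for label, p in config.paths.references.items():
        for rec in read_fasta(p):
            references.append((label, rec))

    # --- tnf
    matrix = tnf.build_matrix(
        contigs,
        references,
        min_len=config.tnf.min_len,
        window=config.tnf.window,
        standardize=config.tnf.standardize,
    )
    n_viral_rows = sum(1 for p in matrix.profiles if p.source_label == "viral")
    counters["contigs_total"] = len(contigs)
    counters["contigs_dropped_short"] = len(contigs) - n_viral_rows
    with atomic_write(outdir / "profiles.tsv") as tmp:
        matrix.to_tsv(tmp)
    with atomic_write(outdir / "profiles.lrn") as tmp:
        matrix.to_lrn(tmp)
    with atomic_write(outdir / "profiles.cls") as tmp:
        matrix.to_cls(tmp)

    # --- binning
    grid = binning.train_esom(
        matrix,
        rows=config.esom.rows,
        cols=config.esom.cols,
        epochs=config.esom.epochs,
        seed=config.esom.seed,
    )
    um = binning.umatrix(grid)
    clusters = binning.extract_clusters(um, quantile=config.esom.quantile)
    assignments = binning.assign_bins(grid, clusters, matrix)
    hosts = binning.attribute_hosts(assignments, min_count=config.esom.min_host_fragments)
    with atomic_write(outdir / "umatrix.tsv") as tmp:
        um.to_tsv(tmp)
    with atomic_write(outdir / "assignments.tsv") as tmp:
        binning.assignments_to_tsv(assignments, tmp)
    with atomic_write(outdir / "bestmatches.bm") as tmp:
        binning.write_bm(grid, matrix, tmp)

    # --- crispr: detect arrays on reference genomes unless a spacer FASTA is given
    spacers: list[crispr.Spacer] = []
    if config.paths.spacers:
        for rec in read_fasta(config.paths.spacers):
            spacers.append(crispr.Spacer(spacer_id=rec.id, seq=rec.seq, host_label=rec.description or "unknown"))
    else:
        params = crispr.CrisprParams(
            repeat_len=config.crispr.repeat_len,
            spacer_len=config.crispr.spacer_len,
            max_repeat_mismatch=config.crispr.max_repeat_mismatch,
            min_repeats=config.crispr.min_repeats,
            seed_k=config.crispr.seed_k,
        )
        all_arrays = []
        for label, rec in references:
            arrays = crispr.find_arrays(rec, params)
            all_arrays.extend(arrays)
            spacers.extend(crispr.extract_spacers(arrays, host_label=label, source_dataset="references"))
        with atomic_write(outdir / "arrays.gff3") as tmp:
            crispr.arrays_to_gff3(all_arrays, tmp)
        counters["crispr_arrays"] = len(all_arrays)
    counters["spacers"] = len(spacers)
    with atomic_write(outdir / "spacers.fasta") as tmp_fa:
        with atomic_write(outdir / "spacers.tsv") as tmp_tsv:
            crispr.spacers_to_fasta(spacers, tmp_fa, tmp_tsv)

    # --- spacer matching
    scheme = spacermatch.ScoringScheme(
        match=config.match.match,
        mismatch=config.match.mismatch,
        gap_open=config.match.gap_open,
        gap_extend=config.match.gap_extend,
    )
    matches: list[spacermatch.SpacerMatch] = []
    if spacers:
        matches = spacermatch.match_spacers(
            spacers,
            contigs,
            mode=config.match.mode,
            scheme=scheme,
            strict_identity=config.match.strict_identity,
            strict_evalue=config.match.strict_evalue,
            survey_identity=config.match.survey_identity,
            survey_coverage=config.match.survey_coverage,
        )
    counters["spacer_matches"] = len(matches)
    with atomic_write(outdir / "matches.tsv") as tmp:
        spacermatch.matches_to_outfmt6(matches, tmp)
    spacer_hosts = {sp.spacer_id: sp.host_label for sp in spacers}
    votes = spacermatch.attribute_contig_hosts(matches, spacer_hosts)
    with atomic_write(outdir / "host_votes.tsv") as tmp:
        votes.to_csv(tmp, sep="\t", index=False)

    # --- orfs
    orfs = []
    for rec in contigs:
        orfs.extend(orfdom.find_orfs(rec, minsize=config.orf.minsize))
    counters["orfs"] = len(orfs)
    with atomic_write(outdir / "orfs.gff3") as tmp:
        orfdom.orfs_to_gff3(orfs, tmp)
    with atomic_write(outdir / "orfs.faa") as tmp:
        orfdom.orfs_to_protein_fasta(orfs, tmp)

    # --- domains + survey
    if config.paths.domtblout:
        hits = orfdom.parse_domtblout(config.paths.domtblout, known_orf_ids={o.orf_id for o in orfs})
        counters["domain_hits"] = len(hits)
        by_orf: dict[str, list[orfdom.DomainHit]] = {}
        for h in hits:
            by_orf.setdefault(h.orf_id, []).append(h)
        with atomic_write(outdir / "architectures.tsv") as tmp:
            with open(tmp, "w") as fh:
                fh.write("orf_id\tarchitecture\tcanonical_endolysin\n")
                for orf_id in sorted(by_orf):
                    arch = orfdom.domain_architecture(by_orf[orf_id])
                    fh.write(f"{orf_id}\t{arch.string}\t{int(arch.canonical_endolysin)}\n")
        # targeting survey in contig coordinates
        orf_by_id = {o.orf_id: o for o in orfs}
        instances: dict[str, list] = {}
        for h in hits:
            o = orf_by_id.get(h.orf_id)
            if o is None:
                continue
            instances.setdefault(h.name, []).append(
                orf_aa_to_contig_interval(o, h.ali_interval)
            )
        rows = survey.targeting_table(instances, matches)
        with atomic_write(outdir / "targeting.tsv") as tmp:
            survey.targeting_to_tsv(rows, tmp)

    manifest = {
        "package": "phagebin",
        "version": __version__,
        "config_hash": config_hash(config),
        "config": dataclasses.asdict(config),
        "counters": counters,
        "n_clusters": clusters.n_clusters,
        "cluster_hosts": {str(k): v for k, v in hosts.items()},
    }
    with atomic_write(outdir / "run_manifest.yaml") as tmp:
        with open(tmp, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    return RunResult(
        outdir=outdir,
        assignments=assignments,
        cluster_hosts=hosts,
        n_clusters=clusters.n_clusters,
        matches=matches,
        n_orfs=len(orfs),
        counters=counters,
    )


def orf_aa_to_contig_interval(orf: orfdom.OrfRecord, ali_interval: tuple[int, int]):
    """Map 1-based amino-acid coordinates on an ORF to contig nucleotides."""
    from .seqcore import Interval

    aa_from, aa_to = ali_interval
    if orf.interval.strand == "+":
        start = orf.interval.start + 3 * (aa_from - 1)
        end = orf.interval.start + 3 * aa_to - 1
    else:
        end = orf.interval.end - 3 * (aa_from - 1)
        start = orf.interval.end - 3 * aa_to + 1
    return Interval(orf.contig_id, start, end, orf.interval.strand)


def write_synth_bundle(config: CommunityConfig, outdir: str | Path) -> CommunityBundle:
    """Generate the synthetic community and write its fixture bundle."""
    bundle = make_community(config)
    bundle.write(outdir)
    return bundle
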