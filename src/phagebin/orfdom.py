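"""ORF calling with getorf semantics and profile-HMM domain ingestion.

ORFs are maximal stop-free stretches between stop codons in all six reading
frames (getorf's default "find 0" mode: stop-to-stop, no ATG requirement),
including stretches abutting the sequence ends, trimmed to a codon multiple
from the downstream end, and reported iff their nucleotide length reaches
``minsize`` (default 300, i.e. 100 aa).  This choice matters: ATG-anchored
calling would change every downstream count.

Domain annotation is ingested from standard hmmsearch ``--domtblout`` tables
rather than re-scoring profile HMMs; an optional thin wrapper can invoke an
external ``hmmsearch`` executable when one is available, but the core
pipeline never requires it.

The endolysin catalog lists the surveyed lysis-associated Pfam domains split
into catalytic (cell-wall cleaving) and binding (cell-wall anchoring) roles,
plus three non-lysis control genes (portal, virE, NinC).  Accessions are
recorded where the survey fixed them; other entries are matched by name.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .seqcore import Interval, SequenceRecord, gff3_line, revcomp, write_gff3


@dataclass(frozen=True)
class OrfRecord:
    """One stop-free ORF; nucleotide coordinates on the forward strand."""

    orf_id: str
    contig_id: str
    interval: Interval
    frame: int  # 1..3 forward strand, 4..6 reverse strand
    protein: str

    @property
    def nt_len(self) -> int:
        return len(self.interval)

    def __post_init__(self) -> None:
        if self.nt_len % 3 != 0:
            raise ValueError(f"{self.orf_id}: nt length {self.nt_len} not a codon multiple")
        if self.nt_len != 3 * len(self.protein):
            raise ValueError(f"{self.orf_id}: nt_len != 3 * protein length")
        if "*" in self.protein:
            raise ValueError(f"{self.orf_id}: internal stop in protein")


def _frame_orfs(
    seq: str, offset: int, minsize: int
) -> list[tuple[int, int, str]]:
    """Stop-to-stop stretches in one frame of one strand.

    Returns (start0, end0_exclusive, protein) in coordinates of ``seq``.
    """
    usable = len(seq) - offset
    n_codons = usable // 3
    if n_codons == 0:
        return []
    frame_seq = seq[offset : offset + 3 * n_codons]
    protein = str(Seq(frame_seq).translate(table=1))
    out = []
    start_codon = 0
    for chunk in protein.split("*"):
        if len(chunk) * 3 >= minsize and chunk:
            s0 = offset + 3 * start_codon
            out.append((s0, s0 + 3 * len(chunk), chunk))
        start_codon += len(chunk) + 1
    return out


def find_orfs(
    record: SequenceRecord, minsize: int = 300, table: int = 1
) -> list[OrfRecord]:
    """Six-frame stop-to-stop ORF calling (getorf "find 0" semantics).

    A sequence shorter than ``minsize`` simply yields no ORFs.  Frames 1-3
    are the forward strand, frames 4-6 the reverse; reverse-strand
    coordinates are mapped back to the forward strand.
    """
    if minsize < 3:
        raise ValueError("minsize must be >= 3")
    if table != 1:
        raise ValueError("only the standard genetic code (table 1) is supported")
    seq = record.seq
    L = len(seq)
    orfs: list[OrfRecord] = []
    counter = 0
    for offset in range(3):
        for s0, e0, protein in _frame_orfs(seq, offset, minsize):
            counter += 1
            orfs.append(
                OrfRecord(
                    orf_id=f"{record.id}_orf{counter}",
                    contig_id=record.id,
                    interval=Interval(record.id, s0 + 1, e0, "+"),
                    frame=offset + 1,
                    protein=protein,
                )
            )
    rc = revcomp(seq)
    for offset in range(3):
        for s0, e0, protein in _frame_orfs(rc, offset, minsize):
            counter += 1
            # position p (0-based) on rc maps to forward 0-based L-1-p
            fwd_start = L - e0  # 0-based
            fwd_end = L - s0  # exclusive
            orfs.append(
                OrfRecord(
                    orf_id=f"{record.id}_orf{counter}",
                    contig_id=record.id,
                    interval=Interval(record.id, fwd_start + 1, fwd_end, "-"),
                    frame=offset + 4,
                    protein=protein,
                )
            )
    return orfs


# ---------------------------------------------------------------------------
# Endolysin catalog


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    role: str  # catalytic | binding | control
    accession: str | None = None


ENDOLYSIN_CATALOG: tuple[CatalogEntry, ...] = (
    # catalytic (cell-wall hydrolase) domains
    CatalogEntry("Phage_lysozyme", "catalytic"),
    CatalogEntry("Muramidase", "catalytic"),
    CatalogEntry("Glyco_hydro_19", "catalytic", "PF00182"),
    CatalogEntry("Glyco_hydro_25", "catalytic"),
    CatalogEntry("Glyco_hydro_108", "catalytic", "PF05838"),
    CatalogEntry("SLT", "catalytic", "PF01464"),
    CatalogEntry("Transglycosylase", "catalytic"),
    CatalogEntry("Glucosaminidase", "catalytic"),
    CatalogEntry("Amidase02_C", "catalytic"),
    CatalogEntry("Amidase_5", "catalytic"),
    CatalogEntry("Amidase_3", "catalytic"),
    CatalogEntry("Amidase_2", "catalytic"),
    CatalogEntry("NlpD", "catalytic"),
    CatalogEntry("VanY", "catalytic"),
    CatalogEntry("Peptidase_U40", "catalytic"),
    CatalogEntry("Peptidase_M15_3", "catalytic"),
    CatalogEntry("Peptidase_M15_4", "catalytic"),
    CatalogEntry("Peptidase_M23", "catalytic", "PF01551"),
    CatalogEntry("YkuD", "catalytic"),
    CatalogEntry("NLPC_P60", "catalytic"),
    CatalogEntry("Peptidase_C39_2", "catalytic"),
    CatalogEntry("CHAP", "catalytic"),
    CatalogEntry("DUF3597", "catalytic"),
    # cell-wall binding domains
    CatalogEntry("PG_binding_3", "binding", "PF09374"),
    CatalogEntry("LysM", "binding"),
    CatalogEntry("SH3_3", "binding"),
    CatalogEntry("SH3_5", "binding"),
    CatalogEntry("PG_binding_1", "binding"),
    CatalogEntry("ChW", "binding"),
    CatalogEntry("Cpl-7", "binding"),
    CatalogEntry("LGFP", "binding"),
    CatalogEntry("SH3-related", "binding"),
    CatalogEntry("FOG", "binding"),
    CatalogEntry("SPOR", "binding"),
    CatalogEntry("SLAP", "binding"),
    # non-lysis control genes
    CatalogEntry("portal", "control"),
    CatalogEntry("virE", "control"),
    CatalogEntry("NinC", "control"),
)

_CATALOG_BY_NAME = {e.name: e for e in ENDOLYSIN_CATALOG}
_CATALOG_BY_ACC = {e.accession: e for e in ENDOLYSIN_CATALOG if e.accession}


def catalog_role(name: str, accession: str | None = None) -> str:
    """Role of a domain per the endolysin catalog; "other" when unlisted."""
    entry = _CATALOG_BY_NAME.get(name)
    if entry is None and accession:
        entry = _CATALOG_BY_ACC.get(accession.split(".")[0])
    return entry.role if entry else "other"


# ---------------------------------------------------------------------------
# domtblout ingestion


@dataclass
class DomainHit:
    """One profile-HMM domain instance on an ORF."""

    orf_id: str
    name: str
    accession: str
    score: float
    evalue: float
    ali_interval: tuple[int, int]  # amino-acid coordinates, 1-based inclusive
    role: str = "other"

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if self.ali_interval[0] > self.ali_interval[1] or self.ali_interval[0] < 1:
            raise ValueError("invalid alignment interval")


def parse_domtblout(
    path: str | Path, known_orf_ids: set[str] | None = None
) -> list[DomainHit]:
    """Parse an hmmsearch per-domain table (``--domtblout``).

    Each data row has 22 whitespace-delimited fields followed by a free-text
    description.  The target name is the ORF id, the query name/accession the
    domain; the independent e-value and per-domain bit score are kept, and the
    role is looked up in the endolysin catalog.  Malformed rows raise with
    their line number; hits to unknown ORF ids are kept with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 23:
                raise ValueError(
                    f"{path}:{lineno}: malformed domtblout row "
                    f"({len(fields)} fields, expected >= 23)"
                )
            try:
                orf_id = fields[0]
                query_name = fields[3]
                query_acc = fields[4]
                i_evalue = float(fields[12])
                dom_score = float(fields[13])
                ali_from = int(fields[17])
                ali_to = int(fields[18])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field: {exc}") from exc
            if known_orf_ids is not None and orf_id not in known_orf_ids:
                logger.warning("%s:%d: hit to unknown ORF id %r kept with null linkage", path, lineno, orf_id)
            hits.append(
                DomainHit(
                    orf_id=orf_id,
                    name=query_name,
                    accession=query_acc,
                    score=dom_score,
                    evalue=i_evalue,
                    ali_interval=(ali_from, ali_to),
                    role=catalog_role(query_name, query_acc if query_acc != "-" else None),
                )
            )
    return hits


@dataclass
class Architecture:
    """Ordered, non-overlapping domain organization of one ORF."""

    orf_id: str
    domains: list[DomainHit]
    canonical_endolysin: bool

    @property
    def string(self) -> str:
        return "+".join(h.name for h in self.domains)


def domain_architecture(orf_hits: Sequence[DomainHit]) -> Architecture:
    """Resolve overlaps (higher bit score wins) and order domains by start.

    ``canonical_endolysin`` is true when at least one catalytic domain is
    followed (downstream on the protein) by at least one binding domain.
    """
    if not orf_hits:
        raise ValueError("no hits supplied")
    orf_ids = {h.orf_id for h in orf_hits}
    if len(orf_ids) != 1:
        raise ValueError(f"hits span multiple ORFs: {sorted(orf_ids)}")
    kept: list[DomainHit] = []
    for hit in sorted(orf_hits, key=lambda h: (-h.score, h.ali_interval)):
        if all(
            hit.ali_interval[1] < k.ali_interval[0] or k.ali_interval[1] < hit.ali_interval[0]
            for k in kept
        ):
            kept.append(hit)
    kept.sort(key=lambda h: h.ali_interval)
    canonical = any(
        a.role == "catalytic" and b.role == "binding"
        for i, a in enumerate(kept)
        for b in kept[i + 1 :]
    )
    return Architecture(orf_id=orf_hits[0].orf_id, domains=kept, canonical_endolysin=canonical)


# ---------------------------------------------------------------------------
# output + optional external search


def orfs_to_gff3(orfs: Sequence[OrfRecord], path: str | Path) -> Path:
    lines = [
        gff3_line(
            o.interval,
            "phagebin",
            "ORF",
            f"ID={o.orf_id};frame={o.frame}",
        )
        for o in orfs
    ]
    return write_gff3(lines, path)


def orfs_to_protein_fasta(orfs: Sequence[OrfRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f">{o.orf_id}\n")
            for i in range(0, len(o.protein), 60):
                fh.write(o.protein[i : i + 60] + "\n")
    return path


class ToolUnavailableError(RuntimeError):
    """An optional external executable is not on PATH."""


def run_hmmsearch_wrapper(
    orfs: Sequence[OrfRecord], hmm_path: str | Path, out_path: str | Path | None = None
) -> Path:
    """Convenience wrapper around an external ``hmmsearch`` (optional).

    Requires the executable on PATH; otherwise raises
    :class:`ToolUnavailableError` without side effects, instructing use of
    :func:`parse_domtblout` on precomputed tables.
    """
    if not orfs:
        raise ValueError("nothing to search: empty ORF list")
    exe = shutil.which("hmmsearch")
    if exe is None:
        raise ToolUnavailableError(
            "hmmsearch not found on PATH; run it elsewhere and ingest the "
            "--domtblout table with parse_domtblout()"
        )
    out_path = Path(out_path) if out_path else Path(tempfile.mkstemp(suffix=".domtblout")[1])
    with tempfile.NamedTemporaryFile("w", suffix=".faa", delete=False) as tmp:
        faa = Path(tmp.name)
    orfs_to_protein_fasta(orfs, faa)
    proc = subprocess.run(
        [exe, "--domtblout", str(out_path), str(hmm_path), str(faa)],
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise RuntimeError(f"hmmsearch failed (exit {proc.returncode}): {proc.stderr[:500]}")
    return out_path
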