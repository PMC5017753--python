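"""Dataset-level survey statistics.

Covers the CRISPR-targeting table (per-domain fraction of annotated
instances hit by at least one retained spacer match), the per-cluster domain
presence matrix (0 / 1 / 2-or-more coding), rarefaction curves as an explicit
seeded subsampling statistic, read-class percentage arithmetic, and spacer
database accounting with a rough individuals estimate.

Percentages are stored at full floating precision and rendered only at
export time; targeting percentages render to 10 significant digits, the
precision at which such tables are conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import BinAssignment
from .seqcore import Interval
from .spacermatch import SpacerMatch


def render_pct(pct: float) -> str:
    """Render a percentage to 10 significant digits, trailing zeros stripped."""
    return f"{pct:.10g}"


@dataclass
class TargetingRow:
    """Per-domain CRISPR-targeting summary."""

    domain_name: str
    n_instances: int
    n_targeted: int
    no_instances: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.n_targeted <= max(self.n_instances, 0)):
            raise ValueError("need 0 <= n_targeted <= n_instances")
        self.no_instances = self.n_instances == 0

    @property
    def pct_targeted(self) -> float:
        if self.n_instances == 0:
            return 0.0
        return 100.0 * self.n_targeted / self.n_instances

    @property
    def rendered(self) -> str:
        return render_pct(self.pct_targeted)


def targeting_table(
    domain_instances: Mapping[str, Sequence[Interval]],
    matches: Iterable[SpacerMatch],
) -> list[TargetingRow]:
    """Count, per domain, how many annotated instances have a spacer hit.

    An instance is targeted iff at least one retained match overlaps its
    nucleotide interval by >= 1 bp (strand-agnostic).
    """
    match_list = list(matches)
    rows = []
    for name, instances in domain_instances.items():
        targeted = sum(
            1
            for iv in instances
            if any(iv.overlaps(m.contig_interval) for m in match_list)
        )
        rows.append(TargetingRow(domain_name=name, n_instances=len(instances), n_targeted=targeted))
    return rows


def targeting_to_tsv(rows: Sequence[TargetingRow], path: str | Path) -> Path:
    """Table in (instances, targeted, name, pct) column order."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("n_instances\tn_targeted\tdomain\tpct_targeted\n")
        for r in rows:
            fh.write(f"{r.n_instances}\t{r.n_targeted}\t{r.domain_name}\t{r.rendered}\n")
    return path


@dataclass
class PresenceMatrix:
    """Domain-by-cluster counts with ordinal 0 / 1 / 2+ coding."""

    counts: pd.DataFrame  # rows: domain names, cols: cluster labels
    codes: pd.DataFrame

    def to_tsv(self, counts_path: str | Path, codes_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.codes.to_csv(codes_path, sep="\t")


def presence_matrix(
    assignments: Sequence[BinAssignment],
    orf_domains: Sequence,
    orf_contigs: Mapping[str, str],
    small_contig_ids: Iterable[str] = (),
) -> PresenceMatrix:
    """Per (domain, cluster) hit counts coded as min(count, 2).

    ``orf_domains`` are DomainHit-like objects; each ORF must map to a contig
    that either carries a cluster assignment or sits in the under-1Kb pool,
    otherwise the orphan ORF is a hard error.
    """
    cluster_of: dict[str, object] = {a.seq_id: a.cluster_id for a in assignments}
    small = set(small_contig_ids)
    cluster_labels = sorted(
        {a.cluster_id for a in assignments if isinstance(a.cluster_id, int)}
    )
    columns = [f"cluster_{c}" for c in cluster_labels] + ["under_1kb"]
    row_order: list[str] = []
    counts: dict[tuple[str, str], int] = {}
    for hit in orf_domains:
        contig = orf_contigs.get(hit.orf_id)
        if contig is None:
            raise ValueError(f"orphan ORF {hit.orf_id!r}: no contig mapping")
        if contig in cluster_of:
            col = f"cluster_{cluster_of[contig]}"
        elif contig in small:
            col = "under_1kb"
        else:
            raise ValueError(
                f"orphan ORF {hit.orf_id!r}: contig {contig!r} has no cluster "
                "and is not in the under-1Kb pool"
            )
        if hit.name not in row_order:
            row_order.append(hit.name)
        counts[(hit.name, col)] = counts.get((hit.name, col), 0) + 1
    mat = pd.DataFrame(0, index=row_order, columns=columns, dtype=int)
    for (name, col), n in counts.items():
        mat.loc[name, col] = n
    codes = mat.clip(upper=2)
    return PresenceMatrix(counts=mat, codes=codes)


def rarefaction(
    annotation_ids: Sequence[str],
    depths: Sequence[int],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean (+/- sd) number of distinct annotations in subsamples.

    For each depth, ``reps`` subsamples are drawn without replacement from
    the annotation multiset; deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ids = np.asarray(annotation_ids, dtype=object)
    total = len(ids)
    for d in depths:
        if d < 0 or d > total:
            raise ValueError(f"depth {d} outside [0, {total}]")
    rng = np.random.default_rng(seed)
    rows = []
    for d in depths:
        distinct = np.empty(reps)
        for r in range(reps):
            if d == 0:
                distinct[r] = 0
            else:
                sub = rng.choice(ids, size=d, replace=False)
                distinct[r] = len(set(sub))
        rows.append({"depth": d, "mean_distinct": distinct.mean(), "sd": distinct.std(ddof=0)})
    return pd.DataFrame(rows)


@dataclass
class ClassPercent:
    """One read-class fraction, kept at full precision."""

    label: str
    count: int
    total: int

    @property
    def pct(self) -> float:
        return 100.0 * self.count / self.total

    def rendered(self, decimals: int = 1) -> str:
        return f"{self.pct:.{decimals}f}"


def class_percentages(class_counts: Mapping[str, int], total: int) -> dict[str, ClassPercent]:
    """Percentage per class label, full precision plus fixed-decimal render."""
    if total <= 0:
        raise ValueError("total must be positive")
    out = {}
    for label, count in class_counts.items():
        if count > total:
            raise ValueError(f"class {label!r}: count {count} exceeds total {total}")
        out[label] = ClassPercent(label=label, count=count, total=total)
    return out


@dataclass
class SpacerDbSummary:
    per_host: dict[str, int]
    total: int
    individuals_per_host: dict[str, int]
    individuals_total: int


def spacer_db_summary(spacers: Sequence, per_individual: int = 100) -> SpacerDbSummary:
    """Per-host spacer counts and a floor-divide individuals estimate.

    The estimate assumes an individual host cell carries roughly
    ``per_individual`` unique spacers (default 100).
    """
    per_host: dict[str, int] = {}
    for sp in spacers:
        per_host[sp.host_label] = per_host.get(sp.host_label, 0) + getattr(sp, "multiplicity", 1)
    total = sum(per_host.values())
    return SpacerDbSummary(
        per_host=per_host,
        total=total,
        individuals_per_host={h: n // per_individual for h, n in per_host.items()},
        individuals_total=total // per_individual,
    )


def circos_table(counts: pd.DataFrame, path: str | Path) -> Path:
    """Circos tableviewer-compatible matrix export of a counts DataFrame."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(str(c) for c in counts.columns) + "\n")
        for name, row in counts.iterrows():
            fh.write(str(name) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    return path
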