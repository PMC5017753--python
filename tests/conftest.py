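"""Shared fixtures: seeded RNGs, the default synthetic community, a trained map."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phagebin import binning, synth, tnf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def default_bundle() -> synth.CommunityBundle:
    """The default 3-host + free-phage community (seed 7)."""
    return synth.make_community()


@pytest.fixture(scope="session")
def default_matrix(default_bundle) -> tnf.ProfileMatrix:
    refs = [(h.id, h) for h in default_bundle.hosts]
    return tnf.build_matrix(default_bundle.contigs, refs)


@pytest.fixture(scope="session")
def trained_map(default_matrix):
    """Trained SOM + U-matrix + clusters + assignments for the default bundle."""
    grid = binning.train_esom(default_matrix, seed=0)
    um = binning.umatrix(grid)
    clusters = binning.extract_clusters(um)
    assignments = binning.assign_bins(grid, clusters, default_matrix)
    return grid, um, clusters, assignments


@pytest.fixture(scope="session")
def truth_labels(default_bundle) -> dict[str, str]:
    return {p["id"]: p["parent"] for p in default_bundle.manifest.phages}


def cluster_purity(assignments, truth: dict[str, str]) -> float:
    """Fraction of viral contigs whose cluster's majority truth label is their own."""
    from collections import Counter

    by_cluster: dict[int, Counter] = {}
    for a in assignments:
        if a.source_label == "viral":
            by_cluster.setdefault(a.cluster_id, Counter())[truth[a.seq_id]] += 1
    n_ok = sum(c.most_common(1)[0][1] for c in by_cluster.values())
    n_tot = sum(sum(c.values()) for c in by_cluster.values())
    return n_ok / n_tot


DOMTBLOUT_HEADER = (
    "#                                                               --- full sequence ---"
    " --- this domain --- hmm coord ali coord env coord\n"
    "# target name        accession   tlen query name           accession   qlen   E-value"
    "  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from"
    "    to  acc description of target\n"
)


def domtblout_row(
    orf_id: str,
    name: str,
    accession: str,
    score: float = 50.0,
    i_evalue: float = 1e-12,
    ali: tuple[int, int] = (5, 90),
    desc: str = "synthetic fixture hit",
) -> str:
    return (
        f"{orf_id} - 200 {name} {accession} 120 1e-13 {score + 1:.1f} 0.1 1 1 "
        f"{i_evalue:.1e} {i_evalue:.1e} {score:.1f} 0.1 2 110 {ali[0]} {ali[1]} "
        f"{ali[0] - 1} {ali[1] + 2} 0.95 {desc}\n"
    )
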