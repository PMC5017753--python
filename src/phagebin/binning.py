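"""Emergent self-organizing map (ESOM) binning of TNF profiles.

An online SOM is trained on the stacked profile matrix; the U-matrix (mean
Euclidean distance from each node's weight to its 8 toroidal neighbours)
exposes cluster structure as valleys separated by ridges.  Cluster extraction
is made algorithmic: nodes at or below a U-value quantile are "valley" nodes,
8-connected toroidal components of valley nodes become clusters (numbered by
decreasing size), and ridge nodes attach to the nearest valley node by
toroidal Chebyshev grid distance (ties go to the lower cluster id).

Every input row is then assigned the cluster of its best-matching unit (BMU),
and clusters are attributed to reference genomes by majority vote over the
reference fragments they contain.

Training is deterministic given (seed, data order): weight initialization and
the per-epoch sample shuffle both come from one seeded generator.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .tnf import ProfileMatrix


@dataclass
class EsomGrid:
    """A trained toroidal map of weight vectors."""

    rows: int
    cols: int
    weights: np.ndarray  # (rows, cols, dim)
    toroidal: bool = True
    seed: int = 0
    epochs: int = 20
    schedule: tuple[float, float, float, float] = (0.5, 0.05, 0.0, 1.0)
    qe_history: list[float] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.weights.shape[2]

    @property
    def flat_weights(self) -> np.ndarray:
        return self.weights.reshape(self.rows * self.cols, self.dim)


def default_grid_shape(n_rows: int) -> tuple[int, int]:
    """~5*sqrt(N) nodes at ~1.6:1 aspect, floor 10x16."""
    nodes = max(5.0 * math.sqrt(max(n_rows, 1)), 160.0)
    rows = max(10, int(round(math.sqrt(nodes / 1.6))))
    cols = max(16, int(round(nodes / rows)))
    return rows, cols


def _toroidal_sq_grid_dist(rows: int, cols: int) -> np.ndarray:
    """Precomputed squared toroidal grid distance between all node pairs.

    Returned shape: (rows, cols, rows, cols) collapsed to
    (rows*cols, rows*cols) row-major.
    """
    r = np.arange(rows)
    c = np.arange(cols)
    dr = np.abs(r[:, None] - r[None, :])
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(c[:, None] - c[None, :])
    dc = np.minimum(dc, cols - dc)
    d2 = (dr[:, None, :, None] ** 2 + dc[None, :, None, :] ** 2).astype(float)
    return d2.reshape(rows * cols, rows * cols)


def train_esom(
    matrix: ProfileMatrix,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 20,
    seed: int = 0,
    toroidal: bool = True,
    lr_start: float = 0.5,
    lr_end: float = 0.05,
    radius_start: float | None = None,
    radius_end: float = 1.0,
) -> EsomGrid:
    """Train an online SOM on the profile matrix.

    Per sample: find the BMU (minimal Euclidean distance, ties row-major),
    then pull every node towards the sample with a Gaussian neighbourhood
    kernel on toroidal grid distance.  Learning rate and radius decay
    linearly over epochs.
    """
    if len(matrix) == 0:
        raise ValueError("empty profile matrix")
    if epochs <= 0:
        raise ValueError("epochs must be positive")
    data = np.asarray(matrix.values, dtype=float)
    n, dim = data.shape
    if rows is None or cols is None:
        rows, cols = default_grid_shape(n)
    if rows <= 0 or cols <= 0 or rows * cols < 4:
        raise ValueError(f"invalid grid dimensions ({rows}, {cols})")
    if radius_start is None:
        radius_start = max(rows, cols) / 2.0

    rng = np.random.default_rng(seed)
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    W = rng.uniform(lo, hi, size=(rows * cols, dim))
    d2grid = _toroidal_sq_grid_dist(rows, cols)
    if not toroidal:
        r = np.arange(rows)
        c = np.arange(cols)
        dr = np.abs(r[:, None] - r[None, :])
        dc = np.abs(c[:, None] - c[None, :])
        d2grid = (
            (dr[:, None, :, None] ** 2 + dc[None, :, None, :] ** 2)
            .astype(float)
            .reshape(rows * cols, rows * cols)
        )

    qe_history: list[float] = []
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = lr_start + (lr_end - lr_start) * frac
        sigma = radius_start + (radius_end - radius_start) * frac
        order = rng.permutation(n)
        for idx in order:
            x = data[idx]
            d = ((W - x) ** 2).sum(axis=1)
            bmu_flat = int(np.argmin(d))
            h = np.exp(-d2grid[bmu_flat] / (2.0 * sigma * sigma))
            W += (lr * h)[:, None] * (x - W)
        # full quantization-error pass at epoch end
        dists = np.sqrt(
            (
                (data[:, None, :] - W[None, :, :]) ** 2
            ).sum(axis=2)
        ).min(axis=1)
        qe_history.append(float(dists.mean()))

    return EsomGrid(
        rows=rows,
        cols=cols,
        weights=W.reshape(rows, cols, dim),
        toroidal=toroidal,
        seed=seed,
        epochs=epochs,
        schedule=(lr_start, lr_end, radius_start, radius_end),
        qe_history=qe_history,
    )


def bmu(grid: EsomGrid, profile: np.ndarray) -> tuple[int, int]:
    """Best-matching unit of a vector; ties broken row-major."""
    x = np.asarray(profile, dtype=float).ravel()
    if x.shape[0] != grid.dim:
        raise ValueError(f"profile has dimension {x.shape[0]}, grid expects {grid.dim}")
    d = ((grid.flat_weights - x) ** 2).sum(axis=1)
    flat = int(np.argmin(d))
    return divmod(flat, grid.cols)


@dataclass
class UMatrix:
    """Per-node mean distance to topological neighbours (grid shape)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("U-matrix entries must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        np.savetxt(path, self.values, delimiter="\t", fmt="%.6g")
        return path


_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def umatrix(grid: EsomGrid) -> UMatrix:
    """Mean Euclidean distance from each node to its 8 toroidal neighbours."""
    rows, cols = grid.rows, grid.cols
    W = grid.weights
    um = np.zeros((rows, cols))
    for dr, dc in _NEIGH8:
        shifted = np.roll(np.roll(W, -dr, axis=0), -dc, axis=1)
        um += np.sqrt(((W - shifted) ** 2).sum(axis=2))
    um /= len(_NEIGH8)
    return UMatrix(um)


@dataclass
class ClusterMap:
    """Per-node cluster ids (>=1), same shape as the grid."""

    labels: np.ndarray  # int array (rows, cols)
    n_clusters: int
    valley_mask: np.ndarray
    threshold: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _toroidal_components(mask: np.ndarray) -> np.ndarray:
    """8-connected toroidal components of a boolean mask; 0 = background."""
    rows, cols = mask.shape
    comp = np.zeros((rows, cols), dtype=int)
    next_id = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and comp[r0, c0] == 0:
                next_id += 1
                comp[r0, c0] = next_id
                queue = deque([(r0, c0)])
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in _NEIGH8:
                        rr = (r + dr) % rows
                        cc = (c + dc) % cols
                        if mask[rr, cc] and comp[rr, cc] == 0:
                            comp[rr, cc] = next_id
                            queue.append((rr, cc))
    return comp


def extract_clusters(um: UMatrix, quantile: float = 0.4) -> ClusterMap:
    """Quantile-thresholded valley clustering of the U-matrix.

    Nodes with U-value <= the given quantile of all U-values are valley
    nodes; their 8-connected toroidal components are clusters numbered by
    decreasing size.  Every ridge node is attached to the cluster of its
    nearest valley node by toroidal Chebyshev grid distance (ties: lower
    cluster id).
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    values = um.values
    rows, cols = values.shape
    thresh = float(np.quantile(values, quantile))
    valley = values <= thresh
    comp = _toroidal_components(valley)
    n_comp = comp.max()
    if n_comp == 0:  # cannot happen: quantile always admits some node
        raise AssertionError("no valley nodes")
    # renumber by decreasing size
    sizes = np.bincount(comp.ravel(), minlength=n_comp + 1)
    order = sorted(range(1, n_comp + 1), key=lambda cid: (-sizes[cid], cid))
    renum = {old: new for new, old in enumerate(order, start=1)}
    labels = np.zeros_like(comp)
    for old, new in renum.items():
        labels[comp == old] = new

    if not valley.all():
        # attach ridge nodes to nearest valley node (toroidal Chebyshev)
        vr, vc = np.nonzero(valley)
        vlab = labels[vr, vc]
        rr, rc = np.nonzero(~valley)
        dr = np.abs(rr[:, None] - vr[None, :])
        dr = np.minimum(dr, rows - dr)
        dc = np.abs(rc[:, None] - vc[None, :])
        dc = np.minimum(dc, cols - dc)
        cheb = np.maximum(dr, dc)
        # tie-break: lower cluster id wins at equal distance
        key = cheb * (labels.max() + 1) + vlab
        nearest = vlab[np.argmin(key, axis=1)]
        labels[rr, rc] = nearest
    return ClusterMap(
        labels=labels, n_clusters=int(labels.max()), valley_mask=valley, threshold=thresh
    )


@dataclass
class BinAssignment:
    seq_id: str
    bmu: tuple[int, int]
    cluster_id: int | str
    source_label: str
    host_label: str | None = None


def assign_bins(
    grid: EsomGrid, clusters: ClusterMap, matrix: ProfileMatrix
) -> list[BinAssignment]:
    """Assign every matrix row to the cluster of its BMU."""
    if clusters.shape != (grid.rows, grid.cols):
        raise ValueError("cluster map shape does not match grid")
    out = []
    for prof, vec in zip(matrix.profiles, matrix.values):
        node = bmu(grid, vec)
        out.append(
            BinAssignment(
                seq_id=prof.seq_id,
                bmu=node,
                cluster_id=int(clusters.labels[node]),
                source_label=prof.source_label,
            )
        )
    return out


def attribute_hosts(
    assignments: Sequence[BinAssignment],
    min_count: int = 5,
    viral_label: str = "viral",
) -> dict[int, str]:
    """Attribute each cluster to a reference genome, or "no host".

    A cluster is attributed to genome G iff G's fragments form a strict
    majority of the reference fragments in the cluster and number at least
    ``min_count``.  The host label is also written back onto the viral
    assignments of attributed clusters.
    """
    by_cluster: dict[int, Counter] = {}
    for a in assignments:
        if a.source_label != viral_label and isinstance(a.cluster_id, int):
            by_cluster.setdefault(a.cluster_id, Counter())[a.source_label] += 1
    hosts: dict[int, str] = {}
    all_clusters = {a.cluster_id for a in assignments if isinstance(a.cluster_id, int)}
    for cid in sorted(all_clusters):
        counts = by_cluster.get(cid)
        if not counts:
            hosts[cid] = "no host"
            continue
        label, top = counts.most_common(1)[0]
        total = sum(counts.values())
        hosts[cid] = label if (top * 2 > total and top >= min_count) else "no host"
    for a in assignments:
        if isinstance(a.cluster_id, int):
            a.host_label = hosts.get(a.cluster_id)
    return hosts


def assignments_to_tsv(assignments: Sequence[BinAssignment], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "seq_id": a.seq_id,
                "cluster": a.cluster_id,
                "bmu_row": a.bmu[0],
                "bmu_col": a.bmu[1],
                "source_label": a.source_label,
                "host": a.host_label if a.host_label is not None else "",
            }
            for a in assignments
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def write_bm(grid: EsomGrid, matrix: ProfileMatrix, path: str | Path) -> Path:
    """Databionic ESOM .bm best-match file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"% {grid.rows} {grid.cols}\n")
        fh.write(f"% {len(matrix)}\n")
        for i, vec in enumerate(matrix.values, start=1):
            r, c = bmu(grid, vec)
            fh.write(f"{i}\t{r}\t{c}\n")
    return path


@dataclass
class HclustResult:
    """Agglomerative clustering of profile rows for the heat-map view."""

    linkage_matrix: np.ndarray
    leaf_order: list[int]
    ordered_ids: list[str]
    ordered_values: np.ndarray

    def to_tsv(self, path: str | Path, feature_order: Sequence[str]) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.ordered_values, columns=list(feature_order))
        df.insert(0, "seq_id", self.ordered_ids)
        df.to_csv(path, sep="\t", index=False)
        return path


def hclust_profiles(
    matrix: ProfileMatrix, method: str = "average", metric: str = "euclidean"
) -> HclustResult:
    """Hierarchical clustering of rows; returns leaf order and merge heights."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows for hierarchical clustering")
    Z = linkage(matrix.values, method=method, metric=metric)
    order = [int(i) for i in leaves_list(Z)]
    ids = matrix.ids
    return HclustResult(
        linkage_matrix=Z,
        leaf_order=order,
        ordered_ids=[ids[i] for i in order],
        ordered_values=matrix.values[order],
    )
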