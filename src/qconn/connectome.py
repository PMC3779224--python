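"""Connection matrices and geodesic connection-distance matrices.

``M(i, j)`` counts the retained fibers whose endpoints land in ROIs ``i``
and ``j``; the diagonal is zero by convention (self-connections are
discarded).  ``d(i, j)`` is the geodesic distance between ROIs confined to
the white-matter volume: shortest path over the 26-connected graph of WM
voxel centers with Euclidean edge weights, between the sets of WM voxels
6-adjacent to each ROI (multi-source/multi-target shortest path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .tracking import StreamlineSet

__all__ = [
    "ConnectionMatrix",
    "DistanceMatrix",
    "build_connection_matrix",
    "geodesic_distance_matrix",
    "count_connections",
    "distance_distribution",
]

log = logging.getLogger(__name__)


@dataclass
class ConnectionMatrix:
    counts: np.ndarray  # (N, N) int, symmetric, zero diagonal
    roi_ids: list[int]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.array_equal(c, c.T) or np.any(np.diag(c) != 0) or np.any(c < 0):
            raise ValueError("connection matrix must be symmetric, nonnegative, "
                             "zero-diagonal")

    @property
    def n_inter_roi_fibers(self) -> int:
        return int(np.triu(self.counts, 1).sum())


@dataclass
class DistanceMatrix:
    distances: np.ndarray  # (N, N) mm, inf where no WM path
    roi_ids: list[int]


def build_connection_matrix(fibers: StreamlineSet, roi_ids) -> ConnectionMatrix:
    """Count fibers per unordered ROI pair; self-pairs are discarded."""
    roi_ids = list(roi_ids)
    index = {r: i for i, r in enumerate(roi_ids)}
    n = len(roi_ids)
    counts = np.zeros((n, n), dtype=int)
    if fibers.endpoint_labels is None:
        raise ValueError("fibers must be filtered (endpoint labels missing)")
    for a, b in fibers.endpoint_labels:
        for lab in (a, b):
            if lab not in index:
                raise ValueError(f"endpoint label {lab} not among ROI ids {roi_ids}")
        if a == b:
            continue  # diagonal arbitrarily zero
        counts[index[a], index[b]] += 1
        counts[index[b], index[a]] += 1
    return ConnectionMatrix(counts, roi_ids)


_NEIGH26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)
_NEIGH6 = np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)])


def geodesic_distance_matrix(
    wm_mask: np.ndarray, roi_labels: np.ndarray, voxel_size
) -> DistanceMatrix:
    """Multi-source Dijkstra over the WM voxel graph, one virtual node per ROI."""
    vs = np.asarray(voxel_size, dtype=float)
    shape = wm_mask.shape
    roi_ids = sorted(int(r) for r in np.unique(roi_labels) if r > 0)
    n_roi = len(roi_ids)

    node_id = -np.ones(shape, dtype=int)
    wm_idx = np.argwhere(wm_mask)
    node_id[tuple(wm_idx.T)] = np.arange(len(wm_idx))
    n_wm = len(wm_idx)

    rows, cols, wts = [], [], []
    for off in _NEIGH26:
        nb = wm_idx + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        src = node_id[tuple(wm_idx[ok].T)]
        dst = node_id[tuple(nb[ok].T)]
        hit = dst >= 0
        w = float(np.linalg.norm(off * vs))
        rows.append(src[hit])
        cols.append(dst[hit])
        wts.append(np.full(hit.sum(), w))

    # virtual node per ROI, zero-weight edges to its WM attachment voxels
    for r_i, roi in enumerate(roi_ids):
        vnode = n_wm + r_i
        attach = np.zeros(shape, dtype=bool)
        roi_vox = roi_labels == roi
        for off in _NEIGH6:
            shifted = np.zeros(shape, dtype=bool)
            src = roi_vox
            sl_src = tuple(
                slice(max(-o, 0), s - max(o, 0)) for o, s in zip(off, shape)
            )
            sl_dst = tuple(
                slice(max(o, 0), s - max(-o, 0)) for o, s in zip(off, shape)
            )
            shifted[sl_dst] = src[sl_src]
            attach |= shifted & wm_mask
        nodes = node_id[attach]
        if len(nodes) == 0:
            log.warning("ROI %d has no white-matter-adjacent voxel; distances inf", roi)
            continue
        rows.append(np.full(len(nodes), vnode))
        cols.append(nodes)
        wts.append(np.zeros(len(nodes)))

    n_total = n_wm + n_roi
    graph = coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_total, n_total),
    ).tocsr()
    virt = np.arange(n_wm, n_total)
    dist = dijkstra(graph, directed=False, indices=virt)
    d = dist[:, virt]
    d = np.minimum(d, d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, roi_ids)


def count_connections(M: ConnectionMatrix, n_f: int = 1) -> int:
    """Number of unordered ROI pairs connected by at least ``n_f`` fibers."""
    if n_f < 1:
        raise ValueError("n_f must be >= 1")
    iu = np.triu_indices(len(M.roi_ids), 1)
    return int((M.counts[iu] >= n_f).sum())


def distance_distribution(
    M: ConnectionMatrix,
    D: DistanceMatrix,
    bin_edges,
    n_f: int = 1,
) -> tuple[np.ndarray, int]:
    """Connection counts per distance bin.

    Bins are half-open ``[lo, hi)`` except the last, which is closed.
    Returns (per-bin counts, number of connected pairs with infinite
    distance). Conservation: ``counts.sum() + n_unreachable ==
    count_connections(M, n_f)`` whenever the bins cover all finite
    distances.
    """
    if M.roi_ids != D.roi_ids:
        raise ValueError("connection and distance matrices use different ROI ids")
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins, dtype=int)
    unreachable = 0
    iu = np.triu_indices(len(M.roi_ids), 1)
    for i, j in zip(*iu):
        if M.counts[i, j] < n_f:
            continue
        d = D.distances[i, j]
        if np.isinf(d):
            unreachable += 1
            continue
        b = int(np.searchsorted(edges, d, side="right")) - 1
        if b == n_bins and d == edges[-1]:
            b = n_bins - 1  # last bin closed
        if 0 <= b < n_bins:
            counts[b] += 1
    if unreachable:
        log.info("%d connected pairs have no white-matter path", unreachable)
    return counts, unreachable
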