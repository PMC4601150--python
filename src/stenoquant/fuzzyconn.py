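"""Seeded competing fuzzy-connectedness segmentation.

Each voxel carries a fuzzy membership derived from the segmentation
thresholds: zero at or below the lower threshold LT, rising linearly to 1
at the contrast (aorta) value, and — when an upper threshold UT is defined
(CTA) — zero above UT, which excludes calcified plaque.  The affinity of a
voxel pair is the smaller of the two memberships, so the strength of a
path is the weakest membership along it, and the connectedness of a voxel
to a seed set is the best (max–min) path strength over all 6-connected
paths.

Competing seeds: every voxel receives the label whose seed set reaches it
with the greatest max–min strength.  Ties (common in noise-free interiors
where the membership saturates at 1) are broken by the smaller geodesic
distance in mm to the seed set within the in-band region, and remaining
ties by the lower label — a fully deterministic rule that an exhaustive
oracle can reproduce.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .thresholds import ThresholdSet
from .volume import ImageVolume


@dataclass
class SeedSet:
    """Labelled seed points in world mm coordinates (z, y, x)."""

    seeds: list[tuple[int, tuple[float, float, float]]]

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("at least one seed is required")
        for label, _ in self.seeds:
            if int(label) <= 0:
                raise ValueError("seed labels must be positive integers")

    def labels(self) -> list[int]:
        return sorted({int(label) for label, _ in self.seeds})

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"seeds": [[int(label), list(pos)] for label, pos in self.seeds]}, fh, indent=2
            )

    @classmethod
    def from_json(cls, path: str) -> "SeedSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls([(int(label), tuple(pos)) for label, pos in payload["seeds"]])


@dataclass
class LabelVolume:
    """Competing-segmentation output: integer labels (0 = unassigned) plus
    the winning max–min path strength per voxel."""

    labels: np.ndarray
    strength: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def save(self, path: str) -> None:
        ImageVolume(self.labels.astype(float), self.spacing, self.origin).save(path)


def membership(values: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Trapezoidal in-band membership of intensities, in [0, 1]."""
    v = np.asarray(values, dtype=float)
    lt, top = thresholds.lt, thresholds.aorta_value
    if top > lt:
        m = np.clip((v - lt) / (top - lt), 0.0, 1.0)
    else:  # degenerate band: step function
        m = (v > lt).astype(float)
    m = np.where(v <= lt, 0.0, m)
    if thresholds.ut is not None:
        m = np.where(v > thresholds.ut, 0.0, m)
    return m


def affinity(intensity_a, intensity_b, thresholds: ThresholdSet):
    """Pairwise affinity: the smaller membership of the two intensities.

    1 when both sit at the contrast value, 0 when either is out of band,
    symmetric, and monotone non-decreasing in the smaller intensity within
    the band.
    """
    ma = membership(np.asarray(intensity_a, dtype=float), thresholds)
    mb = membership(np.asarray(intensity_b, dtype=float), thresholds)
    out = np.minimum(ma, mb)
    return float(out) if np.isscalar(intensity_a) and np.isscalar(intensity_b) else out


def _in_band_graph(volume: ImageVolume, memb: np.ndarray):
    """Node ids for in-band voxels and their 6-connected edge lists."""
    in_band = memb > 0
    node_id = -np.ones(volume.shape, dtype=np.int64)
    coords = np.argwhere(in_band)
    node_id[in_band] = np.arange(len(coords))
    edges_u, edges_v, lengths = [], [], []
    for axis in range(3):
        a = np.take(node_id, np.arange(volume.shape[axis] - 1), axis=axis)
        b = np.take(node_id, np.arange(1, volume.shape[axis]), axis=axis)
        ok = (a >= 0) & (b >= 0)
        edges_u.append(a[ok].ravel())
        edges_v.append(b[ok].ravel())
        lengths.append(np.full(int(ok.sum()), volume.spacing[axis]))
    u = np.concatenate(edges_u)
    v = np.concatenate(edges_v)
    w = np.concatenate(lengths)
    return coords, node_id, u, v, w


def _maxmin_dijkstra(
    n: int, indptr: np.ndarray, indices: np.ndarray, node_memb: np.ndarray, sources: np.ndarray
) -> np.ndarray:
    """Best max–min path strength from a source set to every node, where the
    strength of a path is the minimum vertex membership along it."""
    strength = np.zeros(n)
    done = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int]] = []
    for s in sources:
        val = node_memb[s]
        if val > strength[s]:
            strength[s] = val
            heapq.heappush(heap, (-val, int(s)))
    while heap:
        neg, u = heapq.heappop(heap)
        if done[u] or -neg < strength[u]:
            continue
        done[u] = True
        su = strength[u]
        for v in indices[indptr[u] : indptr[u + 1]]:
            cand = min(su, node_memb[v])
            if cand > strength[v]:
                strength[v] = cand
                heapq.heappush(heap, (-cand, int(v)))
    return strength


def fuzzy_connectedness_segment(
    volume: ImageVolume, seeds: SeedSet, thresholds: ThresholdSet
) -> LabelVolume:
    """Competing fuzzy-connectedness labelling of the in-band voxels."""
    memb = membership(volume.values, thresholds)
    coords, node_id, u, v, w = _in_band_graph(volume, memb)
    n = len(coords)
    if n == 0:
        raise ValueError("no voxel lies inside the threshold band")

    labels_sorted = seeds.labels()
    seed_nodes: dict[int, list[int]] = {lab: [] for lab in labels_sorted}
    for label, pos in seeds.seeds:
        idx = np.round(volume.world_to_voxel(np.asarray(pos))).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(volume.shape)):
            raise ValueError(f"seed at {pos} mm lies outside the volume")
        nid = node_id[tuple(idx)]
        if nid < 0:
            raise ValueError(
                f"seed at {pos} mm is outside the [LT, UT] band (intensity "
                f"{volume.values[tuple(idx)]:.1f})"
            )
        seed_nodes[int(label)].append(int(nid))

    # sparse adjacency shared by the strength and distance propagations
    uu = np.concatenate([u, v])
    vv = np.concatenate([v, u])
    ww = np.concatenate([w, w])
    adj = csr_matrix((ww, (uu, vv)), shape=(n, n))
    node_memb = memb[tuple(coords.T)]

    strengths = np.zeros((len(labels_sorted), n))
    dists = np.full((len(labels_sorted), n), np.inf)
    for li, lab in enumerate(labels_sorted):
        src = np.asarray(seed_nodes[lab], dtype=np.int64)
        strengths[li] = _maxmin_dijkstra(n, adj.indptr, adj.indices, node_memb, src)
        dists[li] = _csgraph_dijkstra(adj, directed=False, indices=src, min_only=True)

    best = strengths.max(axis=0)
    tied = strengths >= best[None, :] - 0.0  # exact equality with the max
    dist_masked = np.where(tied, dists, np.inf)
    best_dist = dist_masked.min(axis=0)
    winner_idx = np.argmax(tied & (dist_masked <= best_dist[None, :]), axis=0)

    labels_flat = np.where(best > 0, np.asarray(labels_sorted)[winner_idx], 0)
    labels = np.zeros(volume.shape, dtype=np.int32)
    strength = np.zeros(volume.shape)
    labels[tuple(coords.T)] = labels_flat
    strength[tuple(coords.T)] = np.where(best > 0, best, 0.0)
    return LabelVolume(labels, strength, volume.spacing, volume.origin)
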