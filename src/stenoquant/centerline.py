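"""Vessel centerline trees and the two measurable segments per artery.

The centerline is a single-voxel-wide medial curve of a labelled vessel,
obtained by 3-D thinning, spur pruning and shortest-path rooting at the
aorta attachment.  Two segments are defined per artery: segment 1 runs
from the aorta to the most proximal bifurcation (or the vessel tip when
the artery never branches), segment 2 follows the largest branch — the one
with the largest mean radius over its first 5 mm — from the first to the
second bifurcation (or tip).  All geometry is in mm, so anisotropic voxel
grids are handled transparently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize

from .fuzzyconn import LabelVolume

PRUNE_SPUR_MM = 2.0
LARGEST_BRANCH_PROBE_MM = 5.0
_SMOOTH_WINDOW = 5


@dataclass
class CenterlineTree:
    """Rooted tree of centerline nodes (root = aorta attachment).

    Nodes are ordered root-first, so ``parents[i] < i`` for every non-root
    node.  Positions are world mm (z, y, x); tangents are unit vectors;
    ``arc_length`` is the distance from the root along the tree.
    """

    positions: np.ndarray
    parents: np.ndarray
    radii: np.ndarray
    arc_length: np.ndarray = field(default=None)
    tangents: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.positions)
        if n == 0:
            raise ValueError("empty centerline")
        if self.parents[0] != -1 or np.any(self.parents[1:] >= np.arange(1, n)):
            raise ValueError("nodes must be ordered root-first with parents[i] < i")
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self._children[self.parents[i]].append(i)
        if self.arc_length is None:
            arc = np.zeros(n)
            for i in range(1, n):
                p = self.parents[i]
                arc[i] = arc[p] + np.linalg.norm(self.positions[i] - self.positions[p])
            self.arc_length = arc
        if self.tangents is None:
            self.tangents = self._compute_tangents()

    # ------------------------------------------------------------------ topology
    def children(self, i: int) -> list[int]:
        return self._children[i]

    def is_bifurcation(self, i: int) -> bool:
        return len(self._children[i]) >= 2

    @property
    def bifurcations(self) -> list[int]:
        return [i for i in range(len(self.positions)) if self.is_bifurcation(i)]

    @property
    def n_edges(self) -> int:
        return len(self.positions) - 1

    def branches(self) -> list[list[int]]:
        """Maximal chains: each starts at the root or a bifurcation and runs
        (inclusive of both endpoints) to the next bifurcation or leaf."""
        out = []
        starts = [0] + [c for b in self.bifurcations for c in self._children[b]]
        for start in starts:
            chain = [self.parents[start]] if self.parents[start] >= 0 else []
            node = start
            chain.append(node)
            while len(self._children[node]) == 1 and not self.is_bifurcation(node):
                node = self._children[node][0]
                chain.append(node)
                if self.is_bifurcation(node):
                    break
            out.append(chain)
        # drop duplicates created when the root itself is a bifurcation
        seen, unique = set(), []
        for chain in out:
            key = tuple(chain)
            if key not in seen and len(chain) >= 2:
                seen.add(key)
                unique.append(chain)
        return unique

    def _compute_tangents(self) -> np.ndarray:
        tangents = np.zeros_like(self.positions)
        for chain in self.branches():
            pos = self.positions[chain]
            if len(pos) == 1:
                continue
            diff = np.gradient(pos, axis=0)
            for k, i in enumerate(chain):
                if not np.any(tangents[i]):
                    tangents[i] = diff[k]
        for i in range(len(tangents)):
            norm = np.linalg.norm(tangents[i])
            tangents[i] = tangents[i] / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        return tangents

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "positions_mm": self.positions.tolist(),
                    "parents": self.parents.tolist(),
                    "radii_mm": self.radii.tolist(),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "CenterlineTree":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            np.asarray(payload["positions_mm"]),
            np.asarray(payload["parents"]),
            np.asarray(payload["radii_mm"]),
        )


@dataclass
class VesselSegment:
    """One measurable stretch of an artery with per-node geometry."""

    artery_id: int
    index: int  # 1 or 2
    positions: np.ndarray
    tangents: np.ndarray
    arc_from_root: np.ndarray  # = distance to the aorta along the tree, mm
    radii: np.ndarray
    bif_start_arc: float | None = None
    bif_end_arc: float | None = None

    @property
    def length_mm(self) -> float:
        return float(self.arc_from_root[-1] - self.arc_from_root[0])

    def interpolate(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Position and unit tangent at arc-from-root ``s`` (linear)."""
        arc = self.arc_from_root
        pos = np.array([np.interp(s, arc, self.positions[:, k]) for k in range(3)])
        tan = np.array([np.interp(s, arc, self.tangents[:, k]) for k in range(3)])
        norm = np.linalg.norm(tan)
        return pos, (tan / norm if norm > 0 else np.array([0.0, 0.0, 1.0]))


# --------------------------------------------------------------------------- extraction
_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


def _skeleton_graph(skel: np.ndarray, spacing: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    coords = np.argwhere(skel)
    for c in coords:
        G.add_node(tuple(c))
    shape = np.asarray(skel.shape)
    for off in _OFFSETS_26:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_ok, src_ok = nb[ok], coords[ok]
        hits = skel[tuple(nb_ok.T)]
        step = float(np.linalg.norm(np.asarray(off) * spacing))
        for a, b in zip(src_ok[hits], nb_ok[hits]):
            G.add_edge(tuple(a), tuple(b), weight=step)
    return G


def _prune_spurs(G: nx.Graph, keep: tuple, min_len_mm: float) -> None:
    """Iteratively remove leaf chains shorter than ``min_len_mm`` that end at
    a junction; the ``keep`` voxel (root) is never removed."""
    changed = True
    while changed:
        changed = False
        for leaf in [n for n in G.nodes if G.degree(n) == 1 and n != keep]:
            if leaf not in G:
                continue
            chain, length = [leaf], 0.0
            node, prev = leaf, None
            while G.degree(node) == 2 or node is leaf:
                nbrs = [m for m in G.neighbors(node) if m != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += G.edges[node, nxt]["weight"]
                prev, node = node, nxt
                if G.degree(node) != 2:
                    break
                chain.append(node)
            if length < min_len_mm and G.degree(node) >= 3 and keep not in chain:
                G.remove_nodes_from(chain)
                changed = True


def _smooth_branches(tree_positions: np.ndarray, chains: list[list[int]]) -> np.ndarray:
    """Per-branch moving average of node positions; branch endpoints fixed."""
    pos = tree_positions.copy()
    half = _SMOOTH_WINDOW // 2
    for chain in chains:
        if len(chain) < 3:
            continue
        p = tree_positions[chain]
        sm = p.copy()
        for k in range(1, len(chain) - 1):
            lo, hi = max(0, k - half), min(len(chain), k + half + 1)
            sm[k] = p[lo:hi].mean(axis=0)
        pos[chain[1:-1]] = sm[1:-1]
    return pos


def extract_centerline(
    labels: LabelVolume,
    root_hint_mm: tuple[float, float, float],
    label: int | None = None,
    prune_mm: float = PRUNE_SPUR_MM,
) -> CenterlineTree:
    """Medial centerline tree of one label, rooted nearest ``root_hint_mm``."""
    spacing = np.asarray(labels.spacing)
    origin = np.asarray(labels.origin)
    hint = np.asarray(root_hint_mm, dtype=float)
    if label is None:
        cand = np.argwhere(labels.labels > 0)
        if len(cand) == 0:
            raise ValueError("label volume is empty")
        nearest = cand[np.argmin(np.linalg.norm(cand * spacing + origin - hint, axis=1))]
        label = int(labels.labels[tuple(nearest)])
    mask = labels.labels == label
    if not mask.any():
        raise ValueError(f"label {label} is empty")

    skel = skeletonize(mask)
    if not skel.any():  # a blob thinner than one voxel everywhere
        skel = mask.copy()
    G = _skeleton_graph(skel, spacing)
    coords = np.array(list(G.nodes))
    root_voxel = tuple(
        coords[np.argmin(np.linalg.norm(coords * spacing + origin - hint, axis=1))]
    )
    component = nx.node_connected_component(G, root_voxel)
    G = G.subgraph(component).copy()
    _prune_spurs(G, keep=root_voxel, min_len_mm=prune_mm)

    pred, dist = nx.dijkstra_predecessor_and_distance(G, root_voxel, weight="weight")
    order = sorted(dist, key=lambda n: (dist[n], n))
    index = {n: i for i, n in enumerate(order)}
    positions = np.array([np.asarray(n) * spacing + origin for n in order])
    parents = np.array(
        [-1] + [index[pred[n][0]] for n in order[1:]], dtype=int
    )

    edt = distance_transform_edt(mask, sampling=spacing)
    radii = np.array([float(edt[n]) for n in order])

    tree = CenterlineTree(positions, parents, radii)
    smoothed = _smooth_branches(tree.positions, tree.branches())
    return CenterlineTree(smoothed, parents, radii)


def import_manual_centerline(path: str) -> CenterlineTree:
    """Read a manually drawn centerline.

    Format: ``{"branches": [{"points_mm": [[z,y,x], ...], "radii_mm": [...],
    "parent": null | branch index, "attach_index": node index within the
    parent branch}]}``.  Branch 0 is the root branch; tangents and arc
    lengths are recomputed from the points.
    """
    with open(path) as fh:
        payload = json.load(fh)
    branches = payload["branches"]
    if not branches:
        raise ValueError("no branches in manual centerline file")
    positions: list[np.ndarray] = []
    parents: list[int] = []
    radii: list[float] = []
    branch_node_ids: list[list[int]] = []
    for bi, br in enumerate(branches):
        pts = np.asarray(br["points_mm"], dtype=float)
        if pts.ndim != 2 or len(pts) < 2:
            raise ValueError(f"branch {bi} needs at least 2 points")
        rr = br.get("radii_mm") or [0.0] * len(pts)
        ids = []
        for k, p in enumerate(pts):
            if k == 0:
                if br.get("parent") is None:
                    parent = -1
                else:
                    parent = branch_node_ids[br["parent"]][br["attach_index"]]
                    # the branch's first point hangs off the attachment node
            else:
                parent = ids[-1]
            ids.append(len(positions))
            positions.append(p)
            parents.append(parent)
            radii.append(float(rr[k]))
        branch_node_ids.append(ids)
    return CenterlineTree(np.asarray(positions), np.asarray(parents), np.asarray(radii))


# --------------------------------------------------------------------------- segments
MIN_BRANCH_EXTENSION_MM = 5.0


def _subtree_extension(tree: CenterlineTree, node: int) -> float:
    """Longest arc from ``node`` to any leaf below it."""
    best = 0.0
    stack = [node]
    base = tree.arc_length[node]
    while stack:
        cur = stack.pop()
        best = max(best, tree.arc_length[cur] - base)
        stack.extend(tree.children(cur))
    return float(best)


def _substantial_children(
    tree: CenterlineTree, node: int, min_branch_mm: float
) -> list[int]:
    """Children whose subtree continues at least ``min_branch_mm``; shorter
    side twigs are thinning artifacts, not anatomical bifurcations."""
    return [
        c for c in tree.children(node) if _subtree_extension(tree, c) >= min_branch_mm
    ]


def _walk_chain(tree: CenterlineTree, start: int, min_branch_mm: float) -> tuple[list[int], bool]:
    """Follow the vessel from ``start`` to the next true bifurcation or the
    tip; at artifact junctions the longest continuation is taken.  Returns
    (chain, ends_at_bifurcation)."""
    chain = [start]
    node = start
    while True:
        if node != start and len(_substantial_children(tree, node, min_branch_mm)) >= 2:
            return chain, True
        children = tree.children(node)
        if not children:
            return chain, False
        substantial = _substantial_children(tree, node, min_branch_mm)
        node = max(substantial or children, key=lambda c: _subtree_extension(tree, c))
        chain.append(node)


def _branch_mean_radius(tree: CenterlineTree, first: int, probe_mm: float, min_branch_mm: float) -> float:
    chain, _ = _walk_chain(tree, first, min_branch_mm)
    arcs = tree.arc_length[chain] - tree.arc_length[chain[0]]
    radii = tree.radii[chain]
    within = arcs <= probe_mm
    return float(radii[within].mean()) if within.any() else float(radii.mean())


def _make_segment(
    tree: CenterlineTree,
    chain: list[int],
    artery_id: int,
    index: int,
    bif_start: bool,
    bif_end: bool,
) -> VesselSegment:
    return VesselSegment(
        artery_id=artery_id,
        index=index,
        positions=tree.positions[chain],
        tangents=tree.tangents[chain],
        arc_from_root=tree.arc_length[chain],
        radii=tree.radii[chain],
        bif_start_arc=float(tree.arc_length[chain[0]]) if bif_start else None,
        bif_end_arc=float(tree.arc_length[chain[-1]]) if bif_end else None,
    )


def define_segments(
    tree: CenterlineTree,
    artery_id: int = 1,
    min_branch_mm: float = MIN_BRANCH_EXTENSION_MM,
) -> list[VesselSegment]:
    """Segment 1: root to the most proximal bifurcation (or tip).  Segment 2:
    the largest branch — largest mean radius over its first 5 mm — from the
    first to the second bifurcation (or tip).  Junctions whose side branch
    continues less than ``min_branch_mm`` are thinning artifacts and are
    walked through."""
    chain1, ends_at_bif = _walk_chain(tree, 0, min_branch_mm)
    segments = []
    if len(chain1) >= 2:
        segments.append(_make_segment(tree, chain1, artery_id, 1, False, ends_at_bif))
    if not ends_at_bif:
        return segments
    first_bif = chain1[-1]
    candidates = sorted(
        _substantial_children(tree, first_bif, min_branch_mm),
        key=lambda c: -_branch_mean_radius(tree, c, LARGEST_BRANCH_PROBE_MM, min_branch_mm),
    )
    tail, end_is_bif = _walk_chain(tree, candidates[0], min_branch_mm)
    chain2 = [first_bif] + tail
    if len(chain2) >= 2:
        segments.append(_make_segment(tree, chain2, artery_id, 2, True, end_is_bif))
    return segments
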