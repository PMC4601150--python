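"""Synthetic angiographic phantoms with analytically known stenosis geometry.

A phantom is an aorta-like cylinder plus one or more tubular arteries
branching off it, voxelized onto a CTA-like (0.75 x 0.5 x 0.5 mm) or
MRA-like (2.0 x 0.7 x 0.7 mm) grid.  Each artery carries a baseline radius
and zero or more focal narrowings shaped as smooth raised-cosine dips, so
the true minimum/maximum diameter and area — and hence the true relative
diameter reduction (Dred) and area reduction (Ared) — are known in closed
form before voxelization.

Voxelization by default models partial-volume averaging: a voxel's value is
the background intensity plus the lumen contrast weighted by the fraction
of the voxel footprint inside the lumen (estimated by supersampling voxels
near the surface).  This mirrors how real CT/MR voxels average the signal
over their extent and is what makes sub-voxel diameter measurement
possible at coarse slice spacings; a binary centre-inside rule is
available as ``voxelize="center"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .volume import ImageVolume

PATH_SAMPLE_MM = 0.05  # arc-length step used to discretize artery paths
TRUTH_SAMPLE_MM = 0.05  # arc-length step for analytic truth extrema

# eligibility rules for the maximum-diameter/area reference position
MIN_AORTA_DISTANCE_MM = 10.0
BIFURCATION_MARGIN_MM = 5.0


# --------------------------------------------------------------------------- specs
@dataclass
class Stenosis:
    """A focal narrowing: a raised-cosine dip in the radius profile.

    The radius reduction factor at arc length ``s`` is
    ``depth * 0.5 * (1 + cos(2*pi*(s - center_mm)/width_mm))`` for
    ``|s - center_mm| <= width_mm/2`` and zero outside, so the lumen radius
    reaches ``baseline * (1 - depth)`` exactly at the dip centre.
    """

    center_mm: float
    depth: float  # fractional radius reduction at the dip centre, in [0, 1)
    width_mm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth < 1.0:
            raise ValueError(f"stenosis depth must be in [0, 1), got {self.depth}")
        if self.width_mm <= 0:
            raise ValueError("stenosis width must be positive")


@dataclass
class ArterySpec:
    """A tubular artery given by a smooth path and a radius profile."""

    path_mm: np.ndarray  # ordered control points, (n, 3) world mm in (z, y, x)
    baseline_radius_mm: float
    stenoses: list[Stenosis] = field(default_factory=list)
    branches: list[tuple[float, "ArterySpec"]] = field(default_factory=list)
    # each branch: (attachment arc length on this artery, child spec)

    def __post_init__(self) -> None:
        self.path_mm = np.asarray(self.path_mm, dtype=float)
        if self.path_mm.ndim != 2 or self.path_mm.shape[0] < 2 or self.path_mm.shape[1] != 3:
            raise ValueError("artery path needs >= 2 control points of 3 coordinates")
        if self.baseline_radius_mm <= 0:
            raise ValueError("artery radius must be positive")

    def sampled(self, step_mm: float = PATH_SAMPLE_MM) -> tuple[np.ndarray, np.ndarray]:
        """Resample the path at a fixed arc-length step; returns (points, arcs)."""
        return _resample_path(self.path_mm, step_mm)

    def length_mm(self) -> float:
        _, arcs = self.sampled()
        return float(arcs[-1])

    def radius_at(self, s: np.ndarray) -> np.ndarray:
        """Lumen radius (mm) at arc length(s) ``s`` from the path start."""
        s = np.asarray(s, dtype=float)
        reduction = np.zeros_like(s)
        for st in self.stenoses:
            inside = np.abs(s - st.center_mm) <= st.width_mm / 2
            reduction += np.where(
                inside,
                st.depth * 0.5 * (1 + np.cos(2 * np.pi * (s - st.center_mm) / st.width_mm)),
                0.0,
            )
        return self.baseline_radius_mm * np.clip(1.0 - reduction, 0.0, None)

    def validate(self) -> None:
        length = self.length_mm()
        for st in self.stenoses:
            if not 0.0 <= st.center_mm <= length:
                raise ValueError(
                    f"stenosis at {st.center_mm} mm lies outside the {length:.1f} mm path"
                )
        for attach, child in self.branches:
            if not 0.0 <= attach <= length:
                raise ValueError(f"branch attachment {attach} mm outside path length {length:.1f}")
            child.validate()


@dataclass
class AortaSpec:
    """Axis-aligned (z) cylinder standing in for the abdominal aorta."""

    center_yx_mm: tuple[float, float]
    radius_mm: float
    intensity: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("aorta radius must be positive")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int]  # voxels, (z, y, x)
    voxel_spacing: tuple[float, float, float]  # mm, (z, y, x)
    aorta: AortaSpec
    arteries: list[ArterySpec]
    background_intensity: float = 60.0
    noise_sd: float = 0.0
    plaques: list[tuple[tuple[float, float, float], float, float]] = field(default_factory=list)
    # each plaque: (centre mm (z, y, x), radius mm, intensity)
    seed: int = 0
    voxelize: str = "partial"  # "partial" (partial-volume averaging) or "center"
    supersample: int = 3  # sub-divisions per axis for boundary voxels

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive on all axes")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        for _, radius, intensity in self.plaques:
            if radius <= 0:
                raise ValueError("plaque radius must be positive")
            if intensity <= self.aorta.intensity:
                raise ValueError("plaque intensity must exceed the lumen intensity")
        if self.voxelize not in ("partial", "center"):
            raise ValueError("voxelize must be 'partial' or 'center'")


# --------------------------------------------------------------------------- truth
@dataclass
class SegmentTruth:
    """Analytic per-segment extremes, the ground-truth counterpart of a
    measured segment summary (MinD/MinA/MaxD/MaxA and relative reductions)."""

    artery: int
    segment: int
    min_d_mm: float
    min_a_mm2: float
    max_d_mm: float
    max_a_mm2: float
    dred_pct: float
    ared_pct: float
    fallback_used: bool
    stenosis_positions_mm: list[float]
    span_mm: tuple[float, float]  # arc-length range from the aorta wall

    def __post_init__(self) -> None:
        assert self.min_d_mm <= self.max_d_mm + 1e-9
        assert self.min_a_mm2 <= self.max_a_mm2 + 1e-9


@dataclass
class PhantomTruth:
    segments: list[SegmentTruth]
    bifurcation_arcs_mm: list[float]

    def segment(self, artery: int, segment: int) -> SegmentTruth:
        for t in self.segments:
            if t.artery == artery and t.segment == segment:
                return t
        raise KeyError((artery, segment))

    def to_json(self, path: str) -> None:
        payload = {
            "segments": [vars(s) | {"span_mm": list(s.span_mm)} for s in self.segments],
            "bifurcation_arcs_mm": self.bifurcation_arcs_mm,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "PhantomTruth":
        with open(path) as fh:
            payload = json.load(fh)
        segs = [
            SegmentTruth(**{**d, "span_mm": tuple(d["span_mm"])}) for d in payload["segments"]
        ]
        return cls(segs, payload["bifurcation_arcs_mm"])


def _circle_area(diameter_mm: float) -> float:
    return math.pi * (diameter_mm / 2.0) ** 2


def _segment_truth(
    artery_index: int,
    segment_index: int,
    artery: ArterySpec,
    s_range: tuple[float, float],
    aorta_offset_mm: float,
    start_is_bif: bool,
    end_is_bif: bool,
) -> SegmentTruth:
    """Analytic extremes of one segment, honouring the reference-position
    eligibility rules (>= 10 mm from the aorta, >= 5 mm from a bounding
    bifurcation); when no position is eligible the maximum falls back to the
    unrestricted one, mirroring the visually-obtained fallback."""
    s0, s1 = s_range
    s = np.arange(s0, s1 + TRUTH_SAMPLE_MM / 2, TRUTH_SAMPLE_MM)
    r = artery.radius_at(s)
    dist_aorta = aorta_offset_mm + s
    eligible = dist_aorta >= MIN_AORTA_DISTANCE_MM
    if start_is_bif:
        eligible &= (s - s0) >= BIFURCATION_MARGIN_MM
    if end_is_bif:
        eligible &= (s1 - s) >= BIFURCATION_MARGIN_MM
    min_d = 2.0 * float(r.min())
    fallback = not eligible.any()
    max_r = float(r.max()) if fallback else float(r[eligible].max())
    max_d = 2.0 * max_r
    dred = (1.0 - min_d / max_d) * 100.0 if max_d > 0 else 0.0
    min_a, max_a = _circle_area(min_d), _circle_area(max_d)
    ared = (1.0 - min_a / max_a) * 100.0 if max_a > 0 else 0.0
    positions = [
        aorta_offset_mm + st.center_mm for st in artery.stenoses if s0 <= st.center_mm <= s1
    ]
    return SegmentTruth(
        artery=artery_index,
        segment=segment_index,
        min_d_mm=min_d,
        min_a_mm2=min_a,
        max_d_mm=max_d,
        max_a_mm2=max_a,
        dred_pct=dred,
        ared_pct=ared,
        fallback_used=fallback,
        stenosis_positions_mm=positions,
        span_mm=(aorta_offset_mm + s0, aorta_offset_mm + s1),
    )


def compute_truth(spec: PhantomSpec) -> PhantomTruth:
    """Closed-form segment truth from the radius profiles (no voxels involved).

    Segment 1 runs from the aorta wall to the most proximal bifurcation (or
    the vessel tip); segment 2 follows the largest branch — largest mean
    radius over its first 5 mm — from the first to the second bifurcation.
    """
    segments: list[SegmentTruth] = []
    bif_arcs: list[float] = []
    for ai, artery in enumerate(spec.arteries):
        artery.validate()
        length = artery.length_mm()
        attachments = sorted(a for a, _ in artery.branches)
        if not attachments:
            segments.append(
                _segment_truth(ai, 1, artery, (0.0, length), 0.0, False, False)
            )
            continue
        s_b1 = attachments[0]
        bif_arcs.append(s_b1)
        segments.append(_segment_truth(ai, 1, artery, (0.0, s_b1), 0.0, False, True))
        # candidate continuations from the first bifurcation
        children = [child for a, child in artery.branches if a == s_b1]
        probe = np.arange(0.0, BIFURCATION_MARGIN_MM, TRUTH_SAMPLE_MM)
        candidates: list[tuple[float, str, ArterySpec, tuple[float, float], bool]] = []
        # parent continuation: s_b1 .. next attachment or tip
        nxt = [a for a in attachments if a > s_b1]
        parent_end = min(nxt) if nxt else length
        candidates.append(
            (
                float(artery.radius_at(s_b1 + probe).mean()),
                "parent",
                artery,
                (s_b1, parent_end),
                bool(nxt),
            )
        )
        for child in children:
            child_attach = sorted(a for a, _ in child.branches)
            child_end = child_attach[0] if child_attach else child.length_mm()
            candidates.append(
                (
                    float(child.radius_at(probe).mean()),
                    "child",
                    child,
                    (0.0, child_end),
                    bool(child_attach),
                )
            )
        candidates.sort(key=lambda c: -c[0])
        _, kind, art2, (t0, t1), end_is_bif = candidates[0]
        offset = 0.0 if kind == "parent" else s_b1
        segments.append(_segment_truth(ai, 2, art2, (t0, t1), offset, True, end_is_bif))
        if end_is_bif:
            bif_arcs.append(offset + t1)
    return PhantomTruth(segments, bif_arcs)


# --------------------------------------------------------------------------- voxelization
def _resample_path(points: np.ndarray, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate ordered control points to a fixed arc-length sampling."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    chord = np.concatenate([[0.0], np.cumsum(seg)])
    if chord[-1] <= 0:
        raise ValueError("degenerate artery path (zero length)")
    if len(pts) >= 3:
        spline = CubicSpline(chord, pts, axis=0)
        dense_t = np.linspace(0.0, chord[-1], max(int(chord[-1] / (step_mm / 4)), 8))
        dense = spline(dense_t)
    else:
        dense_t = np.linspace(0.0, chord[-1], max(int(chord[-1] / (step_mm / 4)), 8))
        dense = pts[0] + (dense_t / chord[-1])[:, None] * (pts[1] - pts[0])
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    s_grid = np.arange(0.0, arc[-1] + step_mm / 2, step_mm)
    samples = np.column_stack([np.interp(s_grid, arc, dense[:, k]) for k in range(3)])
    return samples, s_grid


def _all_tube_samples(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Flatten all arteries (and branches) into point/radius samples."""
    pts, radii = [], []

    def visit(artery: ArterySpec) -> None:
        samples, arcs = artery.sampled()
        pts.append(samples)
        radii.append(artery.radius_at(arcs))
        for _, child in artery.branches:
            visit(child)

    for artery in spec.arteries:
        visit(artery)
    return np.concatenate(pts), np.concatenate(radii)


def _tube_inside(tree: cKDTree, radii: np.ndarray, pts: np.ndarray, k: int = 16) -> np.ndarray:
    """Union-of-balls membership test against the sampled tube skeleton."""
    k = min(k, len(radii))
    d, idx = tree.query(pts, k=k)
    if k == 1:
        d, idx = d[:, None], idx[:, None]
    return np.any(d < radii[idx], axis=1)


def _tube_fraction(
    spec: PhantomSpec, tree: cKDTree, radii: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Per-voxel lumen volume fraction for the artery tubes."""
    spacing = np.asarray(spec.voxel_spacing)
    half_diag = 0.5 * float(np.linalg.norm(spacing))
    d, idx = tree.query(centers)
    signed = d - radii[idx]
    frac = np.zeros(len(centers))
    frac[signed <= -half_diag] = 1.0
    shell = np.abs(signed) < half_diag
    if spec.voxelize == "center":
        frac[shell] = _tube_inside(tree, radii, centers[shell]).astype(float)
        return frac
    n = spec.supersample
    offs = (np.arange(n) + 0.5) / n - 0.5
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
    sub = sub * spacing  # (n^3, 3) mm offsets
    shell_pts = centers[shell][:, None, :] + sub[None, :, :]
    inside = _tube_inside(tree, radii, shell_pts.reshape(-1, 3))
    frac[shell] = inside.reshape(-1, len(sub)).mean(axis=1)
    return frac


def _axial_fraction(spec: PhantomSpec, ny: int, nx: int) -> np.ndarray:
    """In-plane lumen fraction map for the z-aligned aorta cylinder."""
    sy, sx = spec.voxel_spacing[1], spec.voxel_spacing[2]
    y = np.arange(ny) * sy
    x = np.arange(nx) * sx
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cy, cx = spec.aorta.center_yx_mm
    d = np.hypot(yy - cy, xx - cx) - spec.aorta.radius_mm
    half_diag = 0.5 * math.hypot(sy, sx)
    frac = np.zeros_like(d)
    frac[d <= -half_diag] = 1.0
    shell = np.abs(d) < half_diag
    if spec.voxelize == "center":
        frac[shell] = (d[shell] < 0).astype(float)
        return frac
    n = spec.supersample
    offs = (np.arange(n) + 0.5) / n - 0.5
    oy, ox = np.meshgrid(offs * sy, offs * sx, indexing="ij")
    sub_y = yy[shell][:, None] + oy.ravel()[None, :]
    sub_x = xx[shell][:, None] + ox.ravel()[None, :]
    inside = np.hypot(sub_y - cy, sub_x - cx) < spec.aorta.radius_mm
    frac[shell] = inside.mean(axis=1)
    return frac


def _sphere_fraction(
    spec: PhantomSpec, center: np.ndarray, radius: float, centers: np.ndarray
) -> np.ndarray:
    spacing = np.asarray(spec.voxel_spacing)
    half_diag = 0.5 * float(np.linalg.norm(spacing))
    d = np.linalg.norm(centers - center, axis=1) - radius
    frac = np.zeros(len(centers))
    frac[d <= -half_diag] = 1.0
    shell = np.abs(d) < half_diag
    if spec.voxelize == "center":
        frac[shell] = (d[shell] < 0).astype(float)
        return frac
    n = spec.supersample
    offs = (np.arange(n) + 0.5) / n - 0.5
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3) * spacing
    pts = centers[shell][:, None, :] + sub[None, :, :]
    inside = np.linalg.norm(pts.reshape(-1, 3) - center, axis=1) < radius
    frac[shell] = inside.reshape(-1, len(sub)).mean(axis=1)
    return frac


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Voxelize the phantom and return the volume with its analytic truth.

    The intensity model is ``background + (lumen - background) * fraction``
    with the lumen fraction combined over aorta and arteries by maximum;
    hyperintense plaque blobs override where brighter.  Zero-mean Gaussian
    noise of ``spec.noise_sd`` is added from a generator seeded with
    ``spec.seed``, so identical specs yield bit-identical volumes.
    """
    truth = compute_truth(spec)  # also validates artery/stenosis geometry
    nz, ny, nx = spec.grid_shape
    spacing = np.asarray(spec.voxel_spacing)
    bg, lumen = spec.background_intensity, spec.aorta.intensity

    frac = np.zeros(spec.grid_shape, dtype=float)
    frac += _axial_fraction(spec, ny, nx)[None, :, :]

    if spec.arteries:
        samples, radii = _all_tube_samples(spec)
        tree = cKDTree(samples)
        margin = radii.max() + float(np.linalg.norm(spacing))
        lo = np.maximum(np.floor((samples.min(axis=0) - margin) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((samples.max(axis=0) + margin) / spacing).astype(int) + 1,
            np.asarray(spec.grid_shape),
        )
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        centers = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()]) * spacing
        tube = _tube_fraction(spec, tree, radii, centers).reshape(zz.shape)
        box = frac[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(box, tube, out=box)

    values = bg + (lumen - bg) * frac

    for center, radius, intensity in spec.plaques:
        center = np.asarray(center, dtype=float)
        margin = radius + float(np.linalg.norm(spacing))
        lo = np.maximum(np.floor((center - margin) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((center + margin) / spacing).astype(int) + 1, np.asarray(spec.grid_shape)
        )
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        centers = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()]) * spacing
        pf = _sphere_fraction(spec, center, radius, centers).reshape(zz.shape)
        box = values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(box, bg + (intensity - bg) * pf, out=box)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    return ImageVolume(values, spacing=tuple(spec.voxel_spacing)), truth


# --------------------------------------------------------------------------- factories
MODALITY_SPACING = {"CTA": (0.75, 0.5, 0.5), "MRA": (2.0, 0.7, 0.7)}


def renal_phantom(
    modality: str = "CTA",
    dred_pct: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    with_plaque: bool = False,
    lumen_intensity: float = 300.0,
    background_intensity: float = 60.0,
) -> PhantomSpec:
    """Default single-artery phantom: an 8 mm-radius aorta at mid-volume with
    one 2.5 mm-radius renal artery running ~36 mm along +x in the axial
    mid-plane, narrowed by one 8 mm-wide dip centred 22 mm from the ostium.
    """
    if modality not in MODALITY_SPACING:
        raise ValueError(f"modality must be one of {sorted(MODALITY_SPACING)}")
    spacing = MODALITY_SPACING[modality]
    extent = np.array([44.0, 32.0, 56.0])  # mm (z, y, x)
    shape = tuple(int(round(e / s)) + 1 for e, s in zip(extent, spacing))
    z_mid, y_mid = extent[0] / 2, extent[1] / 2
    aorta = AortaSpec(center_yx_mm=(y_mid, 10.0), radius_mm=8.0, intensity=lumen_intensity)
    x_wall = 10.0 + aorta.radius_mm
    path = np.array(
        [
            [z_mid, y_mid, x_wall],
            [z_mid, y_mid + 0.8, x_wall + 12.0],
            [z_mid, y_mid + 1.2, x_wall + 24.0],
            [z_mid, y_mid + 0.8, x_wall + 36.0],
        ]
    )
    artery = ArterySpec(
        path_mm=path,
        baseline_radius_mm=2.5,
        stenoses=[Stenosis(center_mm=22.0, depth=dred_pct / 100.0, width_mm=8.0)]
        if dred_pct > 0
        else [],
    )
    plaques = []
    if with_plaque:
        if modality != "CTA":
            raise ValueError("calcified plaques are modelled for CTA phantoms only")
        # blob abutting the artery wall near the stenosis, brighter than contrast
        plaques = [((z_mid, y_mid + 4.0, x_wall + 22.0), 1.5, 800.0)]
    return PhantomSpec(
        grid_shape=shape,
        voxel_spacing=spacing,
        aorta=aorta,
        arteries=[artery],
        background_intensity=background_intensity,
        noise_sd=noise_sd,
        plaques=plaques,
        seed=seed,
    )


def default_seed_points(spec: PhantomSpec) -> list[tuple[int, tuple[float, float, float]]]:
    """Competing seeds for the default phantom layout: label 1 on the aorta
    axis, label 2 inside each artery 8 mm from the ostium."""
    nz = spec.grid_shape[0]
    z_mid = (nz - 1) / 2 * spec.voxel_spacing[0]
    cy, cx = spec.aorta.center_yx_mm
    seeds = [(1, (z_mid, cy, cx))]
    for artery in spec.arteries:
        samples, arcs = artery.sampled()
        s_seed = min(8.0, float(arcs[-1]) / 2)
        pos = samples[np.searchsorted(arcs, s_seed)]
        seeds.append((2, tuple(pos)))
    return seeds
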