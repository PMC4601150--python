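"""Cross-section measurement along a vessel segment.

At a fixed arc-length step along the centerline, the volume is resampled
on a plane orthogonal to the local tangent; the lumen cross-section is
segmented as the thresholded connected region around the centerline with
curvature-controlled boundary smoothing (the analogue of a
thresholding-based level-set contour with curvature scale 10); and two
quantities are measured on the mask: the area (pixel count times pixel
area) and the shortest diameter, formalized as the minimum Feret width of
the region over rotation angles at a 1-degree step.

Per-segment extremes follow the reference-position rules: the minima MinD
and MinA are taken over all positions (independently), while the maxima
MaxD and MaxA only over positions at least 10 mm from the aorta and 5 mm
from a bounding bifurcation, falling back to the unrestricted maxima (with
a flag) when no position qualifies — the automated counterpart of reading
the reference visually.  Relative reductions are

    Dred = (1 - MinD/MaxD) * 100 %      Ared = (1 - MinA/MaxA) * 100 %
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes, map_coordinates
from skimage.measure import label as cc_label
from skimage.morphology import closing as _closing, disk, opening as _opening

from .centerline import VesselSegment
from .thresholds import ThresholdSet
from .volume import ImageVolume

DEFAULT_STEP_MM = 0.5  # arc-length sampling step (about the finest voxel pitch)
DEFAULT_INPLANE_STEP_MM = 0.2
DEFAULT_FOV_MM = 12.0
FERET_ANGLE_STEP_DEG = 1.0
MIN_AORTA_DISTANCE_MM = 10.0
BIFURCATION_MARGIN_MM = 5.0
DEFAULT_CURVATURE_SCALE = 10.0


# --------------------------------------------------------------------------- plane resampling
def _inplane_axes(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane axes: the tangent is crossed with
    the world axis most orthogonal to it, then orthonormalized."""
    t = np.asarray(tangent, dtype=float)
    norm = np.linalg.norm(t)
    if norm < 1e-12:
        raise ValueError("degenerate tangent vector")
    t = t / norm
    axis = int(np.argmin(np.abs(t)))
    e = np.zeros(3)
    e[axis] = 1.0
    u = np.cross(t, e)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def resample_plane(
    volume: ImageVolume,
    origin_mm: np.ndarray,
    tangent: np.ndarray,
    fov_mm: float = DEFAULT_FOV_MM,
    step_mm: float = DEFAULT_INPLANE_STEP_MM,
) -> np.ndarray:
    """Trilinear resampling of the plane orthogonal to ``tangent``.

    Returns a square 2-D image of side ``round(fov/step)+1`` pixels centred
    on ``origin_mm``; sampling positions outside the volume take the edge
    value (the background surround of any realistic field of view).
    """
    u, v = _inplane_axes(tangent)
    half = fov_mm / 2.0
    coords_1d = np.arange(-half, half + step_mm / 2, step_mm)
    uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    pts = (
        np.asarray(origin_mm)[None, None, :]
        + uu[..., None] * u[None, None, :]
        + vv[..., None] * v[None, None, :]
    )
    vox = (pts - np.asarray(volume.origin)) / np.asarray(volume.spacing)
    img = map_coordinates(
        volume.values, vox.reshape(-1, 3).T, order=1, mode="nearest"
    ).reshape(uu.shape)
    return img


# --------------------------------------------------------------------------- 2-D segmentation
def _smoothing_radius_px(curvature_scale: float, step_mm: float) -> int:
    # maps the level-set curvature weight to a morphological regularization
    # radius: scale 10 at the default 0.2 mm pixel pitch gives a 2-pixel disc
    return max(1, int(round(curvature_scale * step_mm)))


def segment_cross_section(
    image_2d: np.ndarray,
    thresholds: ThresholdSet,
    seed_px: tuple[int, int] | None = None,
    curvature_scale: float = DEFAULT_CURVATURE_SCALE,
    step_mm: float = DEFAULT_INPLANE_STEP_MM,
) -> np.ndarray:
    """Smoothed connected in-band region around the seed pixel.

    The raw region is all pixels in [LT, UT]; the component containing the
    seed is regularized by hole filling plus morphological closing/opening
    with a disc whose radius grows with ``curvature_scale``.  Pixels above
    UT (calcified plaque) are never part of the lumen mask.  A seed outside
    the band yields an empty mask.
    """
    img = np.asarray(image_2d, dtype=float)
    if seed_px is None:
        seed_px = (img.shape[0] // 2, img.shape[1] // 2)
    in_band = img >= thresholds.lt
    over = np.zeros_like(in_band)
    if thresholds.ut is not None:
        over = img > thresholds.ut
        in_band &= ~over
    if not in_band[seed_px]:
        # search a small neighbourhood (1 mm) for the nearest in-band pixel
        r = max(1, int(round(1.0 / step_mm)))
        y0, x0 = seed_px
        ys = slice(max(0, y0 - r), min(img.shape[0], y0 + r + 1))
        xs = slice(max(0, x0 - r), min(img.shape[1], x0 + r + 1))
        window = in_band[ys, xs]
        if not window.any():
            return np.zeros_like(in_band)
        yy, xx = np.nonzero(window)
        d2 = (yy + ys.start - y0) ** 2 + (xx + xs.start - x0) ** 2
        k = int(np.argmin(d2))
        seed_px = (int(yy[k] + ys.start), int(xx[k] + xs.start))
    comps = cc_label(in_band, connectivity=2)
    mask = comps == comps[seed_px]
    mask = binary_fill_holes(mask)
    selem = disk(_smoothing_radius_px(curvature_scale, step_mm))
    mask = _opening(_closing(mask, selem), selem).astype(bool)
    mask &= ~over
    comps = cc_label(mask, connectivity=2)
    if not mask[seed_px]:
        # smoothing may have shifted the region off the exact seed pixel
        if not mask.any():
            return mask
        yy, xx = np.nonzero(mask)
        k = int(np.argmin((yy - seed_px[0]) ** 2 + (xx - seed_px[1]) ** 2))
        seed_px = (int(yy[k]), int(xx[k]))
        comps = cc_label(mask, connectivity=2)
    return comps == comps[seed_px]


# --------------------------------------------------------------------------- measurement
def measure_mask(mask: np.ndarray, in_plane_spacing_mm: float) -> tuple[float, float]:
    """Area (mm^2) and shortest (minimum Feret) diameter (mm) of a region."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    px = float(in_plane_spacing_mm)
    area = n * px * px
    coords = np.argwhere(mask).astype(float) * px
    if n > 3:
        try:
            from scipy.spatial import ConvexHull

            coords = coords[ConvexHull(coords).vertices]
        except Exception:  # collinear / degenerate: fall back to all pixels
            pass
    angles = np.deg2rad(np.arange(0.0, 180.0, FERET_ANGLE_STEP_DEG))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = coords @ dirs.T  # (points, angles)
    widths = proj.max(axis=0) - proj.min(axis=0) + px  # pixel footprint included
    return area, float(widths.min())


@dataclass
class CrossSection:
    arc_length: float  # mm from the aorta along the tree
    area_mm2: float | None
    shortest_diameter_mm: float | None
    eligible_for_max: bool
    mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def valid(self) -> bool:
        return self.area_mm2 is not None


@dataclass
class SegmentProfile:
    """Ordered cross-sections of one segment at a fixed arc-length step."""

    artery_id: int
    segment_index: int
    cross_sections: list[CrossSection]
    step_mm: float

    @property
    def arc_lengths(self) -> np.ndarray:
        return np.array([c.arc_length for c in self.cross_sections])

    @property
    def measurable(self) -> bool:
        return any(c.valid for c in self.cross_sections)


@dataclass
class SegmentSummary:
    """Per-segment extremes and relative reductions."""

    min_d_mm: float | None = None
    min_a_mm2: float | None = None
    max_d_mm: float | None = None
    max_a_mm2: float | None = None
    dred_pct: float | None = None
    ared_pct: float | None = None
    fallback_used: bool = False
    measurable: bool = True

    def __post_init__(self) -> None:
        if self.measurable and self.min_d_mm is not None:
            assert self.min_d_mm <= self.max_d_mm + 1e-9
            assert self.min_a_mm2 <= self.max_a_mm2 + 1e-9


def dred(min_d: float, max_d: float) -> float:
    """Relative diameter reduction (1 - MinD/MaxD) * 100, in percent."""
    if max_d <= 0:
        raise ValueError("MaxD must be positive")
    value = (1.0 - min_d / max_d) * 100.0
    if value < 0:
        warnings.warn("MinD exceeds MaxD (measurement noise); clamping to 0 %", stacklevel=2)
    return float(np.clip(value, 0.0, 100.0))


def ared(min_a: float, max_a: float) -> float:
    """Relative area reduction (1 - MinA/MaxA) * 100, in percent."""
    if max_a <= 0:
        raise ValueError("MaxA must be positive")
    value = (1.0 - min_a / max_a) * 100.0
    if value < 0:
        warnings.warn("MinA exceeds MaxA (measurement noise); clamping to 0 %", stacklevel=2)
    return float(np.clip(value, 0.0, 100.0))


def profile_segment(
    volume: ImageVolume,
    segment: VesselSegment,
    thresholds: ThresholdSet,
    step_mm: float = DEFAULT_STEP_MM,
    inplane_step_mm: float = DEFAULT_INPLANE_STEP_MM,
    fov_mm: float = DEFAULT_FOV_MM,
    curvature_scale: float = DEFAULT_CURVATURE_SCALE,
    min_aorta_distance_mm: float = MIN_AORTA_DISTANCE_MM,
    bifurcation_margin_mm: float = BIFURCATION_MARGIN_MM,
    keep_masks: bool = False,
) -> SegmentProfile:
    """Measure cross-sections along the whole segment at ``step_mm``."""
    if len(segment.positions) < 2:
        raise ValueError("segment needs at least 2 centerline nodes")
    s0, s1 = float(segment.arc_from_root[0]), float(segment.arc_from_root[-1])
    stations = np.arange(s0, s1 + step_mm / 2, step_mm)
    sections: list[CrossSection] = []
    for s in stations:
        pos, tan = segment.interpolate(s)
        img = resample_plane(volume, pos, tan, fov_mm=fov_mm, step_mm=inplane_step_mm)
        mask = segment_cross_section(
            img, thresholds, curvature_scale=curvature_scale, step_mm=inplane_step_mm
        )
        eligible = s >= min_aorta_distance_mm
        if segment.bif_start_arc is not None:
            eligible &= (s - segment.bif_start_arc) >= bifurcation_margin_mm
        if segment.bif_end_arc is not None:
            eligible &= (segment.bif_end_arc - s) >= bifurcation_margin_mm
        if mask.any():
            area, diameter = measure_mask(mask, inplane_step_mm)
            sections.append(
                CrossSection(float(s), area, diameter, bool(eligible), mask if keep_masks else None)
            )
        else:
            sections.append(CrossSection(float(s), None, None, bool(eligible)))
    return SegmentProfile(segment.artery_id, segment.index, sections, step_mm)


def summarize_segment(profile: SegmentProfile) -> SegmentSummary:
    """Extremes over the profile: minima over all valid positions, maxima
    over eligible positions only (independently per measure), with the
    unrestricted-maximum fallback when no position is eligible."""
    valid = [c for c in profile.cross_sections if c.valid]
    if not valid:
        return SegmentSummary(measurable=False)
    diameters = np.array([c.shortest_diameter_mm for c in valid])
    areas = np.array([c.area_mm2 for c in valid])
    eligible = np.array([c.eligible_for_max for c in valid])
    min_d, min_a = float(diameters.min()), float(areas.min())
    fallback = not eligible.any()
    if fallback:
        max_d, max_a = float(diameters.max()), float(areas.max())
    else:
        max_d = float(diameters[eligible].max())
        max_a = float(areas[eligible].max())
    # noise can leave the global minimum above the eligible maximum
    max_d, max_a = max(max_d, min_d), max(max_a, min_a)
    return SegmentSummary(
        min_d_mm=min_d,
        min_a_mm2=min_a,
        max_d_mm=max_d,
        max_a_mm2=max_a,
        dred_pct=dred(min_d, max_d),
        ared_pct=ared(min_a, max_a),
        fallback_used=fallback,
        measurable=True,
    )
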