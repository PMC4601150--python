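"""Segmentation thresholds from aorta and background ROI statistics.

The lower threshold separating contrast-filled lumen from background is

    LT = (aorta + 2 * background) / 3

where ``aorta`` is the contrast value — the mean of the per-slice ROI
maxima at the reference slice (the axial slice whose aorta-ROI mean is
greatest) and the slices 10 mm proximal and 10 mm distal — and
``background`` is the mean of the ROI means in non-contrast-filled tissue
(four psoas-muscle ROIs for CTA, three vertebral-body ROIs for MRA).  For
CTA an upper threshold (UT) is additionally derived with the same
three-slice maximum recipe, to exclude calcified plaque whose attenuation
exceeds that of contrast-mixed blood; UT is undefined for MRA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import ImageVolume

STRICT_ROI_COUNTS = {"CTA": 4, "MRA": 3}
SLICE_OFFSET_MM = 10.0


@dataclass
class CircularRoi:
    """Circular disc ROI in an axial plane."""

    slice_index: int
    center_yx_mm: tuple[float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("ROI radius must be positive")

    def voxel_values(self, volume: ImageVolume, slice_index: int | None = None) -> np.ndarray:
        """Intensities of the disc applied at ``slice_index`` (default: own slice)."""
        k = self.slice_index if slice_index is None else slice_index
        if not 0 <= k < volume.shape[0]:
            raise ValueError(f"ROI slice {k} outside volume of {volume.shape[0]} slices")
        cy, cx = self.center_yx_mm
        y = volume.voxel_centers(1) - volume.origin[1]
        x = volume.voxel_centers(2) - volume.origin[2]
        yy, xx = np.meshgrid(y, x, indexing="ij")
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius_mm**2
        if not mask.any():
            raise ValueError("ROI contains no voxel centres")
        ey, ex = volume.extent_mm[1], volume.extent_mm[2]
        if not (0 <= cy <= ey and 0 <= cx <= ex):
            raise ValueError(f"ROI centre ({cy}, {cx}) mm outside the volume extent")
        return volume.values[k][mask]


@dataclass
class RoiSet:
    """A set of ROIs targeting one structure (aorta, psoas or vertebral)."""

    rois: list[CircularRoi]
    target: str = "aorta"

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("empty ROI set")
        if self.target not in ("aorta", "psoas", "vertebral"):
            raise ValueError(f"unknown ROI target {self.target!r}")

    def slices(self) -> list[int]:
        return sorted({r.slice_index for r in self.rois})

    def on_slice(self, k: int) -> list[CircularRoi]:
        return [r for r in self.rois if r.slice_index == k]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "target": self.target,
                    "rois": [
                        {
                            "slice_index": r.slice_index,
                            "center_yx_mm": list(r.center_yx_mm),
                            "radius_mm": r.radius_mm,
                        }
                        for r in self.rois
                    ],
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "RoiSet":
        with open(path) as fh:
            payload = json.load(fh)
        rois = [
            CircularRoi(d["slice_index"], tuple(d["center_yx_mm"]), d["radius_mm"])
            for d in payload["rois"]
        ]
        return cls(rois, payload.get("target", "aorta"))


@dataclass
class ThresholdSet:
    """Lower (and for CTA upper) segmentation thresholds with provenance."""

    aorta_value: float
    background_value: float
    lt: float
    ut: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.background_value < self.aorta_value and not (
            self.background_value <= self.lt <= self.aorta_value
        ):
            raise ValueError("LT must lie between background and aorta values")
        if self.ut is not None and self.ut < self.aorta_value:
            raise ValueError("UT must not be below the aorta value")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "aorta_value": self.aorta_value,
                    "background_value": self.background_value,
                    "lt": self.lt,
                    "ut": self.ut,
                    "provenance": self.provenance,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "ThresholdSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


# --------------------------------------------------------------------------- operations
def locate_reference_slice(volume: ImageVolume, aorta_rois: RoiSet) -> int:
    """Axial slice whose aorta-ROI mean is maximal; ties go to the smallest index."""
    slices = aorta_rois.slices()
    means = []
    for k in slices:
        vals = np.concatenate([r.voxel_values(volume) for r in aorta_rois.on_slice(k)])
        means.append(vals.mean())
    return int(slices[int(np.argmax(means))])  # argmax returns the first maximum


def _three_slice_maxima(
    volume: ImageVolume, aorta_rois: RoiSet, ref_slice: int
) -> tuple[list[float], list[int]]:
    offset = int(round(SLICE_OFFSET_MM / volume.spacing[0]))
    wanted = [ref_slice - offset, ref_slice, ref_slice + offset]
    used = [min(max(k, 0), volume.shape[0] - 1) for k in wanted]
    if used != wanted:
        warnings.warn(
            f"slices at +/-{SLICE_OFFSET_MM} mm fall outside the volume; clamped to {used}",
            stacklevel=3,
        )
    discs = aorta_rois.on_slice(ref_slice)
    if not discs:
        raise ValueError(f"no aorta ROI on reference slice {ref_slice}")
    maxima = [
        float(max(r.voxel_values(volume, slice_index=k).max() for r in discs)) for k in used
    ]
    return maxima, used


def compute_contrast_value(
    volume: ImageVolume, aorta_rois: RoiSet, ref_slice: int | None = None
) -> float:
    """Contrast (aorta) value: mean of the per-slice ROI maxima at the
    reference slice and the slices 10 mm proximal and distal."""
    if ref_slice is None:
        ref_slice = locate_reference_slice(volume, aorta_rois)
    maxima, _ = _three_slice_maxima(volume, aorta_rois, ref_slice)
    return float(np.mean(maxima))


def compute_background_value(
    volume: ImageVolume, background_rois: RoiSet, modality: str = "CTA", strict: bool = True
) -> float:
    """Background value: mean over ROIs of the per-ROI mean intensity."""
    expected = STRICT_ROI_COUNTS.get(modality)
    if strict and expected is not None and len(background_rois.rois) != expected:
        raise ValueError(
            f"{modality} expects {expected} background ROIs, got {len(background_rois.rois)}"
        )
    means = [float(r.voxel_values(volume).mean()) for r in background_rois.rois]
    return float(np.mean(means))


def compute_lower_threshold(aorta_value: float, background_value: float) -> float:
    """LT = (aorta + 2*background) / 3."""
    if not (np.isfinite(aorta_value) and np.isfinite(background_value)):
        raise ValueError("non-finite threshold inputs")
    return (aorta_value + 2.0 * background_value) / 3.0


def compute_upper_threshold(
    volume: ImageVolume, aorta_rois: RoiSet, modality: str = "CTA", ref_slice: int | None = None
) -> float:
    """UT (CTA only): mean of the three per-slice aorta-ROI maxima.

    Numerically the same recipe as the contrast value; kept distinct because
    UT exists only for CTA and may be derived from different ROI placements.
    """
    if modality != "CTA":
        raise ValueError("the upper threshold is defined for CTA only")
    if ref_slice is None:
        ref_slice = locate_reference_slice(volume, aorta_rois)
    maxima, _ = _three_slice_maxima(volume, aorta_rois, ref_slice)
    return float(np.mean(maxima))


def estimate_thresholds(
    volume: ImageVolume,
    aorta_rois: RoiSet,
    background_rois: RoiSet,
    modality: str = "CTA",
    strict: bool = True,
) -> ThresholdSet:
    """Full threshold derivation for one volume."""
    ref_slice = locate_reference_slice(volume, aorta_rois)
    aorta = compute_contrast_value(volume, aorta_rois, ref_slice=ref_slice)
    background = compute_background_value(volume, background_rois, modality, strict=strict)
    lt = compute_lower_threshold(aorta, background)
    ut = (
        compute_upper_threshold(volume, aorta_rois, modality, ref_slice=ref_slice)
        if modality == "CTA"
        else None
    )
    _, used = _three_slice_maxima(volume, aorta_rois, ref_slice)
    return ThresholdSet(
        aorta_value=aorta,
        background_value=background,
        lt=lt,
        ut=ut,
        provenance={"reference_slice": ref_slice, "slices_used": used, "modality": modality},
    )


def default_phantom_rois(spec, volume: ImageVolume) -> tuple[RoiSet, RoiSet]:
    """Programmatic ROI placement for generated phantoms: aorta discs on
    every 4th slice along the aorta axis, background discs in tissue clear
    of all structures (stands in for the manual placement on clinical scans)."""
    from .phantom import PhantomSpec  # noqa: F401  (type only)

    nz = volume.shape[0]
    cy, cx = spec.aorta.center_yx_mm
    # keep ROI slices far enough from the ends that +/-10 mm slices exist
    margin = int(np.ceil(SLICE_OFFSET_MM / volume.spacing[0])) + 1
    slices = list(range(margin, nz - margin, 4)) or [nz // 2]
    aorta = RoiSet(
        [CircularRoi(k, (cy, cx), radius_mm=0.5 * spec.aorta.radius_mm) for k in slices],
        target="aorta",
    )
    ey, ex = volume.extent_mm[1], volume.extent_mm[2]
    modality = "CTA" if abs(volume.spacing[0] - 0.75) < 0.3 else "MRA"
    n_bg = STRICT_ROI_COUNTS[modality]
    slots = np.linspace(0.55, 0.9, n_bg)
    background = RoiSet(
        [
            CircularRoi(int(nz * 0.5), (0.15 * ey, f * ex), radius_mm=2.0)
            for f in slots
        ],
        target="psoas" if modality == "CTA" else "vertebral",
    )
    return aorta, background
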