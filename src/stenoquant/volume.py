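"""3-D scalar image volume with physical (mm) coordinates.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` — slice, row, column;
* ``spacing`` is mm per axis in the same ``(z, y, x)`` order, so an
  anisotropic CTA-like grid is ``(0.75, 0.5, 0.5)`` and an MRA-like one
  ``(2.0, 0.7, 0.7)``;
* world coordinates are mm, with the centre of voxel ``(0, 0, 0)`` at
  ``origin``; all distances are computed in mm, never in voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """A 3-D scalar grid with anisotropic voxel spacing.

    Parameters
    ----------
    values
        3-D float array indexed ``(z, y, x)``.
    spacing
        Voxel size in mm per axis, ``(z, y, x)``. Must be positive.
    origin
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = field(default="zyx", repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.axis_order != "zyx":
            raise ValueError("only 'zyx' axis order is supported")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical extent (mm) spanned by voxel centres along each axis."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert world mm coordinates to continuous (z, y, x) voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = (pts - np.asarray(self.origin)) / np.asarray(self.spacing)
        return out if np.asarray(points_mm).ndim > 1 else out[0]

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Convert (z, y, x) voxel indices (possibly fractional) to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        out = idx * np.asarray(self.spacing) + np.asarray(self.origin)
        return out if np.asarray(indices).ndim > 1 else out[0]

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World mm coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def contains_world(self, points_mm: np.ndarray) -> np.ndarray:
        """Whether world points fall inside the voxel-centre bounding box."""
        idx = np.atleast_2d(self.world_to_voxel(points_mm))
        shape = np.asarray(self.shape)
        ok = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
        return ok if np.asarray(points_mm).ndim > 1 else bool(ok[0])

    # ------------------------------------------------------------------ I/O
    def save(self, path: str) -> None:
        """Write as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
        path = str(path)
        if path.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            # nibabel stores (x, y, z); our arrays are (z, y, x)
            data = np.transpose(self.values, (2, 1, 0))
            affine = np.diag([self.spacing[2], self.spacing[1], self.spacing[0], 1.0])
            affine[:3, 3] = [self.origin[2], self.origin[1], self.origin[0]]
            nib.save(nib.Nifti1Image(data, affine), path)
        elif path.endswith((".mha", ".mhd")):
            import SimpleITK as sitk

            img = sitk.GetImageFromArray(self.values)  # SimpleITK expects (z, y, x)
            img.SetSpacing((self.spacing[2], self.spacing[1], self.spacing[0]))
            img.SetOrigin((self.origin[2], self.origin[1], self.origin[0]))
            sitk.WriteImage(img, path)
        else:
            raise ValueError(f"unsupported volume format: {path}")

    @classmethod
    def load(cls, path: str) -> "ImageVolume":
        path = str(path)
        if path.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(path)
            data = np.transpose(np.asanyarray(img.dataobj, dtype=float), (2, 1, 0))
            zooms = img.header.get_zooms()[:3]  # (x, y, z)
            origin_xyz = img.affine[:3, 3]
            return cls(
                data,
                spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
                origin=(float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0])),
            )
        if path.endswith((".mha", ".mhd")):
            import SimpleITK as sitk

            img = sitk.ReadImage(path)
            data = sitk.GetArrayFromImage(img).astype(float)
            sp = img.GetSpacing()  # (x, y, z)
            og = img.GetOrigin()
            return cls(
                data,
                spacing=(float(sp[2]), float(sp[1]), float(sp[0])),
                origin=(float(og[2]), float(og[1]), float(og[0])),
            )
        raise ValueError(f"unsupported volume format: {path}")
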