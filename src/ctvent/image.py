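"""3D scalar image volumes on a regular grid.

The universal carrier for phantom images, noisy acquisitions, lung masks
and ventilation maps.  Geometry is axis-aligned: physical position of voxel
index ``(i, j, k)`` is ``origin + index * spacing`` (mm); direction cosines
are not supported.  Array axis order is ``(x, y, z)``, matching the NIfTI
convention used by nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3D scalar grid (HU, a binary mask, or a unitless map).

    Parameters
    ----------
    data:
        3D array; HU for CT images, {0,1} for masks, unitless for
        ventilation maps.
    spacing:
        Voxel size in mm per axis.
    origin:
        Physical position (mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres (1 cc = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def physical_coords(self, sparse: bool = True):
        """Meshgrid of physical coordinates (mm) per axis, indexing='ij'."""
        axes = [
            self.origin[d] + np.arange(self.shape[d]) * self.spacing[d]
            for d in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=sparse)

    def index_from_physical(self, points: np.ndarray) -> np.ndarray:
        """Convert physical points (..., 3) in mm to fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    # -- I/O ----------------------------------------------------------------
    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str, dtype=None) -> None:
        arr = self.data if dtype is None else self.data.astype(dtype)
        nib.save(nib.Nifti1Image(arr, self.affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "ImageVolume":
        img = nib.load(path)
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
            raise ValueError("only axis-aligned volumes are supported")
        spacing = tuple(float(s) for s in np.diag(aff[:3, :3]))
        if any(s < 0 for s in spacing):
            raise ValueError("negative spacing (flipped axes) not supported")
        return cls(
            data=np.asarray(img.dataobj),
            spacing=spacing,
            origin=tuple(float(o) for o in aff[:3, 3]),
        )

    def copy(self, data: np.ndarray | None = None) -> "ImageVolume":
        return ImageVolume(
            data=self.data.copy() if data is None else data,
            spacing=self.spacing,
            origin=self.origin,
            meta=dict(self.meta),
        )
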