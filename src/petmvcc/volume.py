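"""Minimal 3-D volume container with NIfTI-1 round-tripping.

All image stages of the package consume and produce :class:`Volume`.
Volumes are assumed to live on an axis-aligned grid in a common
(MNI-like) space: the affine is diagonal with per-axis voxel size and a
world-space origin at voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3-D intensity grid with voxel size and origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities. Must be finite.
    voxel_size_mm : tuple of float
        Edge length of a voxel along each axis, in mm; all positive.
    origin_mm : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (diagonal scaling + origin)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def index_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Convert voxel indices (..., 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=np.float64)
        return ijk * np.asarray(self.voxel_size_mm) + np.asarray(self.origin_mm)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        return Volume(
            data=self.data.copy() if data is None else np.asarray(data, dtype=np.float64),
            voxel_size_mm=self.voxel_size_mm,
            origin_mm=self.origin_mm,
        )

    # -- NIfTI I/O -----------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float64), self.affine)
        img.header.set_zooms(self.voxel_size_mm)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "Volume":
        aff = img.affine
        voxel = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(v) for v in aff[:3, 3])
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        return cls(data=data, voxel_size_mm=voxel, origin_mm=origin)

    @classmethod
    def load(cls, path) -> "Volume":
        return cls.from_nifti(nib.load(str(path)))
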