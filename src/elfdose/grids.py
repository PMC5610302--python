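"""Voxel-grid containers shared by every stage of the pipeline.

An :class:`ImageVolume` is a 3D scalar grid with per-axis physical spacing
(in-plane pixel spacing and slice thickness, in mm), an origin, and a
modality tag (``dwi`` for the pre-treatment diffusion-weighted volume,
``flair`` for the post-treatment T2-FLAIR volume).  A :class:`LesionMask`
is a binary grid sharing the same geometry; it is both the segmentation
output and the dosimetry region of interest.

Conventions: voxel indices are 0-based ``(i, j, k)`` with ``k`` the axial
slice index; the physical coordinate of voxel ``(i, j, k)`` is its center,
``origin_mm + (i, j, k) * spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

MODALITIES = ("dwi", "flair")


def _check_geometry(data: np.ndarray, spacing_mm, origin_mm) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
    spacing = np.asarray(spacing_mm, dtype=float)
    origin = np.asarray(origin_mm, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing_mm and origin_mm must be length-3")
    if not np.all(spacing > 0):
        raise ValueError(f"spacing components must be > 0, got {spacing_mm}")


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image with physical voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities; must be finite.
    spacing_mm : (float, float, float)
        Per-axis voxel size: (pixel_x, pixel_y, slice_thickness).
    origin_mm : (float, float, float)
        Physical coordinate of the center of voxel (0, 0, 0).
    modality : {"dwi", "flair"}
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "dwi"

    def __post_init__(self):
        _check_geometry(self.data, self.spacing_mm, self.origin_mm)
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_center_mm(self, index) -> np.ndarray:
        """Physical coordinate (mm) of a voxel center."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(self.spacing_mm)

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, modality: str = "dwi") -> "ImageVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()[:3]
        origin = img.affine[:3, 3]
        return cls(data=data, spacing_mm=tuple(zooms), origin_mm=tuple(origin), modality=modality)


@dataclass(frozen=True)
class LesionMask:
    """A binary voxel mask sharing an :class:`ImageVolume`'s geometry."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        _check_geometry(self.data, self.spacing_mm, self.origin_mm)
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def same_geometry_as(self, other) -> bool:
        return (
            self.shape == other.shape
            and self.spacing_mm == other.spacing_mm
            and self.origin_mm == other.origin_mm
        )

    def voxel_centers_mm(self) -> np.ndarray:
        """Physical coordinates (mm) of all masked voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.data).astype(float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def with_data(self, data: np.ndarray) -> "LesionMask":
        return replace(self, data=data)

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "LesionMask":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj) > 0
        return cls(data=data, spacing_mm=tuple(img.header.get_zooms()[:3]),
                   origin_mm=tuple(img.affine[:3, 3]))
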