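"""Seeded region-growing lesion segmentation and voxel volumetry.

The segmentation rule mirrors semi-automated clinical tools: starting from
operator-chosen seed voxels inside the hyperintense lesion, neighboring
voxels are added while their intensity stays within a band of 20% of the
seed's own intensity.  Growth is 2D with 8-connectivity inside each axial
slice, matching section-by-section reading; a ``2d_propagate`` mode carries
the grown footprint into adjacent slices (emulating the reader seeding
every section of a lesion from a single click), and a ``3d`` mode grows
with full 26-connectivity.  A manual-editing surrogate applies explicit
add/remove masks, and volumetry multiplies the voxel count by pixel
spacing and slice thickness.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ImageVolume, LesionMask

logger = logging.getLogger(__name__)

GROWTH_MODES = ("2d", "2d_propagate", "3d")
BANDS = ("symmetric", "upper")


@dataclass(frozen=True)
class SeedPoint:
    """A 0-based voxel index (i, j, k); k is the axial slice."""

    index: tuple[int, int, int]

    def __post_init__(self):
        idx = tuple(int(v) for v in self.index)
        if len(idx) != 3:
            raise ValueError("seed index must have 3 components")
        object.__setattr__(self, "index", idx)


def _structure(connectivity: int, ndim: int) -> np.ndarray:
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    # 4 -> faces only (6-connectivity in 3D); 8 -> full neighborhood (26 in 3D)
    rank = 1 if connectivity == 4 else ndim
    return ndimage.generate_binary_structure(ndim, rank)


def _band_predicate(data: np.ndarray, seed_intensity: float, rel_threshold: float,
                    band: str) -> np.ndarray:
    tol = rel_threshold * seed_intensity
    if band == "symmetric":
        return np.abs(data - seed_intensity) <= tol
    if band == "upper":
        return data >= seed_intensity - tol
    raise ValueError(f"band must be one of {BANDS}, got {band!r}")


def region_grow(volume: ImageVolume, seeds, rel_threshold: float = 0.20,
                connectivity: int = 8, mode: str = "2d",
                band: str = "symmetric") -> LesionMask:
    """Grow a lesion mask from seed voxels.

    Each seed defines its own inclusion band from its own intensity
    ``I_s``: a voxel qualifies when ``|I - I_s| <= rel_threshold * I_s``
    (or ``I >= (1 - rel_threshold) * I_s`` with ``band="upper"``).  The
    mask is the union over seeds of the voxels connected to the seed
    through qualifying voxels; the result depends only on that reachable
    set, so it is invariant to seed order and traversal strategy.

    Parameters
    ----------
    mode : {"2d", "2d_propagate", "3d"}
        "2d" confines each seed's region to its own axial slice;
        "2d_propagate" grows slice-by-slice, using the in-plane footprint
        of each grown section to seed the neighboring sections;
        "3d" grows in the full volume (26-connectivity when
        ``connectivity=8``).
    """
    if mode not in GROWTH_MODES:
        raise ValueError(f"mode must be one of {GROWTH_MODES}, got {mode!r}")
    seeds = [s if isinstance(s, SeedPoint) else SeedPoint(tuple(s)) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed is required")

    data = volume.data
    out = np.zeros(data.shape, dtype=bool)
    for seed in seeds:
        i, j, k = seed.index
        if not (0 <= i < data.shape[0] and 0 <= j < data.shape[1] and 0 <= k < data.shape[2]):
            raise IndexError(f"seed {seed.index} outside grid {data.shape}")
        seed_intensity = float(data[i, j, k])
        if seed_intensity <= 0:
            raise ValueError(
                f"seed {seed.index} has intensity {seed_intensity} <= 0; "
                "the relative threshold band is degenerate")
        pred = _band_predicate(data, seed_intensity, rel_threshold, band)
        out |= _grow_one(pred, seed.index, connectivity, mode)
    return LesionMask(out, volume.spacing_mm, volume.origin_mm)


def _grow_one(pred: np.ndarray, seed_index, connectivity: int, mode: str) -> np.ndarray:
    i, j, k = seed_index
    if mode == "3d":
        labels, _ = ndimage.label(pred, structure=_structure(connectivity, 3))
        return labels == labels[i, j, k]

    structure = _structure(connectivity, 2)
    nz = pred.shape[2]
    if mode == "2d":
        labels, _ = ndimage.label(pred[:, :, k], structure=structure)
        out = np.zeros(pred.shape, dtype=bool)
        out[:, :, k] = labels == labels[i, j]
        return out

    # 2d_propagate: BFS over per-slice connected components, linked by
    # voxel-wise (i, j) overlap between adjacent slices.
    slice_labels = [ndimage.label(pred[:, :, kk], structure=structure)[0] for kk in range(nz)]
    out = np.zeros(pred.shape, dtype=bool)
    start = (k, int(slice_labels[k][i, j]))
    if start[1] == 0:
        return out  # seed voxel itself outside the band (cannot happen for rel_threshold >= 0)
    seen = {start}
    queue = deque([start])
    while queue:
        kk, lab = queue.popleft()
        comp = slice_labels[kk] == lab
        out[:, :, kk] |= comp
        for k2 in (kk - 1, kk + 1):
            if not 0 <= k2 < nz:
                continue
            for lab2 in np.unique(slice_labels[k2][comp]):
                if lab2 != 0 and (k2, int(lab2)) not in seen:
                    seen.add((k2, int(lab2)))
                    queue.append((k2, int(lab2)))
    return out


def edit_mask(mask: LesionMask, add: LesionMask, remove: LesionMask) -> LesionMask:
    """Manual-editing surrogate: ``(mask | add) & ~remove``; remove wins."""
    for other, name in ((add, "add"), (remove, "remove")):
        if not mask.same_geometry_as(other):
            raise ValueError(f"'{name}' mask geometry does not match the base mask")
    return mask.with_data((mask.data | add.data) & ~remove.data)


def lesion_volume(mask: LesionMask, spacing_mm=None) -> float:
    """Lesion volume in cm^3: voxel count x pixel spacing x slice thickness."""
    spacing = np.asarray(spacing_mm if spacing_mm is not None else mask.spacing_mm, dtype=float)
    if not np.all(spacing > 0):
        raise ValueError(f"spacing must be positive, got {spacing}")
    count = mask.voxel_count
    if count == 0:
        logger.warning("lesion mask is empty; volume is 0.0 cm^3")
        return 0.0
    return float(count * spacing.prod() / 1000.0)  # mm^3 -> cm^3


def per_slice_areas(mask: LesionMask) -> pd.DataFrame:
    """Per-axial-slice voxel counts and areas (mm^2) of a mask."""
    counts = mask.data.sum(axis=(0, 1))
    px, py, _ = mask.spacing_mm
    return pd.DataFrame({
        "slice": np.arange(mask.shape[2]),
        "voxel_count": counts.astype(int),
        "area_mm2": counts * px * py,
    })
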