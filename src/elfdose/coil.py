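"""Magnetostatic model of the single-turn stimulation coil.

The stimulation device drives a single-turn rectangular coil of
14 x 10.6 cm with a 240 A pulsed current; at these extremely low
frequencies (75 Hz) the field is quasi-static and tissue is transparent
to B, so the flux density anywhere in the head is the magnetostatic field
of the coil filament alone.  The coil is modeled as an ideal closed
polyline of straight current segments, each evaluated with the exact
finite-segment Biot-Savart closed form; a cylindrical warp bends the long
(14 cm) dimension onto the mean coronal head curvature while preserving
arc length.

Units are SI internally (meters, amperes, tesla); report-facing helpers
convert to cm and mT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import GeometryError, SingularityError

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import HeadModel

MU0 = 4.0e-7 * np.pi  # vacuum permeability, T m / A

#: default guard distance around the filament, meters
DEFAULT_GUARD_M = 1.0e-3


@dataclass(frozen=True)
class CoilGeometry:
    """An ordered closed polyline of 3D points carrying a drive current.

    ``vertices`` is an (n, 3) float array in meters; the loop is closed
    implicitly (the last vertex connects back to the first), so the number
    of straight segments equals the number of vertices.
    """

    vertices: np.ndarray
    current_A: float

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 3 or verts.shape[0] < 3:
            raise GeometryError("vertices must be an (n>=3, 3) array")
        # drop an explicit closing vertex so closure is always implicit
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        nxt = np.roll(verts, -1, axis=0)
        if np.any(np.linalg.norm(nxt - verts, axis=1) == 0):
            raise GeometryError("consecutive vertices must be distinct")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "current_A", float(self.current_A))

    @property
    def n_segments(self) -> int:
        return self.vertices.shape[0]

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Start and end points of every segment, each (n, 3)."""
        return self.vertices, np.roll(self.vertices, -1, axis=0)

    @property
    def perimeter_m(self) -> float:
        starts, ends = self.segments()
        return float(np.linalg.norm(ends - starts, axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def with_current(self, current_A: float) -> "CoilGeometry":
        return CoilGeometry(self.vertices.copy(), current_A)

    def reversed(self) -> "CoilGeometry":
        """Loop traversed in the opposite orientation (B reverses sign)."""
        return CoilGeometry(self.vertices[::-1].copy(), self.current_A)

    def save_vertices(self, path) -> None:
        """Plain-text vertex list, one ``x y z`` line per vertex (meters)."""
        np.savetxt(str(path), self.vertices, fmt="%.9e", header="x_m y_m z_m")

    @classmethod
    def load_vertices(cls, path, current_A: float) -> "CoilGeometry":
        return cls(np.loadtxt(str(path)), current_A)


def make_rect_coil(width_m: float = 0.14, height_m: float = 0.106,
                   current_A: float = 240.0, n_segments: int = 4) -> CoilGeometry:
    """Flat rectangular loop centered at the origin in the x-y plane.

    The width (default 14 cm) lies along x, the height (10.6 cm) along y,
    and the coil axis is +z.  The perimeter is discretized into
    ``n_segments`` straight segments with the four corners always kept as
    vertices; since the sides are straight, 4 segments already give the
    exact field, and finer discretization only matters once the coil is
    warped.
    """
    if width_m <= 0 or height_m <= 0:
        raise ValueError(f"coil dimensions must be positive, got {width_m} x {height_m}")
    if current_A <= 0:
        raise ValueError(f"current must be positive, got {current_A}")
    if n_segments < 4:
        raise ValueError("n_segments must be >= 4 (one per side)")

    a, b = width_m / 2.0, height_m / 2.0
    corners = np.array([[-a, -b], [a, -b], [a, b], [-a, b]], dtype=float)
    sides = np.array([width_m, height_m, width_m, height_m])
    # largest-remainder allocation of segments to sides, >= 1 each
    quota = n_segments * sides / sides.sum()
    counts = np.maximum(np.floor(quota).astype(int), 1)
    order = np.argsort(-(quota - np.floor(quota)))
    i = 0
    while counts.sum() < n_segments:
        counts[order[i % 4]] += 1
        i += 1
    while counts.sum() > n_segments:
        j = int(np.argmax(counts))
        counts[j] -= 1

    verts = []
    for s in range(4):
        p0, p1 = corners[s], corners[(s + 1) % 4]
        for t in np.arange(counts[s]) / counts[s]:
            verts.append(p0 + t * (p1 - p0))
    verts = np.column_stack([np.asarray(verts), np.zeros(len(verts))])
    return CoilGeometry(verts, current_A)


def warp_coil(coil: CoilGeometry, head: "HeadModel") -> CoilGeometry:
    """Wrap the coil's x-dimension onto a cylinder approximating the head.

    The cylinder models the mean head curvature in the coronal plane: its
    axis runs along y (the coil height direction) at height
    ``z = R`` in the coil frame, so the coil bends toward +z (into the
    head).  The map is arc-length preserving along x:
    ``(x, y, z) -> (R sin(x/R), y, R (1 - cos(x/R)) + z_shift)``,
    which recovers the flat coil as ``R -> inf``.  A nonzero
    ``surface_offset_mm`` shifts the whole coil by that standoff along -z.
    """
    radius_m = head.curvature_radius_mm / 1000.0
    half_width = float(np.max(np.abs(coil.vertices[:, 0])))
    if radius_m <= half_width:
        raise GeometryError(
            f"curvature radius {radius_m} m must exceed the coil half-width {half_width} m")
    x, y, z = coil.vertices.T
    wrapped = np.column_stack([
        radius_m * np.sin(x / radius_m),
        y,
        radius_m * (1.0 - np.cos(x / radius_m)) + z - head.surface_offset_mm / 1000.0,
    ])
    return CoilGeometry(wrapped, coil.current_A)


def _segment_fields(starts: np.ndarray, ends: np.ndarray, current_A: float,
                    points: np.ndarray, guard_m: float = DEFAULT_GUARD_M) -> np.ndarray:
    """Exact Biot-Savart field of straight segments at ``points``.

    Vectorized over (n_points, n_segments).  Returns (n_points, 3) tesla.
    Raises :class:`SingularityError` if any point lies within ``guard_m``
    of any segment.
    """
    P = points[:, None, :]            # (np, 1, 3)
    a = (ends - starts)[None, :, :]   # (1, ns, 3)
    r0 = P - starts[None, :, :]       # (np, ns, 3)
    r1 = P - ends[None, :, :]

    cross = np.cross(a, r0)                       # a x r0, (np, ns, 3)
    cross_sq = np.einsum("ijk,ijk->ij", cross, cross)
    alen = np.linalg.norm(a, axis=2)              # (1, ns)
    r0n = np.linalg.norm(r0, axis=2)
    r1n = np.linalg.norm(r1, axis=2)

    # distance from each point to each closed segment (for the guard)
    t = np.clip(np.einsum("ijk,ijk->ij", r0, np.broadcast_to(a, r0.shape)) / alen**2, 0.0, 1.0)
    closest = starts[None, :, :] + t[..., None] * a
    dist_seg = np.linalg.norm(P - closest, axis=2)
    if np.any(dist_seg < guard_m):
        bad = int(np.argwhere(dist_seg < guard_m)[0, 0])
        raise SingularityError(
            f"field point {bad} lies within the {guard_m * 1e3:.1f} mm guard distance "
            "of the conductor", guard_m=guard_m, point_index=bad)

    # perpendicular distance to the infinite line; where it vanishes the
    # point is collinear (outside the segment, or it would have tripped the
    # guard) and the contribution is exactly zero.
    with np.errstate(divide="ignore", invalid="ignore"):
        cos1 = np.einsum("ijk,ijk->ij", np.broadcast_to(a, r0.shape), r0) / (alen * r0n)
        cos2 = np.einsum("ijk,ijk->ij", np.broadcast_to(a, r1.shape), r1) / (alen * r1n)
        mag = MU0 * current_A / (4.0 * np.pi) * alen / cross_sq * (cos1 - cos2)
    mag = np.where(cross_sq > 0, mag, 0.0)
    return np.einsum("ij,ijk->ik", np.nan_to_num(mag), cross)


def biot_savart_segment(p_start, p_end, current_A: float, field_point,
                        guard_m: float = DEFAULT_GUARD_M) -> np.ndarray:
    """Flux-density contribution (tesla) of one finite straight segment.

    Closed form: the field circles the segment direction with magnitude
    ``mu0 I / (4 pi rho) * (cos(theta_1) - cos(theta_2))`` where ``rho`` is
    the perpendicular distance to the line and the thetas are the angles
    subtended at the two endpoints.  Collinear exterior points get exactly
    zero; points within ``guard_m`` of the segment raise
    :class:`SingularityError`.
    """
    starts = np.asarray(p_start, dtype=float)[None, :]
    ends = np.asarray(p_end, dtype=float)[None, :]
    pts = np.asarray(field_point, dtype=float)[None, :]
    return _segment_fields(starts, ends, current_A, pts, guard_m=guard_m)[0]


@dataclass(frozen=True)
class FieldGrid:
    """Per-point magnetic flux density evaluated from a coil."""

    points: np.ndarray  # (n, 3), meters
    B: np.ndarray       # (n, 3), tesla

    @property
    def magnitude_T(self) -> np.ndarray:
        return np.linalg.norm(self.B, axis=1)

    @property
    def magnitude_mT(self) -> np.ndarray:
        return self.magnitude_T * 1.0e3

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "x_m": self.points[:, 0], "y_m": self.points[:, 1], "z_m": self.points[:, 2],
            "Bx_T": self.B[:, 0], "By_T": self.B[:, 1], "Bz_T": self.B[:, 2],
            "Bmag_mT": self.magnitude_mT,
        })


def coil_field(coil: CoilGeometry, points, guard_m: float = DEFAULT_GUARD_M,
               chunk: int = 65536) -> FieldGrid:
    """Sum the segment fields of ``coil`` at ``points`` ((n, 3), meters).

    Linear in the drive current; evaluation is chunked over points so
    whole-volume grids stay within memory.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    starts, ends = coil.segments()
    B = np.empty_like(pts)
    for lo in range(0, pts.shape[0], chunk):
        sl = slice(lo, lo + chunk)
        try:
            B[sl] = _segment_fields(starts, ends, coil.current_A, pts[sl], guard_m=guard_m)
        except SingularityError as err:
            raise SingularityError(str(err), guard_m=err.guard_m,
                                   point_index=lo + (err.point_index or 0)) from None
    return FieldGrid(points=pts, B=B)


def field_magnitude_volume(coil: CoilGeometry, like, coil_center_mm) -> np.ndarray:
    """|B| in mT at every voxel center of an image grid.

    ``like`` supplies the grid geometry (shape, spacing_mm, origin_mm);
    ``coil_center_mm`` is the coil-frame origin expressed in image
    coordinates, with the coil axis along the image +z axis.
    """
    shape = like.shape
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    centers_mm = np.asarray(like.origin_mm) + idx * np.asarray(like.spacing_mm)
    pts_m = (centers_mm - np.asarray(coil_center_mm, dtype=float)) / 1000.0
    grid = coil_field(coil, pts_m)
    return grid.magnitude_mT.reshape(shape)


def rect_center_field(half_width_a: float, half_height_b: float, current_A: float) -> float:
    """Analytic |B| (tesla) at the center of a flat rectangular loop.

    ``mu0 I sqrt(a^2 + b^2) / (pi a b)`` for half-sides a, b.
    """
    if half_width_a <= 0 or half_height_b <= 0:
        raise ValueError("half-sides must be positive")
    a, b = half_width_a, half_height_b
    return MU0 * current_A * np.hypot(a, b) / (np.pi * a * b)


def rect_axis_field(half_width_a: float, half_height_b: float, current_A: float,
                    z: float) -> float:
    """Analytic on-axis |B| (tesla) of a flat rectangular loop at height z.

    ``mu0 I a b / pi * [1/(a^2+z^2) + 1/(b^2+z^2)] / sqrt(a^2+b^2+z^2)``;
    reduces to :func:`rect_center_field` at z = 0 and decays as 1/z^3.
    """
    if half_width_a <= 0 or half_height_b <= 0:
        raise ValueError("half-sides must be positive")
    a, b = half_width_a, half_height_b
    return (MU0 * current_A * a * b / np.pi
            * (1.0 / (a * a + z * z) + 1.0 / (b * b + z * z))
            / np.sqrt(a * a + b * b + z * z))


@dataclass(frozen=True)
class PulseWaveform:
    """The device's pulsed drive: 75 +/- 2 Hz, 1.3 ms pulses, 1.8 +/- 0.2 mT peak."""

    frequency_Hz: float = 75.0
    pulse_width_s: float = 1.3e-3
    peak_mT: float = 1.8
    frequency_tol_Hz: float = 2.0
    peak_tol_mT: float = 0.2

    def __post_init__(self):
        if self.peak_mT <= 0:
            raise ValueError("peak must be positive")
        if not self.pulse_width_s < 1.0 / self.frequency_Hz:
            raise ValueError("pulse width must be shorter than the period")

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_Hz

    @property
    def duty_fraction(self) -> float:
        return self.pulse_width_s * self.frequency_Hz


def pulse_waveform(wave: PulseWaveform, t) -> np.ndarray:
    """Instantaneous amplitude (mT) of the rectangular pulse train at time t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return np.where(np.mod(t, wave.period_s) < wave.pulse_width_s, wave.peak_mT, 0.0)


@dataclass(frozen=True)
class TissueProperties:
    """Electric properties of the ischemic/edematous tissue, carried as
    metadata only: at 75 Hz the tissue does not perturb B, so the field
    computation never consumes them."""

    sigma_S_per_m: float = 1.7
    eps_r: str = "gray_matter"

    def __post_init__(self):
        if self.sigma_S_per_m < 0:
            raise ValueError("conductivity must be >= 0")
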