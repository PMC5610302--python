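"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: ellipsoid
membership is counted with explicit loops, region growing is re-derived
with a hand-rolled graph BFS, and segment fields are integrated with
adaptive quadrature of the raw Biot-Savart integrand.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest
from hypothesis import settings
from scipy.integrate import quad

from elfdose import ImageVolume, PhantomSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

MU0 = 4.0e-7 * np.pi


@pytest.fixture
def small_noiseless_spec():
    """A compact noiseless phantom whose lesion sits off-lattice."""
    return PhantomSpec(grid_shape=(48, 48, 24), spacing_mm=(1.0, 1.0, 1.0),
                       lesion_center_mm=(24.5, 24.5, 12.0),
                       lesion_semiaxes_mm=(8.0, 8.0, 5.0),
                       lesion_intensity=200.0, background_intensity=100.0,
                       noise_sd=0.0, rng_seed=0)


def make_volume(data, spacing=(1.0, 1.0, 1.0), modality="dwi"):
    """Wrap a 2D slice or 3D array as an ImageVolume."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return ImageVolume(arr, spacing, modality=modality)


def brute_force_ellipsoid_count(spec: PhantomSpec) -> int:
    """Voxel centers inside the ellipsoid, counted with explicit loops."""
    cx, cy, cz = spec.lesion_center_mm
    ax, ay, az = spec.lesion_semiaxes_mm
    sx, sy, sz = spec.spacing_mm
    count = 0
    for i in range(spec.grid_shape[0]):
        for j in range(spec.grid_shape[1]):
            for k in range(spec.grid_shape[2]):
                r = (((i * sx - cx) / ax) ** 2 + ((j * sy - cy) / ay) ** 2
                     + ((k * sz - cz) / az) ** 2)
                if r <= 1.0:
                    count += 1
    return count


def bfs_region_oracle(data: np.ndarray, seed, rel_threshold=0.20,
                      connectivity=8, mode="2d", band="symmetric",
                      traversal="bfs") -> np.ndarray:
    """Graph-reachability re-derivation of seeded region growing.

    Edges: 8- (or 4-) adjacency within each axial slice, plus, in
    ``2d_propagate`` mode, co-located (i, j) adjacency between neighboring
    slices; ``3d`` mode uses the full 26- (or 6-) neighborhood.  Both BFS
    and DFS frontiers are supported to probe traversal invariance.
    """
    seed = tuple(int(v) for v in seed)
    I0 = float(data[seed])
    tol = rel_threshold * I0
    if band == "symmetric":
        ok = np.abs(data - I0) <= tol
    else:
        ok = data >= I0 - tol
    if connectivity == 8:
        inplane = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        inplane = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    out = np.zeros(data.shape, dtype=bool)
    frontier = deque([seed])
    out[seed] = True
    pop = frontier.popleft if traversal == "bfs" else frontier.pop
    while frontier:
        i, j, k = pop()
        neighbors = [(i + di, j + dj, k) for di, dj in inplane]
        if mode in ("2d_propagate", "3d"):
            neighbors += [(i, j, k - 1), (i, j, k + 1)]
        if mode == "3d" and connectivity == 8:
            neighbors = [(i + di, j + dj, k + dk)
                         for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
                         if (di, dj, dk) != (0, 0, 0)]
        for n in neighbors:
            if all(0 <= c < s for c, s in zip(n, data.shape)) and ok[n] and not out[n]:
                out[n] = True
                frontier.append(n)
    return out


def quadrature_segment_field(p0, p1, current, point) -> np.ndarray:
    """Adaptive quadrature of the Biot-Savart integrand over one segment."""
    p0, p1, point = (np.asarray(v, dtype=float) for v in (p0, p1, point))
    d = p1 - p0

    def integrand(t, comp):
        r = point - (p0 + t * d)
        dB = np.cross(d, r) / np.linalg.norm(r) ** 3
        return dB[comp]

    return np.array([
        MU0 * current / (4 * np.pi) * quad(integrand, 0.0, 1.0, args=(c,),
                                           epsabs=1e-14, epsrel=1e-10)[0]
        for c in range(3)
    ])
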