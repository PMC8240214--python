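"""Shared fixtures and the brute-force oracle for surface-distance metrics.

The oracle deliberately re-derives everything from first principles with a
different code path than the package (index shifting instead of morphology,
an all-pairs distance matrix instead of a KD-tree, a hand-written linear-
interpolation quantile instead of ``np.percentile``), so agreement between
the two is a real check and not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from oarconcord import ImageGrid, StructureMask


# ---------------------------------------------------------------------------
# Mask construction helpers
# ---------------------------------------------------------------------------

def make_mask(
    occ: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    **labels,
) -> StructureMask:
    occ = np.asarray(occ, dtype=bool)
    grid = ImageGrid(shape=occ.shape, spacing=spacing, origin=origin)
    return StructureMask(grid, occ, **labels)


def box_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0)) -> StructureMask:
    """Axis-aligned filled box with voxel index corners lo (incl) .. hi (excl)."""
    occ = np.zeros(shape, dtype=bool)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return make_mask(occ, spacing=spacing)


def sphere_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)) -> StructureMask:
    """Digitized sphere: voxel centres within radius (in mm) of center (mm)."""
    idx = np.indices(shape, dtype=float)
    coords = [idx[d] * spacing[d] for d in range(3)]
    dist2 = sum((c - cc) ** 2 for c, cc in zip(coords, center))
    return make_mask(dist2 <= radius**2, spacing=spacing)


def random_blob_mask(rng: np.random.Generator, shape, spacing=(1.0, 1.0, 1.0)) -> StructureMask:
    """Random connected-ish blob: thresholded smoothed noise, never empty."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    occ = field > np.quantile(field, 0.8)
    if not occ.any():  # pragma: no cover - quantile guarantees nonempty
        occ[tuple(s // 2 for s in shape)] = True
    return make_mask(occ, spacing=spacing)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def oracle_surface_points(mask: StructureMask) -> np.ndarray:
    """Boundary-voxel centres (mm) by explicit 6-neighbour shifting."""
    occ = mask.occupancy
    padded = np.pad(occ, 1, constant_values=False)
    boundary = np.zeros_like(occ)
    for axis in range(3):
        for step in (-1, 1):
            neighbour = np.roll(padded, step, axis=axis)[1:-1, 1:-1, 1:-1]
            boundary |= occ & ~neighbour
    idx = np.argwhere(boundary).astype(float)
    return idx * np.asarray(mask.grid.spacing) + np.asarray(mask.grid.origin)


def oracle_directed(from_pts: np.ndarray, to_pts: np.ndarray) -> np.ndarray:
    """All-pairs nearest-point distances (O(n^2))."""
    if len(from_pts) == 0:
        return np.empty(0)
    return cdist(from_pts, to_pts).min(axis=1)


def oracle_pooled(a: StructureMask, b: StructureMask) -> np.ndarray:
    sa, sb = oracle_surface_points(a), oracle_surface_points(b)
    return np.concatenate([oracle_directed(sa, sb), oracle_directed(sb, sa)])


def oracle_quantile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile written out by hand."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 1:
        return float(v[0])
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def oracle_dice(a: StructureMask, b: StructureMask) -> float:
    na = int(a.occupancy.sum())
    nb = int(b.occupancy.sum())
    overlap = int((a.occupancy & b.occupancy).sum())
    return 2.0 * overlap / (na + nb)


def oracle_msd(a: StructureMask, b: StructureMask) -> float:
    pooled = oracle_pooled(a, b)
    return float(pooled.sum() / len(pooled))


def oracle_hd95(a: StructureMask, b: StructureMask) -> float:
    return oracle_quantile(oracle_pooled(a, b), 0.95)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210628)
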