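"""Pairwise 3D contour-agreement metrics: DSC, MSD, HD95 and volume.

The three statistics used to compare an observer's delineation against a
reference contour on a shared voxel grid:

* **DSC** (Dice similarity coefficient): volume-overlap ratio
  ``2|A∩B| / (|A|+|B|)`` on voxel counts; 1 for perfect overlap, 0 for
  disjoint structures.  Note DSC is biased with regard to volume — larger
  structures score higher for the same absolute boundary error — which is
  exactly why the two distance metrics are reported alongside it (and is a
  tested property of this module).
* **MSD** (mean surface distance, mm): mean over the pooled symmetric
  multiset of nearest-surface distances {d(p, ∂B): p ∈ ∂A} ∪ {d(q, ∂A): q ∈ ∂B}.
* **HD95** (95 % Hausdorff distance, mm): 95th percentile (linear
  interpolation between order statistics) of the same pooled multiset — a
  robust variant of the maximum Hausdorff distance.

The surface of a mask is the set of centres of its 6-connectivity boundary
voxels: occupied voxels with at least one face-adjacent unoccupied neighbour,
where the volume edge counts as outside (a structure cropped by the scan,
e.g. a spinal cord reaching the most caudal slice, still has a closed
surface).  Distances are Euclidean in mm, so anisotropic spacing is handled
exactly.  Correctness of the fast KD-tree path is defined by (and tested
against) a brute-force all-pairs nearest-point computation.

Empty or absent structures never get imputed "penalty" distances; they are
flagged via :class:`AgreementResult.status` and excluded from distance
statistics downstream, mirroring how delineation counts are reported
separately from agreement values.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid_io import StructureMask, assert_same_grid

__all__ = [
    "EmptyMaskError",
    "Status",
    "SurfacePointSet",
    "AgreementResult",
    "dice",
    "extract_surface",
    "directed_distances",
    "pooled_surface_distances",
    "msd",
    "msd_directed",
    "hd95",
    "volume_cc",
    "compare",
]

#: 6-connectivity structuring element (face neighbours only).
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


class EmptyMaskError(ValueError):
    """A metric was requested for an empty mask where it is undefined."""


class Status(str, Enum):
    """Outcome category for one (reference, test) comparison."""

    OK = "OK"
    TEST_EMPTY = "TEST_EMPTY"
    REF_EMPTY = "REF_EMPTY"
    BOTH_EMPTY = "BOTH_EMPTY"
    NOT_DELINEATED = "NOT_DELINEATED"


@dataclass(frozen=True)
class SurfacePointSet:
    """World-coordinate (mm) centres of a mask's boundary voxels."""

    points: np.ndarray  # (n, 3) float64, mm

    @property
    def count(self) -> int:
        return int(self.points.shape[0])

    @property
    def is_empty(self) -> bool:
        return self.count == 0


@dataclass(frozen=True)
class AgreementResult:
    """DSC, MSD, HD95 and volumes for one (reference, test) pair.

    Undefined metrics are NaN.  Invariants: status ``OK`` implies all three
    metrics are defined; ``TEST_EMPTY``/``REF_EMPTY`` imply ``dsc == 0`` with
    distances undefined; ``BOTH_EMPTY``/``NOT_DELINEATED`` imply everything
    undefined.
    """

    dsc: float
    msd_mm: float
    hd95_mm: float
    volume_ref_cc: float
    volume_test_cc: float
    status: Status

    @property
    def ok(self) -> bool:
        return self.status is Status.OK

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "msd_mm": self.msd_mm,
            "hd95_mm": self.hd95_mm,
            "volume_ref_cc": self.volume_ref_cc,
            "volume_test_cc": self.volume_test_cc,
            "status": self.status.value,
        }


# ---------------------------------------------------------------------------
# Elementary metrics
# ---------------------------------------------------------------------------

def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)`` on voxel counts.

    Symmetric in its arguments and in [0, 1].  Undefined (raises
    :class:`EmptyMaskError`) when both masks are empty.
    """
    assert_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise EmptyMaskError("DSC is undefined when both masks are empty")
    overlap = int(np.count_nonzero(a.occupancy & b.occupancy))
    return 2.0 * overlap / (na + nb)


def extract_surface(mask: StructureMask) -> SurfacePointSet:
    """Boundary-voxel centres (mm) under 6-connectivity.

    A voxel is boundary iff occupied and at least one of its six face
    neighbours is unoccupied or outside the volume (``border_value=0`` makes
    the volume edge count as background).  An empty mask yields an empty set.
    """
    occ = mask.occupancy
    if not occ.any():
        return SurfacePointSet(points=np.empty((0, 3), dtype=np.float64))
    interior = ndimage.binary_erosion(occ, structure=_FACE_STRUCT, border_value=0)
    boundary = occ & ~interior
    idx = np.argwhere(boundary).astype(np.float64)
    spacing = np.asarray(mask.grid.spacing, dtype=np.float64)
    origin = np.asarray(mask.grid.origin, dtype=np.float64)
    return SurfacePointSet(points=idx * spacing + origin)


def directed_distances(from_set: SurfacePointSet, to_set: SurfacePointSet) -> np.ndarray:
    """Euclidean mm distance from each point of ``from_set`` to its nearest
    point in ``to_set``; result has length ``from_set.count``.

    Uses a KD-tree; results equal the brute-force all-pairs minimum exactly.
    """
    if to_set.is_empty:
        raise EmptyMaskError("directed distances are undefined against an empty surface")
    if from_set.is_empty:
        return np.empty(0, dtype=np.float64)
    tree = cKDTree(to_set.points)
    dists, _ = tree.query(from_set.points, k=1)
    return np.asarray(dists, dtype=np.float64)


def pooled_surface_distances(a: StructureMask, b: StructureMask) -> np.ndarray:
    """The symmetric pooled multiset {d(p, ∂B): p∈∂A} ∪ {d(q, ∂A): q∈∂B}."""
    assert_same_grid(a, b)
    if a.is_empty or b.is_empty:
        raise EmptyMaskError("surface distances are undefined for an empty mask")
    sa, sb = extract_surface(a), extract_surface(b)
    return np.concatenate([directed_distances(sa, sb), directed_distances(sb, sa)])


def msd(a: StructureMask, b: StructureMask) -> float:
    """Mean surface distance (mm): mean of the pooled symmetric multiset.

    Symmetric in its arguments; 0 iff the two surfaces coincide.
    """
    return float(pooled_surface_distances(a, b).mean())


def msd_directed(a: StructureMask, b: StructureMask) -> tuple[float, float]:
    """Both one-directional mean surface distances (a→b, b→a) in mm.

    Exposed for sensitivity analysis; the headline ``msd`` is the pooled
    symmetric mean of the same distances.
    """
    assert_same_grid(a, b)
    if a.is_empty or b.is_empty:
        raise EmptyMaskError("surface distances are undefined for an empty mask")
    sa, sb = extract_surface(a), extract_surface(b)
    return (
        float(directed_distances(sa, sb).mean()),
        float(directed_distances(sb, sa).mean()),
    )


def hd95(a: StructureMask, b: StructureMask, percentile: float = 95.0) -> float:
    """95th percentile (linear interpolation) of the pooled symmetric
    surface-distance multiset, in mm.

    Bounded above by the exact (maximum) Hausdorff distance of the pair.
    """
    return float(np.percentile(pooled_surface_distances(a, b), percentile))


def volume_cc(mask: StructureMask) -> float:
    """Structure volume in cc: occupied-voxel count × voxel volume / 1000."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# Pair comparison with empty/absent semantics
# ---------------------------------------------------------------------------

def compare(
    reference: StructureMask | None,
    test: StructureMask | None,
    *,
    percentile: float = 95.0,
) -> AgreementResult:
    """Full agreement result for one (reference, test) pair.

    ``test=None`` means the observer did not delineate the structure
    (``NOT_DELINEATED``); an all-zero test mask means they delineated it
    empty (``TEST_EMPTY``, DSC 0, distances undefined).  The reference must
    be present.
    """
    if reference is None:
        raise ValueError("a reference mask is required for comparison")
    vol_ref = volume_cc(reference)
    nan = float("nan")

    if test is None:
        return AgreementResult(nan, nan, nan, vol_ref, nan, Status.NOT_DELINEATED)

    assert_same_grid(reference, test)
    vol_test = volume_cc(test)
    ref_empty, test_empty = reference.is_empty, test.is_empty
    if ref_empty and test_empty:
        return AgreementResult(nan, nan, nan, vol_ref, vol_test, Status.BOTH_EMPTY)
    if test_empty:
        return AgreementResult(0.0, nan, nan, vol_ref, vol_test, Status.TEST_EMPTY)
    if ref_empty:
        return AgreementResult(0.0, nan, nan, vol_ref, vol_test, Status.REF_EMPTY)

    pooled = pooled_surface_distances(reference, test)
    return AgreementResult(
        dsc=dice(reference, test),
        msd_mm=float(pooled.mean()),
        hd95_mm=float(np.percentile(pooled, percentile)),
        volume_ref_cc=vol_ref,
        volume_test_cc=vol_test,
        status=Status.OK,
    )
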