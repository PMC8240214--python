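"""Voxel-grid data model and I/O for structure masks and cohort manifests.

All agreement metrics in this package are computed in millimetres on a shared,
axis-aligned voxel grid (one planning-CT frame per patient).  This module owns
that frame: :class:`ImageGrid` (shape, anisotropic spacing, world origin),
:class:`StructureMask` (binary occupancy labelled with organ / patient /
observer / group), and the cohort manifest that maps those labels to NIfTI
files on disk.

Masks are stored one structure per NIfTI-1 file with values {0, 1}.  Oblique
(non-axis-aligned) orientations are rejected rather than resampled: every
comparison in the pipeline happens on one grid, and silently resampling would
corrupt the millimetre geometry the distance metrics depend on.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np

__all__ = [
    "GROUPS",
    "GridMismatchError",
    "UnsupportedOrientationError",
    "ManifestError",
    "ImageGrid",
    "StructureMask",
    "ManifestEntry",
    "CohortManifest",
    "CohortBundle",
    "read_mask",
    "write_mask",
    "assert_same_grid",
    "load_cohort",
]

#: Valid observer-group labels.  ICG marks observers following the 2015
#: international consensus guidelines; OTHER marks observers using no or
#: different guidelines; REFERENCE marks the guideline-conformant reference
#: contour each observer is compared against.
GROUPS = ("ICG", "OTHER", "REFERENCE")

SPACING_ATOL_MM = 1e-6


class GridMismatchError(ValueError):
    """Two masks do not share a voxel grid; no resampling is ever attempted."""


class UnsupportedOrientationError(ValueError):
    """Volume orientation is oblique (not axis-aligned up to permutation/sign)."""


class ManifestError(ValueError):
    """Cohort manifest violates its schema or invariants."""


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned voxel lattice shared by all masks of one patient.

    Parameters
    ----------
    shape
        Number of voxels along each axis ``(nx, ny, nz)``; all entries >= 1.
    spacing
        Voxel edge lengths in mm ``(sx, sy, sz)``; all entries > 0.  The third
        axis is the cranio-caudal (axial-slice) direction by convention.
    origin
        World coordinate (mm) of the centre of voxel ``(0, 0, 0)``.

    The world coordinate of voxel index ``(i, j, k)`` is
    ``origin + (i*sx, j*sy, k*sz)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(float(s) <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_geometry(self, other: "ImageGrid", atol: float = SPACING_ATOL_MM) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= atol for a, b in zip(self.spacing, other.spacing)
        )

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal spacing, translation = origin)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class StructureMask:
    """Binary occupancy of one structure on an :class:`ImageGrid`.

    An all-zero occupancy is legal and means "delineated but empty"; a missing
    record (``None`` elsewhere in the pipeline) means "not delineated".
    """

    grid: ImageGrid
    occupancy: np.ndarray
    organ: str = ""
    patient: str = ""
    observer: str = ""
    group: str = "REFERENCE"

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != tuple(self.grid.shape):
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid shape {self.grid.shape}"
            )
        if occ.dtype != bool:
            vals = np.unique(occ)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("occupancy must be strictly binary")
            occ = occ.astype(bool)
        self.occupancy = occ
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def with_labels(self, **labels: str) -> "StructureMask":
        """Copy sharing the occupancy array but with replaced label fields."""
        kwargs = dict(
            organ=self.organ, patient=self.patient, observer=self.observer, group=self.group
        )
        kwargs.update(labels)
        return StructureMask(self.grid, self.occupancy, **kwargs)


# ---------------------------------------------------------------------------
# NIfTI mask I/O
# ---------------------------------------------------------------------------

def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> ImageGrid:
    """Build an ImageGrid from a NIfTI affine, rejecting oblique orientations.

    The 3x3 rotation-scale block must have exactly one non-negligible entry per
    row and per column (axis-aligned up to permutation and sign).  The grid is
    expressed in the array's own index order, so spacing[i] is the world step
    along array axis i regardless of which world axis that is.
    """
    rot = np.asarray(affine, dtype=float)[:3, :3]
    col_norms = np.linalg.norm(rot, axis=0)
    if np.any(col_norms <= 0):
        raise UnsupportedOrientationError("affine has a zero-length axis")
    # an axis-aligned column has all its mass in a single row
    dominant = np.abs(rot).max(axis=0)
    residual = np.sqrt(np.maximum(col_norms**2 - dominant**2, 0.0))
    if np.any(residual > 1e-4 * col_norms):
        raise UnsupportedOrientationError(
            "volume orientation is oblique (direction cosines are not axis-aligned); "
            "resample the volume explicitly before loading"
        )
    rows = np.abs(rot).argmax(axis=0)
    if len(set(rows.tolist())) != 3:
        raise UnsupportedOrientationError("affine axes are degenerate")
    spacing = tuple(float(s) for s in col_norms)
    origin = tuple(float(o) for o in np.asarray(affine, dtype=float)[:3, 3])
    return ImageGrid(shape=tuple(int(n) for n in shape), spacing=spacing, origin=origin)


def read_mask(
    path: str | Path,
    *,
    organ: str = "",
    patient: str = "",
    observer: str = "",
    group: str = "REFERENCE",
    threshold: float = 0.5,
) -> StructureMask:
    """Read a binary structure mask from a NIfTI-1 volume.

    Voxels with value strictly greater than ``threshold`` (default 0.5, tolerant
    of interpolated or lossily compressed files) are occupied.  The grid is
    populated from the header; oblique orientations raise
    :class:`UnsupportedOrientationError` and 4-D volumes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D with shape {data.shape}: {path}")
    grid = _grid_from_affine(img.affine, data.shape)
    occupancy = data > threshold
    return StructureMask(
        grid, occupancy, organ=organ, patient=patient, observer=observer, group=group
    )


def write_mask(mask: StructureMask, path: str | Path) -> None:
    """Write a mask as a NIfTI-1 volume with values {0, 1} (uint8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), mask.grid.affine())
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def assert_same_grid(a: StructureMask, b: StructureMask) -> None:
    """Raise :class:`GridMismatchError` unless both masks share one voxel grid.

    Shapes must be equal and spacings equal within 1e-6 mm.  This is the single
    gate every cross-mask metric goes through; nothing is ever resampled.
    """
    if not a.grid.same_geometry(b.grid):
        raise GridMismatchError(
            "masks are on different grids: "
            f"shape {a.grid.shape} spacing {a.grid.spacing} vs "
            f"shape {b.grid.shape} spacing {b.grid.spacing}"
        )


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    patient: str
    observer: str
    organ: str
    group: str
    path: str

    @property
    def is_reference(self) -> bool:
        return self.group == "REFERENCE"


@dataclass
class CohortManifest:
    """Mapping from (patient, observer, organ, group) to mask files.

    Invariants: at most one entry per (patient, observer, organ), and every
    (patient, organ) that has any observer entry has exactly one REFERENCE
    entry.  Paths are forward-slash, relative to ``root``.
    """

    entries: list[ManifestEntry]
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        seen: set[tuple[str, str, str]] = set()
        for e in self.entries:
            if e.group not in GROUPS:
                raise ManifestError(f"invalid group {e.group!r} for {e.patient}/{e.observer}/{e.organ}")
            key = (e.patient, e.observer, e.organ)
            if key in seen:
                raise ManifestError(f"duplicate manifest entry for {key}")
            seen.add(key)
        ref_counts: dict[tuple[str, str], int] = {}
        observed: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.patient, e.organ)
            if e.is_reference:
                ref_counts[key] = ref_counts.get(key, 0) + 1
            else:
                observed.add(key)
        for key in observed:
            n_ref = ref_counts.get(key, 0)
            if n_ref != 1:
                raise ManifestError(
                    f"(patient, organ) {key} has {n_ref} reference entries; exactly 1 required"
                )

    @property
    def observers(self) -> list[str]:
        """Sorted roster of non-reference observers appearing anywhere."""
        return sorted({e.observer for e in self.entries if not e.is_reference})

    @property
    def observer_groups(self) -> dict[str, str]:
        groups: dict[str, str] = {}
        for e in self.entries:
            if not e.is_reference:
                prev = groups.setdefault(e.observer, e.group)
                if prev != e.group:
                    raise ManifestError(
                        f"observer {e.observer!r} appears with groups {prev} and {e.group}"
                    )
        return groups

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if not isinstance(doc, dict) or "entries" not in doc:
            raise ManifestError(f"manifest {path} must be a JSON object with an 'entries' list")
        entries = [
            ManifestEntry(
                patient=str(e["patient"]),
                observer=str(e["observer"]),
                organ=str(e["organ"]),
                group=str(e["group"]),
                path=str(e["path"]),
            )
            for e in doc["entries"]
        ]
        return cls(entries=entries, root=path.parent)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        """Flat-CSV alternate: columns patient, observer, organ, group, path."""
        path = Path(path)
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"patient", "observer", "organ", "group", "path"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ManifestError(f"manifest CSV must have columns {sorted(required)}")
            entries = [
                ManifestEntry(
                    patient=row["patient"],
                    observer=row["observer"],
                    organ=row["organ"],
                    group=row["group"],
                    path=row["path"],
                )
                for row in reader
            ]
        return cls(entries=entries, root=path.parent)

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        if path.suffix.lower() == ".csv":
            return cls.from_csv(path)
        return cls.from_json(path)

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        doc = {
            "schema": "oarconcord-manifest-v1",
            "entries": [
                {
                    "patient": e.patient,
                    "observer": e.observer,
                    "organ": e.organ,
                    "group": e.group,
                    "path": e.path,
                }
                for e in self.entries
            ],
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class CohortBundle:
    """Reference plus per-observer masks for one (patient, organ).

    ``observations[obs]`` is ``None`` when the observer delineated nothing for
    this organ ("not delineated"), as opposed to an all-zero mask ("delineated
    but empty").
    """

    patient: str
    organ: str
    reference: StructureMask
    observations: dict[str, StructureMask | None]
    groups: dict[str, str]


def load_cohort(
    manifest: CohortManifest,
    *,
    observers: Iterable[str] | None = None,
) -> dict[tuple[str, str], CohortBundle]:
    """Load all masks of a manifest, grouped by (patient, organ).

    Every (patient, organ) bundle lists the full observer roster; observers
    with no manifest entry for that organ are recorded as not delineated
    (``None``).  The roster defaults to all observers appearing anywhere in
    the manifest.
    """
    roster = sorted(observers) if observers is not None else manifest.observers
    groups = manifest.observer_groups
    by_key: dict[tuple[str, str], dict[str, ManifestEntry]] = {}
    refs: dict[tuple[str, str], ManifestEntry] = {}
    for e in manifest.entries:
        key = (e.patient, e.organ)
        if e.is_reference:
            refs[key] = e
        else:
            by_key.setdefault(key, {})[e.observer] = e

    bundles: dict[tuple[str, str], CohortBundle] = {}
    for key in sorted(by_key):
        patient, organ = key
        if key not in refs:
            raise ManifestError(f"no reference entry for (patient, organ) {key}")
        ref_entry = refs[key]
        reference = read_mask(
            manifest.root / ref_entry.path,
            organ=organ, patient=patient, observer=ref_entry.observer, group="REFERENCE",
        )
        observations: dict[str, StructureMask | None] = {}
        for obs in roster:
            entry = by_key[key].get(obs)
            if entry is None:
                observations[obs] = None
            else:
                mask = read_mask(
                    manifest.root / entry.path,
                    organ=organ, patient=patient, observer=obs, group=entry.group,
                )
                assert_same_grid(reference, mask)
                observations[obs] = mask
        bundles[key] = CohortBundle(
            patient=patient, organ=organ, reference=reference,
            observations=observations, groups=dict(groups),
        )
    return bundles
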