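"""Synthetic multi-observer contour cohorts for head-and-neck organs at risk.

No real contour submissions are available for this kind of interobserver
study, so the pipeline is exercised end-to-end on synthetic data with a known
ground truth.  The generator has three layers:

1. **Phantoms** — parametric voxelized stand-ins for ten head-and-neck organs
   at risk (ellipsoids for glands and cochlea, a tapered cylinder for the
   brainstem, a thin caudally-cropped cylinder for the spinal cord, an arch
   for the mandible, lumen-carved slabs for oral cavity and larynx, a thin
   curved shell for the pharyngeal constrictors).

2. **Observer-error model** — each simulated observer perturbs the reference
   with a fixed-order composition of the error modes seen in real delineation
   audits: omission, wrong-location gross errors, surrogate-structure
   substitution (e.g. spinal canal delineated instead of cord), systematic
   shifts, cranio-caudal extent errors in whole axial slices, inclusion of an
   adjacent substructure (e.g. teeth with the mandible), and smooth boundary
   jitter realized as a correlated random perturbation of the signed distance
   field.

3. **Cohort layout** — two observer groups with different error magnitudes
   and per-organ delineation probabilities, emulating clinicians who do or
   do not follow international consensus guidelines (ICG): the ICG group
   delineates guideline organs more often and with lower boundary jitter.

Everything is a pure function of (specs, profiles, seed): random streams are
split deterministically per (patient, observer, organ), so adding an observer
never perturbs another observer's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grid_io import (
    CohortManifest,
    ImageGrid,
    ManifestEntry,
    StructureMask,
    write_mask,
)

__all__ = [
    "Organ",
    "ShapeFamily",
    "ErrorMode",
    "PhantomSpec",
    "ErrorModeConfig",
    "ObserverProfile",
    "CohortDataset",
    "make_phantom",
    "signed_distance_mm",
    "perturb",
    "simulate_observer",
    "simulate_cohort",
    "export_cohort",
    "default_grid",
    "default_specs",
    "default_profiles",
    "DEFAULT_ORGANS",
]


class Organ(str, Enum):
    BRAINSTEM = "BRAINSTEM"
    COCHLEA = "COCHLEA"
    GLOTTIC_AREA = "GLOTTIC_AREA"
    MANDIBLE = "MANDIBLE"
    ORAL_CAVITY = "ORAL_CAVITY"
    PAROTID = "PAROTID"
    PCM = "PCM"
    SPINAL_CORD = "SPINAL_CORD"
    SMG = "SMG"
    SUPRAGLOTTIC_LARYNX = "SUPRAGLOTTIC_LARYNX"


class ShapeFamily(str, Enum):
    ELLIPSOID = "ELLIPSOID"
    TAPERED_CYLINDER = "TAPERED_CYLINDER"
    THIN_CYLINDER = "THIN_CYLINDER"
    ARCH = "ARCH"
    SLAB_STACK = "SLAB_STACK"
    CURVED_SHELL = "CURVED_SHELL"


class ErrorMode(str, Enum):
    BOUNDARY_JITTER = "BOUNDARY_JITTER"
    EXTENT_CRANIAL = "EXTENT_CRANIAL"
    EXTENT_CAUDAL = "EXTENT_CAUDAL"
    SYSTEMATIC_SHIFT = "SYSTEMATIC_SHIFT"
    SUBSTRUCTURE_INCLUSION = "SUBSTRUCTURE_INCLUSION"
    WRONG_LOCATION = "WRONG_LOCATION"
    SURROGATE_STRUCTURE = "SURROGATE_STRUCTURE"
    OMISSION = "OMISSION"


#: Fixed application order of error modes inside :func:`perturb`.
_MODE_ORDER = (
    ErrorMode.OMISSION,
    ErrorMode.WRONG_LOCATION,
    ErrorMode.SURROGATE_STRUCTURE,
    ErrorMode.SYSTEMATIC_SHIFT,
    ErrorMode.EXTENT_CRANIAL,
    ErrorMode.EXTENT_CAUDAL,
    ErrorMode.SUBSTRUCTURE_INCLUSION,
    ErrorMode.BOUNDARY_JITTER,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one organ phantom.

    ``size_mm`` is interpreted per shape family:

    - ELLIPSOID: semi-axes (a, b, c)
    - TAPERED_CYLINDER: (cranial radius, caudal radius, half-height)
    - THIN_CYLINDER: (radius, unused, height above the caudal grid edge)
    - ARCH: (centreline radius R, tube radius r, unused); a half-torus open
      posteriorly, the mandible stand-in
    - SLAB_STACK: (a, b, c) outer semi-axes with a central cylindrical lumen
      of radius ``lumen_mm`` carved out (oral cavity / larynx stand-ins)
    - CURVED_SHELL: (inner radius, outer radius, half-height); a posterior
      half-shell, the pharyngeal-constrictor stand-in
    """

    organ: Organ
    family: ShapeFamily
    size_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float]
    lumen_mm: float = 0.0
    edge_cropped: bool = False  # caudally cropped by the scan (spinal cord)

    def scaled(self, factor: float) -> "PhantomSpec":
        return replace(self, size_mm=tuple(s * factor for s in self.size_mm))


@dataclass(frozen=True)
class ErrorModeConfig:
    """One error mode with its magnitude, occurrence probability and sense.

    ``magnitude`` is in mm for all modes except the EXTENT modes, where it is
    a number of whole axial slices.  ``grow`` selects extension vs truncation
    for the EXTENT modes (delineating too far vs stopping short) and is
    ignored elsewhere.
    """

    mode: ErrorMode
    magnitude: float = 0.0
    probability: float = 0.0
    grow: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must be in [0,1], got {self.probability}")
        if self.magnitude < 0:
            raise ValueError(f"magnitude must be >= 0, got {self.magnitude}")


@dataclass(frozen=True)
class ObserverProfile:
    """Generative description of one simulated observer.

    ``delineation_prob`` maps each organ to the probability that this observer
    delineates it at all; ``error_modes`` maps organs to their gross-error
    configurations.  ``jitter_scale_mm`` is the standard deviation of the
    smooth boundary-jitter field and ``jitter_corr_mm`` its spatial
    correlation length; jitter applies to every delineated organ.
    """

    observer: str
    group: str  # "ICG" or "OTHER"
    delineation_prob: Mapping[Organ, float]
    error_modes: Mapping[Organ, tuple[ErrorModeConfig, ...]] = field(default_factory=dict)
    jitter_scale_mm: float = 1.0
    jitter_corr_mm: float = 10.0

    def prob_for(self, organ: Organ) -> float:
        if organ not in self.delineation_prob:
            raise KeyError(f"profile {self.observer} has no delineation probability for {organ}")
        return float(self.delineation_prob[organ])


@dataclass
class CohortDataset:
    """In-memory synthetic cohort, fully reproducible from (specs, profiles, seed)."""

    patients: list[str]
    grid: ImageGrid
    specs: list[PhantomSpec]
    profiles: list[ObserverProfile]
    seed: int
    references: dict[tuple[str, str], StructureMask]  # (patient, organ) -> mask
    observations: dict[tuple[str, str, str], StructureMask | None]  # (patient, observer, organ)

    @property
    def organs(self) -> list[str]:
        return [spec.organ.value for spec in self.specs]

    @property
    def observers(self) -> list[str]:
        return [p.observer for p in self.profiles]

    def groups(self) -> dict[str, str]:
        return {p.observer: p.group for p in self.profiles}


# ---------------------------------------------------------------------------
# Phantom synthesis
# ---------------------------------------------------------------------------

def _world_coords(grid: ImageGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    spacing = grid.spacing
    origin = grid.origin
    axes = [
        (np.arange(n, dtype=np.float64) * s + o)
        for n, s, o in zip(grid.shape, spacing, origin)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def make_phantom(
    spec: PhantomSpec,
    grid: ImageGrid,
    rng: np.random.Generator | None = None,
    *,
    size_scale: float = 1.0,
) -> StructureMask:
    """Voxelize a parametric organ phantom on ``grid``.

    Deterministic: the mask is a pure function of (spec, grid, size_scale);
    ``rng`` is accepted for interface uniformity with the perturbation
    operations but the base shapes draw nothing from it.  ``size_scale``
    carries the per-patient anatomy variation drawn by the cohort simulator.
    """
    spec = spec.scaled(size_scale)
    x, y, z = _world_coords(grid)
    cx, cy, cz = spec.center_mm
    a, b, c = spec.size_mm
    fam = spec.family

    if fam is ShapeFamily.ELLIPSOID:
        occ = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    elif fam is ShapeFamily.TAPERED_CYLINDER:
        # radius varies linearly from caudal radius b (z = cz - c) to cranial a (z = cz + c)
        t = np.clip((z - (cz - c)) / (2.0 * c), 0.0, 1.0)
        radius = b + (a - b) * t
        occ = (((x - cx) ** 2 + (y - cy) ** 2) <= radius**2) & (np.abs(z - cz) <= c)
    elif fam is ShapeFamily.THIN_CYLINDER:
        z0 = grid.origin[2]  # caudal grid edge: the scan crops the structure
        occ = (((x - cx) ** 2 + (y - cy) ** 2) <= a**2) & (z >= z0 - 1e-9) & (z <= z0 + c)
    elif fam is ShapeFamily.ARCH:
        rho = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        tube = np.sqrt((rho - a) ** 2 + (z - cz) ** 2)
        occ = (tube <= b) & (y <= cy)  # open posteriorly
    elif fam is ShapeFamily.SLAB_STACK:
        outer = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
        occ = outer
        if spec.lumen_mm > 0:
            lumen = ((x - cx) ** 2 + (y - cy) ** 2) <= spec.lumen_mm**2
            occ = outer & ~(lumen & (np.abs(z - cz) <= c))
    elif fam is ShapeFamily.CURVED_SHELL:
        rho2 = (x - cx) ** 2 + (y - cy) ** 2
        occ = (rho2 >= a**2) & (rho2 <= b**2) & (np.abs(z - cz) <= c) & (y >= cy)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown shape family {fam}")

    occ = np.broadcast_to(occ, grid.shape).copy()
    if not spec.edge_cropped and not occ.any():
        raise ValueError(f"phantom spec {spec.organ.value} produced an empty mask on this grid")
    return StructureMask(
        grid, occ, organ=spec.organ.value, group="REFERENCE", observer="REFERENCE"
    )


# ---------------------------------------------------------------------------
# Observer-error model
# ---------------------------------------------------------------------------

def signed_distance_mm(mask: StructureMask) -> np.ndarray:
    """Signed Euclidean distance to the structure surface, in mm.

    Negative inside, positive outside.  Voxel-centre distance transforms put
    the zero level between the innermost outside voxels and the outermost
    inside voxels; both branches are therefore shifted toward the surface by
    half the smallest voxel step, so a perturbation of amplitude ``a`` mm
    moves the thresholded boundary by ≈ ``a`` mm even when ``a`` is below the
    voxel size.  (On anisotropic grids the half-step is taken from the finest
    axis; the residual sub-voxel bias along coarser axes is accepted.)
    """
    occ = mask.occupancy
    spacing = mask.grid.spacing
    half_step = 0.5 * min(spacing)
    outside = ndimage.distance_transform_edt(~occ, sampling=spacing)
    inside = ndimage.distance_transform_edt(occ, sampling=spacing)
    sdf = np.where(occ, -(inside - half_step), outside - half_step)
    return np.asarray(sdf, dtype=np.float64)


def _correlated_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth zero-mean unit-variance random field with the given correlation
    length, built by Gaussian smoothing of white noise (recorded synthesis
    convention: sigma = corr_mm / spacing per axis, then renormalized)."""
    noise = rng.standard_normal(shape)
    sigma = [max(corr_mm / s, 0.0) for s in spacing]
    if any(s > 0 for s in sigma):
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    std = noise.std()
    if std > 0:
        noise = (noise - noise.mean()) / std
    return noise


def _ball_mask(grid: ImageGrid, center_mm: Sequence[float], radius_mm: float) -> np.ndarray:
    x, y, z = _world_coords(grid)
    cx, cy, cz = center_mm
    occ = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm**2
    return np.broadcast_to(occ, grid.shape).copy()


def _centroid_mm(mask: StructureMask) -> np.ndarray:
    idx = np.argwhere(mask.occupancy).astype(np.float64)
    centroid_idx = idx.mean(axis=0)
    return centroid_idx * np.asarray(mask.grid.spacing) + np.asarray(mask.grid.origin)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def _integer_shift(occ: np.ndarray, offset: Sequence[int]) -> np.ndarray:
    """Translate a binary volume by whole voxels, zero-filling (no wrap)."""
    out = np.zeros_like(occ)
    src = []
    dst = []
    for n, off in zip(occ.shape, offset):
        off = int(off)
        if off >= n or off <= -n:
            return out
        if off >= 0:
            src.append(slice(0, n - off))
            dst.append(slice(off, n))
        else:
            src.append(slice(-off, n))
            dst.append(slice(0, n + off))
    out[tuple(dst)] = occ[tuple(src)]
    return out


def _extent_error(occ: np.ndarray, n_slices: int, *, cranial: bool, grow: bool) -> np.ndarray:
    """Add or remove whole axial slices at one cranio-caudal end.

    Growth replicates the current end slice outward (the contour is carried
    too far); truncation zeroes the end slices (the contour stops short).
    Axis 2 is cranio-caudal with increasing index toward cranial.
    """
    n_slices = int(n_slices)
    if n_slices <= 0 or not occ.any():
        return occ.copy()
    out = occ.copy()
    zs = np.flatnonzero(occ.any(axis=(0, 1)))
    nz = occ.shape[2]
    if cranial:
        end = zs[-1]
        if grow:
            template = occ[:, :, end]
            for k in range(1, n_slices + 1):
                if end + k >= nz:
                    break
                out[:, :, end + k] = template
        else:
            lo = max(end - n_slices + 1, 0)
            out[:, :, lo : end + 1] = False
    else:
        start = zs[0]
        if grow:
            template = occ[:, :, start]
            for k in range(1, n_slices + 1):
                if start - k < 0:
                    break
                out[:, :, start - k] = template
        else:
            hi = min(start + n_slices, nz)
            out[:, :, start:hi] = False
    return out


def perturb(
    reference: StructureMask,
    configs: Sequence[ErrorModeConfig],
    jitter_scale_mm: float,
    jitter_corr_mm: float,
    rng: np.random.Generator,
) -> StructureMask | None:
    """Apply an observer's error model to a reference contour.

    Modes fire independently with their configured probabilities, in the
    fixed order OMISSION → WRONG_LOCATION → SURROGATE_STRUCTURE →
    SYSTEMATIC_SHIFT → EXTENT (cranial, caudal) → SUBSTRUCTURE_INCLUSION →
    BOUNDARY_JITTER.  Returns ``None`` for omission; otherwise a mask on the
    same grid (which may legitimately be empty if the perturbation erased a
    tiny structure).  With all probabilities zero and zero jitter the output
    equals the reference.
    """
    grid = reference.grid
    by_mode: dict[ErrorMode, list[ErrorModeConfig]] = {}
    for cfg in configs:
        by_mode.setdefault(cfg.mode, []).append(cfg)

    def _active(mode: ErrorMode) -> list[ErrorModeConfig]:
        return [c for c in by_mode.get(mode, []) if c.probability > 0 and rng.random() < c.probability]

    occ = reference.occupancy.copy()

    for _ in _active(ErrorMode.OMISSION):
        return None

    if occ.any():
        for cfg in _active(ErrorMode.WRONG_LOCATION):
            volume_mm3 = float(occ.sum()) * grid.voxel_volume_mm3
            radius = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
            direction = _random_unit_vector(rng)
            center = _centroid_mm(reference) + direction * cfg.magnitude
            extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
            center = np.clip(center, np.asarray(grid.origin) + radius,
                             np.asarray(grid.origin) + extent - radius)
            occ = _ball_mask(grid, center, radius)

        for cfg in _active(ErrorMode.SURROGATE_STRUCTURE):
            # uniform dilation in mm (models delineating the enclosing
            # structure, e.g. spinal canal instead of cord)
            sdf = signed_distance_mm(StructureMask(grid, occ))
            occ = sdf <= cfg.magnitude

        for cfg in _active(ErrorMode.SYSTEMATIC_SHIFT):
            shift_mm = rng.normal(0.0, cfg.magnitude, size=3) if cfg.magnitude > 0 else np.zeros(3)
            offset = np.rint(shift_mm / np.asarray(grid.spacing)).astype(int)
            occ = _integer_shift(occ, offset)

        for cfg in _active(ErrorMode.EXTENT_CRANIAL):
            occ = _extent_error(occ, int(round(cfg.magnitude)), cranial=True, grow=cfg.grow)
        for cfg in _active(ErrorMode.EXTENT_CAUDAL):
            occ = _extent_error(occ, int(round(cfg.magnitude)), cranial=False, grow=cfg.grow)

        for cfg in _active(ErrorMode.SUBSTRUCTURE_INCLUSION):
            # union an adjacent parametric blob (teeth with the mandible,
            # arytenoids with the glottic area, ...)
            direction = _random_unit_vector(rng)
            centroid = _centroid_mm(reference)
            pts = np.argwhere(occ).astype(np.float64) * np.asarray(grid.spacing) + np.asarray(grid.origin)
            proj = (pts - centroid) @ direction
            center = centroid + direction * (float(proj.max()) + 0.5 * cfg.magnitude)
            occ = occ | _ball_mask(grid, center, cfg.magnitude)

        if jitter_scale_mm > 0:
            sdf = signed_distance_mm(StructureMask(grid, occ))
            fld = _correlated_field(grid.shape, grid.spacing, jitter_corr_mm, rng)
            occ = sdf <= jitter_scale_mm * fld

    return StructureMask(
        grid,
        occ,
        organ=reference.organ,
        patient=reference.patient,
    )


def simulate_observer(
    references: Mapping[str, StructureMask],
    profile: ObserverProfile,
    rng: np.random.Generator,
) -> dict[str, StructureMask | None]:
    """One observer's delineations for all organs of one patient.

    Per organ (processed in sorted order for determinism): with probability
    ``1 - delineation_prob[organ]`` the organ is not delineated (``None``);
    otherwise the reference is perturbed under the profile's error modes.
    """
    out: dict[str, StructureMask | None] = {}
    for organ_name in sorted(references):
        organ = Organ(organ_name)
        p = profile.prob_for(organ)
        if rng.random() >= p:
            out[organ_name] = None
            continue
        configs = profile.error_modes.get(organ, ())
        mask = perturb(
            references[organ_name],
            configs,
            profile.jitter_scale_mm,
            profile.jitter_corr_mm,
            rng,
        )
        if mask is not None:
            mask = mask.with_labels(observer=profile.observer, group=profile.group)
        out[organ_name] = mask
    return out


def simulate_cohort(
    n_patients: int,
    profiles: Sequence[ObserverProfile],
    specs: Sequence[PhantomSpec],
    grid: ImageGrid,
    seed: int,
    *,
    size_variation: float = 0.15,
) -> CohortDataset:
    """Simulate a full multi-patient, multi-observer contour cohort.

    Per patient, a seeded ±``size_variation`` anatomy-scale factor is drawn
    per organ, references are voxelized, then every observer's contours are
    generated.  Random streams are keyed by (seed, patient, observer index,
    organ index), so the dataset is a pure function of its arguments and
    adding an observer leaves all other draws untouched.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not profiles:
        raise ValueError("at least one observer profile is required")
    names = [p.observer for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("observer identifiers must be unique")

    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    references: dict[tuple[str, str], StructureMask] = {}
    observations: dict[tuple[str, str, str], StructureMask | None] = {}

    sorted_specs = sorted(specs, key=lambda s: s.organ.value)
    for pi, patient in enumerate(patients):
        rng_patient = np.random.default_rng([seed, 0, pi])
        refs: dict[str, StructureMask] = {}
        for spec in sorted_specs:
            scale = 1.0 + rng_patient.uniform(-size_variation, size_variation)
            mask = make_phantom(spec, grid, size_scale=scale)
            refs[spec.organ.value] = mask.with_labels(patient=patient)
            references[(patient, spec.organ.value)] = refs[spec.organ.value]
        for oi, profile in enumerate(profiles):
            rng_obs = np.random.default_rng([seed, 1, pi, oi])
            obs = simulate_observer(refs, profile, rng_obs)
            for organ_name, mask in obs.items():
                if mask is not None:
                    mask = mask.with_labels(patient=patient)
                observations[(patient, profile.observer, organ_name)] = mask

    return CohortDataset(
        patients=patients,
        grid=grid,
        specs=list(sorted_specs),
        profiles=list(profiles),
        seed=int(seed),
        references=references,
        observations=observations,
    )


def export_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write a cohort to disk as NIfTI masks plus a JSON manifest.

    Returns the manifest path.  Layout: ``masks/<patient>_<observer>_<organ>.nii.gz``
    with observer ``REF`` for references; the manifest is ``manifest.json``.
    """
    out_dir = Path(out_dir)
    mask_dir = out_dir / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []

    def _fname(patient: str, observer: str, organ: str) -> str:
        return f"masks/{patient}_{observer}_{organ}.nii.gz"

    for (patient, organ), mask in sorted(dataset.references.items()):
        rel = _fname(patient, "REF", organ)
        write_mask(mask, out_dir / rel)
        entries.append(ManifestEntry(patient, "REF", organ, "REFERENCE", rel))
    groups = dataset.groups()
    for (patient, observer, organ), mask in sorted(dataset.observations.items()):
        if mask is None:
            continue  # absence of an entry encodes "not delineated"
        rel = _fname(patient, observer, organ)
        write_mask(mask, out_dir / rel)
        entries.append(ManifestEntry(patient, observer, organ, groups[observer], rel))

    manifest = CohortManifest(entries=entries, root=out_dir)
    manifest_path = out_dir / "manifest.json"
    manifest.to_json(manifest_path)
    return manifest_path


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: The six organs used in the default two-group comparison cohort.
DEFAULT_ORGANS = (
    Organ.BRAINSTEM,
    Organ.COCHLEA,
    Organ.MANDIBLE,
    Organ.ORAL_CAVITY,
    Organ.PAROTID,
    Organ.SPINAL_CORD,
)


def default_grid() -> ImageGrid:
    """A 120×120×120 mm head-and-neck field of view at CT-like anisotropic
    resolution (2.5 mm in-plane, 3 mm slices)."""
    return ImageGrid(shape=(48, 48, 40), spacing=(2.5, 2.5, 3.0))


def default_specs(organs: Sequence[Organ] = DEFAULT_ORGANS) -> list[PhantomSpec]:
    """Phantom specs for the requested organs on the default grid.

    Sizes are order-of-magnitude realistic for head-and-neck anatomy
    (parotid ≈ 25 cc, cochlea < 0.5 cc, cord a 5 mm-radius column cropped at
    the caudal scan edge, ...).
    """
    catalogue: dict[Organ, PhantomSpec] = {
        Organ.BRAINSTEM: PhantomSpec(
            Organ.BRAINSTEM, ShapeFamily.TAPERED_CYLINDER, (12.0, 8.0, 25.0), (60.0, 60.0, 88.0)
        ),
        Organ.COCHLEA: PhantomSpec(
            Organ.COCHLEA, ShapeFamily.ELLIPSOID, (3.0, 3.0, 3.0), (30.0, 47.5, 75.0)
        ),
        Organ.GLOTTIC_AREA: PhantomSpec(
            Organ.GLOTTIC_AREA, ShapeFamily.SLAB_STACK, (14.0, 14.0, 10.0), (60.0, 37.5, 39.0),
            lumen_mm=5.0,
        ),
        Organ.MANDIBLE: PhantomSpec(
            Organ.MANDIBLE, ShapeFamily.ARCH, (32.0, 7.0, 0.0), (60.0, 62.5, 57.0)
        ),
        Organ.ORAL_CAVITY: PhantomSpec(
            Organ.ORAL_CAVITY, ShapeFamily.SLAB_STACK, (28.0, 24.0, 18.0), (60.0, 50.0, 63.0),
            lumen_mm=7.0,
        ),
        Organ.PAROTID: PhantomSpec(
            Organ.PAROTID, ShapeFamily.ELLIPSOID, (18.0, 12.0, 25.0), (25.0, 62.5, 72.0)
        ),
        Organ.PCM: PhantomSpec(
            Organ.PCM, ShapeFamily.CURVED_SHELL, (15.0, 19.0, 20.0), (60.0, 72.5, 60.0)
        ),
        Organ.SPINAL_CORD: PhantomSpec(
            Organ.SPINAL_CORD, ShapeFamily.THIN_CYLINDER, (5.0, 0.0, 63.0), (60.0, 77.5, 0.0),
            edge_cropped=True,
        ),
        Organ.SMG: PhantomSpec(
            Organ.SMG, ShapeFamily.ELLIPSOID, (12.0, 10.0, 12.0), (40.0, 40.0, 42.0)
        ),
        Organ.SUPRAGLOTTIC_LARYNX: PhantomSpec(
            Organ.SUPRAGLOTTIC_LARYNX, ShapeFamily.SLAB_STACK, (15.0, 15.0, 14.0),
            (60.0, 37.5, 60.0), lumen_mm=6.0,
        ),
    }
    return [catalogue[o] for o in organs]


#: Per-organ delineation probabilities for the two observer groups, set to
#: the per-group delineation percentages observed in multi-centre guideline
#: audits (guideline users delineate the less-well-known organs — cochlea,
#: glottic area, constrictors, supraglottic larynx — far more often; the
#: cord less often because some delineate the canal, which is excluded).
_DELINEATION_PROB = {
    Organ.BRAINSTEM: {"ICG": 0.89, "OTHER": 0.89},
    Organ.COCHLEA: {"ICG": 0.59, "OTHER": 0.26},
    Organ.GLOTTIC_AREA: {"ICG": 0.48, "OTHER": 0.29},
    Organ.MANDIBLE: {"ICG": 0.96, "OTHER": 0.83},
    Organ.ORAL_CAVITY: {"ICG": 0.70, "OTHER": 0.66},
    Organ.PAROTID: {"ICG": 1.00, "OTHER": 1.00},
    Organ.PCM: {"ICG": 0.44, "OTHER": 0.19},
    Organ.SPINAL_CORD: {"ICG": 0.63, "OTHER": 0.97},
    Organ.SMG: {"ICG": 0.98, "OTHER": 0.69},
    Organ.SUPRAGLOTTIC_LARYNX: {"ICG": 0.41, "OTHER": 0.26},
}

#: Gross-error catalogue per organ.  Probabilities are per contour and an
#: order of magnitude rarer than the ever-present boundary jitter; they are
#: extrapolated from small observer counts in delineation audits and are
#: configuration defaults, not measured prevalences.
def _gross_errors(organ: Organ, group: str) -> tuple[ErrorModeConfig, ...]:
    rare = 0.01 if group == "ICG" else 0.04
    if organ is Organ.COCHLEA:
        # wrong-location delineations seen only outside the guideline group
        p = 0.0 if group == "ICG" else 0.04
        return (ErrorModeConfig(ErrorMode.WRONG_LOCATION, magnitude=30.0, probability=p),)
    if organ is Organ.SPINAL_CORD:
        # canal-for-cord substitution: a ~2.5 mm uniform margin
        return (ErrorModeConfig(ErrorMode.SURROGATE_STRUCTURE, magnitude=2.5, probability=0.03),)
    if organ is Organ.MANDIBLE:
        # teeth occasionally included
        return (ErrorModeConfig(ErrorMode.SUBSTRUCTURE_INCLUSION, magnitude=6.0, probability=rare),)
    if organ is Organ.ORAL_CAVITY:
        return (ErrorModeConfig(ErrorMode.SUBSTRUCTURE_INCLUSION, magnitude=6.0, probability=rare),)
    if organ is Organ.SUPRAGLOTTIC_LARYNX:
        # delineation carried 2-3 cm (≈7 slices at 3 mm) too far caudally
        return (ErrorModeConfig(ErrorMode.EXTENT_CAUDAL, magnitude=7.0, probability=rare, grow=True),)
    if organ is Organ.BRAINSTEM:
        # caudal border interpreted a couple of slices differently
        return (
            ErrorModeConfig(ErrorMode.EXTENT_CAUDAL, magnitude=2.0, probability=0.2, grow=True),
            ErrorModeConfig(ErrorMode.EXTENT_CAUDAL, magnitude=2.0, probability=0.2, grow=False),
        )
    return ()


def default_profiles(
    n_icg: int = 7,
    n_other: int = 7,
    organs: Sequence[Organ] = DEFAULT_ORGANS,
    *,
    icg_jitter_mm: float = 1.0,
    other_jitter_mm: float = 2.5,
    jitter_corr_mm: float = 10.0,
) -> list[ObserverProfile]:
    """The default two-group observer panel.

    Guideline-following observers (ICG) get 1.0 mm boundary jitter and higher
    delineation probabilities for guideline organs; the other group gets
    2.5 mm jitter.  These magnitudes are configuration choices calibrated so
    the two-group comparison qualitatively reproduces the expected pattern
    (lower surface distances for guideline users), not estimates of any
    particular clinic's error sizes.
    """
    profiles: list[ObserverProfile] = []
    for group, n, jitter in (("ICG", n_icg, icg_jitter_mm), ("OTHER", n_other, other_jitter_mm)):
        for i in range(n):
            profiles.append(
                ObserverProfile(
                    observer=f"{group}{i + 1:02d}",
                    group=group,
                    delineation_prob={o: _DELINEATION_PROB[o][group] for o in organs},
                    error_modes={o: _gross_errors(o, group) for o in organs},
                    jitter_scale_mm=jitter,
                    jitter_corr_mm=jitter_corr_mm,
                )
            )
    return profiles
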