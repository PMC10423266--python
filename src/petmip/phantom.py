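"""Synthetic whole-body FDG-PET phantoms with focal lesions and outcome labels.

The generator emulates the statistical structure a baseline PET outcome
pipeline assumes: a low-uptake body (SUV ~1), high-uptake physiological
organs (brain ~8, bladder ~45, liver ~2), and 1-15 focal tumour lesions
whose SUV lies above the segmentation threshold of 4.0.  Outcome labels are
drawn from a logistic model whose log-odds depend on total lesion burden
(metabolic tumour volume, MTV) and dissemination (Dmax_bulk), so a
predictor that captures tumour burden from the images can be trained and
validated end to end without any real data.

Lesions are spheres: the simplest shape with an exact analytic volume,
which gives every downstream volume computation an oracle.  Organ positions
are fractions of the grid extent so phantoms scale with ``grid_shape``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
from scipy import ndimage

from .volume_io import PETVolume, TTP0, TTP1, write_volume

logger = logging.getLogger(__name__)

# Fractional organ layout (fractions of the physical grid extent, z measured
# from the head end).  The brain sits near the top, the bladder near the
# bottom, the liver upper-right in the torso.
_BRAIN_CENTER = (0.13, 0.50, 0.50)
_TORSO_CENTER = (0.62, 0.50, 0.50)
_TORSO_SEMI = (0.36, 0.40, 0.46)       # of (Z, Y, X) extent
_BLADDER_CENTER = (0.90, 0.50, 0.50)
_LIVER_CENTER = (0.52, 0.47, 0.65)
_NECK_RADIUS_MM = 40.0
_PLACEMENT_RETRIES = 500


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom.

    All SUV defaults straddle the operating points of the pipeline: lesion
    SUVs (5-20) and brain (8) exceed the 4.0 segmentation threshold, the
    bladder (45) exceeds the SUV-40 normalization cap so truncation is
    exercised, and liver (2) and body (1) stay below threshold.
    """

    grid_shape: tuple[int, int, int] = (150, 90, 90)   # (z, y, x) voxels
    voxel_size_mm: float = 4.0
    n_lesions: int = 5
    lesion_radius_range_mm: tuple[float, float] = (6.0, 15.0)
    body_suv: float = 1.0
    brain_suv: float = 8.0
    bladder_suv: float = 45.0
    liver_suv: float = 2.0
    lesion_suv_range: tuple[float, float] = (5.0, 20.0)
    brain_radius_mm: float = 55.0
    bladder_radius_mm: float = 24.0
    liver_radius_mm: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.lesion_suv_range[0] <= 4.0:
            raise ValueError("lesion SUVs must exceed the 4.0 segmentation threshold")
        if self.body_suv >= 4.0:
            raise ValueError("body background SUV must lie below the 4.0 threshold")
        if self.lesion_radius_range_mm[0] > self.lesion_radius_range_mm[1]:
            raise ValueError("lesion radius range must be (min, max)")
        ext_z = self.grid_shape[0] * self.voxel_size_mm
        if _BRAIN_CENTER[0] * ext_z < self.brain_radius_mm:
            raise ValueError("grid too small: brain sphere would exceed the head end")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_mm for n in self.grid_shape)


@dataclass
class OutcomeModel:
    """Logistic outcome-label model: logit P(TTP1) = b0 + b_mtv*log(MTV) + b_dmax*Dmax.

    MTV is in mL, Dmax_bulk in cm.  With ``beta_mtv = beta_dmax = 0`` the
    labels are independent of the image.  ``noise_scale`` adds a patient-level
    Gaussian term to the logit.
    """

    beta0: float = -11.0
    beta_mtv: float = 2.5
    beta_dmax: float = 0.1
    noise_scale: float = 0.0

    def logit(self, mtv_ml: float, dmax_cm: float) -> float:
        return self.beta0 + self.beta_mtv * math.log(max(mtv_ml, 1e-2)) + self.beta_dmax * dmax_cm

    @staticmethod
    def null() -> "OutcomeModel":
        """Label model with no image dependence (fair coin)."""
        return OutcomeModel(beta0=0.0, beta_mtv=0.0, beta_dmax=0.0, noise_scale=0.0)

    @staticmethod
    def strong() -> "OutcomeModel":
        """Strongly burden-driven labels (~1/3 prevalence): the benchmark
        condition for signal-recovery checks."""
        return OutcomeModel(beta0=-16.0, beta_mtv=4.0, beta_dmax=0.1, noise_scale=0.0)


@dataclass
class Sphere:
    center_mm: tuple[float, float, float]  # (z, y, x)
    radius_mm: float
    suv: float = 0.0

    @property
    def volume_ml(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius_mm**3 / 1000.0


@dataclass
class LesionTruth:
    """Ground truth accompanying a phantom: per-lesion geometry and organ masks."""

    label_map: np.ndarray                 # int, 0 = background, k = lesion k
    lesions: list[Sphere]
    brain_mask: np.ndarray
    bladder_mask: np.ndarray
    liver_mask: np.ndarray
    centroids_mm: list[tuple[float, float, float]] = field(default_factory=list)
    volumes_ml: list[float] = field(default_factory=list)
    mtv_ml: float = 0.0
    dmax_cm: float = 0.0

    @property
    def physiological_mask(self) -> np.ndarray:
        """Brain + bladder + liver voxels (the known high/structured uptake)."""
        return self.brain_mask | self.bladder_mask | self.liver_mask


def _organ_spheres(spec: PhantomSpec) -> tuple[Sphere, Sphere, Sphere]:
    ext = spec.extent_mm
    brain = Sphere(tuple(f * e for f, e in zip(_BRAIN_CENTER, ext)), spec.brain_radius_mm, spec.brain_suv)
    bladder = Sphere(tuple(f * e for f, e in zip(_BLADDER_CENTER, ext)), spec.bladder_radius_mm, spec.bladder_suv)
    liver = Sphere(tuple(f * e for f, e in zip(_LIVER_CENTER, ext)), spec.liver_radius_mm, spec.liver_suv)
    return brain, bladder, liver


def _torso(spec: PhantomSpec) -> tuple[tuple[float, ...], tuple[float, ...]]:
    ext = spec.extent_mm
    center = tuple(f * e for f, e in zip(_TORSO_CENTER, ext))
    semi = tuple(f * e for f, e in zip(_TORSO_SEMI, ext))
    return center, semi


def _inside_torso(point: np.ndarray, spec: PhantomSpec, margin_mm: float) -> bool:
    """Conservative containment test: the sphere of radius ``margin_mm`` at
    ``point`` stays inside the torso ellipsoid."""
    center, semi = _torso(spec)
    shrink = 1.0 - margin_mm / min(semi)
    if shrink <= 0:
        return False
    u = (np.asarray(point) - center) / np.asarray(semi)
    return float(np.sum(u * u)) <= shrink * shrink


def sample_patient_geometry(spec: PhantomSpec, rng: np.random.Generator) -> list[Sphere]:
    """Draw non-overlapping lesion spheres inside the torso.

    Lesions avoid the brain, bladder and liver and each other (centre
    distance > sum of radii + 2 mm).  Raises ``RuntimeError`` naming the
    constraint if placement fails after bounded retries.
    """
    brain, bladder, liver = _organ_spheres(spec)
    ext = spec.extent_mm
    z_lo = brain.center_mm[0] + brain.radius_mm + 10.0
    z_hi = bladder.center_mm[0] - bladder.radius_mm - 10.0
    obstacles: list[Sphere] = [brain, bladder, liver]
    lesions: list[Sphere] = []
    for k in range(spec.n_lesions):
        r = float(rng.uniform(*spec.lesion_radius_range_mm))
        suv = float(rng.uniform(*spec.lesion_suv_range))
        for attempt in range(_PLACEMENT_RETRIES):
            p = np.array([
                rng.uniform(z_lo, z_hi),
                rng.uniform(0.0, ext[1]),
                rng.uniform(0.0, ext[2]),
            ])
            if not _inside_torso(p, spec, r + spec.voxel_size_mm):
                continue
            clear = all(
                np.linalg.norm(p - np.asarray(o.center_mm)) > r + o.radius_mm + 2.0
                for o in obstacles + lesions
            )
            if clear:
                lesions.append(Sphere(tuple(p), r, suv))
                break
        else:
            raise RuntimeError(
                f"could not place lesion {k + 1}/{spec.n_lesions} (radius {r:.1f} mm) "
                f"after {_PLACEMENT_RETRIES} attempts: non-overlap inside the torso "
                f"ellipsoid is infeasible for this spec"
            )
    return lesions


def _sphere_mask_into(mask_or_vol: np.ndarray, sphere: Sphere, spacing: float,
                      value=True) -> np.ndarray:
    """Rasterize a sphere into an array, touching only its bounding box.

    A voxel belongs to the sphere if its centre lies within the radius.
    Returns the boolean mask of the sphere within the full grid shape only
    when ``mask_or_vol`` is None.
    """
    shape = mask_or_vol.shape
    c = np.asarray(sphere.center_mm) / spacing - 0.5  # voxel-centre coordinates
    r_vox = sphere.radius_mm / spacing
    lo = np.maximum(np.floor(c - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c + r_vox).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return mask_or_vol
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    inside = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r_vox**2
    sub = mask_or_vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[inside] = value
    return mask_or_vol


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    """Torso ellipsoid + head sphere + neck cylinder."""
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size_mm
    center, semi = _torso(spec)
    zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
    zmm, ymm, xmm = (zz + 0.5) * v, (yy + 0.5) * v, (xx + 0.5) * v
    body = (((zmm - center[0]) / semi[0]) ** 2
            + ((ymm - center[1]) / semi[1]) ** 2
            + ((xmm - center[2]) / semi[2]) ** 2) <= 1.0
    brain, _, _ = _organ_spheres(spec)
    head = Sphere(brain.center_mm, brain.radius_mm + 10.0)
    _sphere_mask_into(body, head, v, True)
    # neck: cylinder from the head centre down to the torso
    neck = ((zmm >= brain.center_mm[0]) & (zmm <= center[0])
            & ((ymm - brain.center_mm[1]) ** 2 + (xmm - brain.center_mm[2]) ** 2
               <= _NECK_RADIUS_MM**2))
    return body | neck


def generate_phantom(spec: PhantomSpec,
                     lesions: Optional[list[Sphere]] = None) -> tuple[PETVolume, LesionTruth]:
    """Generate one phantom volume plus its ground truth.

    The SUV grid contains the body at ``body_suv``, organs at their SUVs,
    and ``n_lesions`` lesion spheres; voxels outside the body are 0.
    Deterministic given ``spec.seed``.  Pre-sampled ``lesions`` may be
    supplied (the cohort generator does, so its geometry draws are shared
    with the analytic feature simulator).
    """
    if lesions is None:
        rng = np.random.Generator(np.random.Philox(spec.seed))
        lesions = sample_patient_geometry(spec, rng)
    v = spec.voxel_size_mm
    shape = spec.grid_shape

    suv = np.zeros(shape, dtype=np.float32)
    body = _body_mask(spec)
    suv[body] = spec.body_suv

    brain, bladder, liver = _organ_spheres(spec)
    liver_m = np.zeros(shape, dtype=bool)
    _sphere_mask_into(liver_m, liver, v)
    brain_m = np.zeros(shape, dtype=bool)
    _sphere_mask_into(brain_m, brain, v)
    bladder_m = np.zeros(shape, dtype=bool)
    _sphere_mask_into(bladder_m, bladder, v)
    suv[liver_m] = spec.liver_suv
    suv[brain_m] = spec.brain_suv
    suv[bladder_m] = spec.bladder_suv

    label_map = np.zeros(shape, dtype=np.int16)
    for k, les in enumerate(lesions, start=1):
        _sphere_mask_into(label_map, les, v, k)
        _sphere_mask_into(suv, les, v, np.float32(les.suv))

    truth = LesionTruth(label_map=label_map, lesions=lesions,
                        brain_mask=brain_m, bladder_mask=bladder_m, liver_mask=liver_m)
    _fill_truth_features(truth, spacing_mm=(v, v, v))
    volume = PETVolume(suv=suv, spacing_mm=(v, v, v), patient_id=f"phantom-{spec.seed}")
    return volume, truth


def _fill_truth_features(truth: LesionTruth, spacing_mm: tuple[float, float, float]) -> None:
    """Voxel-level MTV (mL), centroids (mm) and Dmax_bulk (cm) from the label map."""
    voxel_ml = float(np.prod(spacing_mm)) / 1000.0
    ids = [k for k in range(1, len(truth.lesions) + 1)]
    counts = ndimage.sum_labels(np.ones_like(truth.label_map), truth.label_map, ids) if ids else []
    truth.volumes_ml = [float(c) * voxel_ml for c in counts]
    truth.mtv_ml = float(sum(truth.volumes_ml))
    if ids:
        coms = ndimage.center_of_mass(np.ones_like(truth.label_map), truth.label_map, ids)
        truth.centroids_mm = [tuple((np.asarray(c) + 0.5) * spacing_mm) for c in coms]
    truth.dmax_cm = _dmax_from_centroids(truth.centroids_mm, truth.volumes_ml)


def _dmax_from_centroids(centroids_mm, volumes_ml) -> float:
    """Max distance (cm) from the largest lesion's centroid to any other centroid."""
    if len(centroids_mm) <= 1:
        return 0.0
    largest = int(np.argmax(volumes_ml))
    ref = np.asarray(centroids_mm[largest])
    d = max(float(np.linalg.norm(np.asarray(c) - ref))
            for i, c in enumerate(centroids_mm) if i != largest)
    return d / 10.0


@dataclass
class CohortPatient:
    patient_id: str
    volume: PETVolume
    truth: LesionTruth
    label: int
    p_ttp1_true: float
    seed: int


def _patient_seeds(seed: int, n: int) -> list[int]:
    """Per-patient seeds split from one cohort seed (order-independent streams)."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1, np.uint32)[0]) for child in ss.spawn(n)]


def generate_cohort(
    n_patients: int,
    outcome: OutcomeModel | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    n_lesions_range: tuple[int, int] = (1, 8),
) -> Iterator[CohortPatient]:
    """Yield phantoms with outcome labels drawn from the logistic label model.

    Per patient, the lesion count is uniform over ``n_lesions_range`` and the
    label is Bernoulli with logit ``beta0 + beta_mtv*log(MTV) + beta_dmax*Dmax``
    evaluated on the voxelized ground truth.  A generator is returned so large
    cohorts can be streamed into MIPs without holding every volume in memory.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be > 0")
    outcome = outcome if outcome is not None else OutcomeModel()
    base = base_spec if base_spec is not None else PhantomSpec()
    seeds = _patient_seeds(seed, n_patients)
    labels_seen: set[int] = set()
    for i in range(n_patients):
        rng = np.random.Generator(np.random.Philox(seeds[i]))
        n_les = int(rng.integers(n_lesions_range[0], n_lesions_range[1] + 1))
        spec = replace(base, n_lesions=n_les, seed=seeds[i])
        volume, truth = generate_phantom(spec, lesions=sample_patient_geometry(spec, rng))
        logit = outcome.logit(truth.mtv_ml, truth.dmax_cm)
        if outcome.noise_scale > 0:
            logit += outcome.noise_scale * float(rng.normal())
        p = 1.0 / (1.0 + math.exp(-logit))
        label = TTP1 if rng.uniform() < p else TTP0
        labels_seen.add(label)
        pid = f"P{i:04d}"
        volume.patient_id = pid
        if i == n_patients - 1 and len(labels_seen) == 1 and n_patients > 10:
            logger.warning("degenerate outcome model: all %d labels are %s",
                           n_patients, "TTP1" if label == TTP1 else "TTP0")
        yield CohortPatient(pid, volume, truth, label, p, seeds[i])


def simulate_feature_table(
    n_patients: int,
    outcome: OutcomeModel | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    n_lesions_range: tuple[int, int] = (1, 8),
) -> "np.recarray":
    """Labels and true features without rasterizing volumes.

    Uses the same per-patient geometry draws as :func:`generate_cohort` but
    computes MTV analytically (sum of sphere volumes) and Dmax from sphere
    centres, so label-model properties can be checked at large n cheaply.
    """
    outcome = outcome if outcome is not None else OutcomeModel()
    base = base_spec if base_spec is not None else PhantomSpec()
    seeds = _patient_seeds(seed, n_patients)
    rows = []
    for i in range(n_patients):
        rng = np.random.Generator(np.random.Philox(seeds[i]))
        n_les = int(rng.integers(n_lesions_range[0], n_lesions_range[1] + 1))
        spec = replace(base, n_lesions=n_les, seed=seeds[i])
        lesions = sample_patient_geometry(spec, rng)
        mtv = sum(l.volume_ml for l in lesions)
        dmax = _dmax_from_centroids([l.center_mm for l in lesions],
                                    [l.volume_ml for l in lesions])
        logit = outcome.logit(mtv, dmax)
        if outcome.noise_scale > 0:
            logit += outcome.noise_scale * float(rng.normal())
        p = 1.0 / (1.0 + math.exp(-logit))
        label = TTP1 if rng.uniform() < p else TTP0
        rows.append((f"P{i:04d}", label, mtv, dmax, p))
    return np.rec.fromrecords(
        rows, names=["patient_id", "label", "mtv_ml", "dmax_cm", "p_ttp1_true"])


def write_cohort(patients: list[CohortPatient], out_dir: str | Path) -> Path:
    """Write phantoms as NIfTI plus a sidecar CSV of labels and true features."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "cohort.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label", "true_mtv_ml", "true_dmax_cm", "seed"])
        for pat in patients:
            write_volume(pat.volume, out / f"{pat.patient_id}.nii.gz")
            w.writerow([pat.patient_id, "TTP1" if pat.label == TTP1 else "TTP0",
                        f"{pat.truth.mtv_ml:.4f}", f"{pat.truth.dmax_cm:.4f}", pat.seed])
    return out / "cohort.csv"
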