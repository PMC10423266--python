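"""PET volume I/O, patient records, and scan-level quality control.

Volumes are standardized-uptake-value (SUV) grids held in a fixed internal
axis convention ``(z, y, x)``: axis 0 is cranio-caudal with index 0 at the
head end, axis 1 anterior-posterior, axis 2 left-right.  Inputs are assumed
to be in SUV units already; conversion from raw DICOM activity is out of
scope.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Binary outcome labels: progression-free at 2 years vs progression within 2 years.
TTP0 = 0
TTP1 = 1

# EANM-style quality-control limits.
LIVER_SUV_RANGE = (1.3, 3.0)   # inclusive on both ends
GLUCOSE_LIMIT_MMOL_L = 11.0    # strict: glucose must be < 11


@dataclass
class PETVolume:
    """A 3D PET volume in SUV units.

    Parameters
    ----------
    suv : ndarray, shape (nz, ny, nx)
        Non-negative SUV grid, axis order (z, y, x), head at z index 0.
    spacing_mm : tuple of float
        Voxel size per axis (z, y, x) in millimetres.
    patient_id : str
        Identifier carried through the pipeline.
    """

    suv: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.suv.ndim != 3 or min(self.suv.shape) < 2:
            raise ValueError(f"volume must be 3D with shape >= (2,2,2), got {self.suv.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        n_nan = int(np.isnan(self.suv).sum())
        if n_nan:
            raise ValueError(f"volume contains {n_nan} NaN voxel(s)")
        n_neg = int((self.suv < 0).sum())
        if n_neg:
            raise ValueError(f"volume contains {n_neg} negative voxel(s)")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class PatientRecord:
    """Outcome label and optional clinical covariates for one patient."""

    patient_id: str
    label: int  # TTP0 or TTP1
    ipi_score: Optional[int] = None
    glucose_mmol_per_L: Optional[float] = None
    liver_roi: Optional[np.ndarray] = None  # boolean mask or index tuple into the volume

    def __post_init__(self) -> None:
        if self.label not in (TTP0, TTP1):
            raise ValueError(f"label must be {TTP0} (TTP0) or {TTP1} (TTP1), got {self.label!r}")
        if self.ipi_score is not None and not (0 <= int(self.ipi_score) <= 5):
            raise ValueError(f"IPI score must be in 0..5, got {self.ipi_score}")


@dataclass
class QCResult:
    """Outcome of the scan-level quality-control checks."""

    passed: bool
    reasons: list[str] = field(default_factory=list)
    evaluated: dict[str, bool] = field(default_factory=dict)
    liver_suv_mean: Optional[float] = None


def write_volume(volume: PETVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI with voxel spacing in the header.

    The internal (z, y, x) grid is stored transposed to NIfTI's (x, y, z)
    fastest-first convention so that round-trips are bit-identical.
    """
    path = Path(path)
    data = np.ascontiguousarray(np.transpose(volume.suv, (2, 1, 0)))
    affine = np.diag([volume.spacing_mm[2], volume.spacing_mm[1], volume.spacing_mm[0], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing_mm[::-1])
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, patient_id: str = "") -> PETVolume:
    """Read a NIfTI volume into the internal (z, y, x) convention.

    Raises
    ------
    ValueError
        If spacing metadata is missing/zero, or the grid contains NaN or
        negative voxels (counts are reported).
    """
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or non-positive voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj)
    suv = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return PETVolume(suv=suv, spacing_mm=spacing, patient_id=patient_id or Path(path).stem.split(".")[0])


def liver_suv_mean(volume: PETVolume, liver_roi: np.ndarray) -> float:
    """Mean SUV over the liver region of interest."""
    vals = volume.suv[liver_roi] if liver_roi.dtype == bool else volume.suv[tuple(liver_roi.T)]
    if vals.size == 0:
        raise ValueError("empty liver ROI")
    return float(np.mean(vals))


def qc_check(volume: PETVolume, record: PatientRecord) -> QCResult:
    """Apply the scan-level QC criteria.

    A scan fails if liver SUVmean lies outside [1.3, 3.0] (inclusive) or
    plasma glucose is >= 11 mmol/L (the requirement is *lower than* 11).
    A criterion whose input is absent (no liver ROI, no glucose value) is
    reported as not evaluated rather than failed.
    """
    reasons: list[str] = []
    evaluated: dict[str, bool] = {"liver": False, "glucose": False}
    liver_mean: Optional[float] = None

    if record.liver_roi is not None:
        try:
            liver_mean = liver_suv_mean(volume, np.asarray(record.liver_roi))
            evaluated["liver"] = True
            lo, hi = LIVER_SUV_RANGE
            # inclusive bounds, with float32-storage tolerance
            if not (lo - 1e-5 <= liver_mean <= hi + 1e-5):
                reasons.append(
                    f"liver SUVmean out of range: {liver_mean:.2f} not in [{lo}, {hi}]"
                )
        except ValueError:
            logger.warning("patient %s: liver ROI empty, liver QC not evaluated", record.patient_id)

    if record.glucose_mmol_per_L is not None:
        evaluated["glucose"] = True
        if record.glucose_mmol_per_L >= GLUCOSE_LIMIT_MMOL_L:
            reasons.append(
                f"plasma glucose {record.glucose_mmol_per_L:g} mmol/L not lower than "
                f"{GLUCOSE_LIMIT_MMOL_L:g} mmol/L"
            )

    return QCResult(passed=not reasons, reasons=reasons, evaluated=evaluated,
                    liver_suv_mean=liver_mean)


def write_patient_table(records: Sequence[PatientRecord], path: str | Path) -> Path:
    """Write the patient table as CSV (patient_id, label, ipi_score, glucose_mmol_per_L)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label", "ipi_score", "glucose_mmol_per_L"])
        for r in records:
            w.writerow([
                r.patient_id,
                "TTP1" if r.label == TTP1 else "TTP0",
                "" if r.ipi_score is None else int(r.ipi_score),
                "" if r.glucose_mmol_per_L is None else r.glucose_mmol_per_L,
            ])
    return path


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read a patient CSV written by :func:`write_patient_table`."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = {"TTP0": TTP0, "TTP1": TTP1, "0": TTP0, "1": TTP1}[row["label"].strip()]
            ipi = row.get("ipi_score", "")
            glu = row.get("glucose_mmol_per_L", "")
            records.append(PatientRecord(
                patient_id=row["patient_id"],
                label=label,
                ipi_score=int(ipi) if ipi not in ("", None) else None,
                glucose_mmol_per_L=float(glu) if glu not in ("", None) else None,
            ))
    return records
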