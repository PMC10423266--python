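"""SUV-threshold lesion segmentation and quantitative PET features.

Tumours are segmented as 26-connected components of voxels with SUV >= 4.0
(the threshold preferred for lymphoma lesion delineation), excluding known
physiological uptake.  Two features summarize the result: the metabolic
tumour volume MTV (total segmented volume, mL) and the dissemination
feature Dmax_bulk (largest distance, cm, from the centroid of the largest
lesion to the centroid of any other lesion).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume_io import PETVolume

#: Default lesion segmentation threshold (SUV).
SUV_THRESHOLD = 4.0

#: 26-connectivity structuring element (all face/edge/corner neighbours).
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Lesion:
    id: int
    voxel_count: int
    volume_ml: float
    centroid_mm: tuple[float, float, float]   # (z, y, x), physical units
    suv_peak: float


@dataclass
class LesionSet:
    """Connected tumour components of one volume, largest first.

    ``label_map`` assigns 0 to non-lesion voxels and k to lesion k; lesion
    ids are 1-based in decreasing voxel count (ties keep scan order).
    """

    label_map: np.ndarray
    lesions: list[Lesion] = field(default_factory=list)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    threshold_suv: float = SUV_THRESHOLD

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def mtv_ml(self) -> float:
        """Metabolic tumour volume: sum of per-lesion volumes (mL)."""
        return float(sum(l.volume_ml for l in self.lesions))

    @property
    def dmax_bulk_cm(self) -> float:
        return dmax_bulk(self)

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0


def segment_lesions(
    volume: PETVolume,
    threshold_suv: float = SUV_THRESHOLD,
    physiological_mask: Optional[np.ndarray] = None,
    min_voxels: int = 0,
) -> LesionSet:
    """Segment supra-threshold voxels into 26-connected lesion components.

    Voxels with ``SUV >= threshold_suv`` (inclusive, so boundary voxels are
    kept) and not in ``physiological_mask`` are grouped with 26-connectivity.
    Components are relabelled 1..K in decreasing voxel count; components
    smaller than ``min_voxels`` are dropped (no minimum by default).

    The manual deletion of physiological uptake adjacent to tumours that an
    interactive tool would support is replaced by the explicit
    ``physiological_mask`` argument (on phantoms: the known brain/bladder/
    liver masks).
    """
    if threshold_suv <= 0:
        raise ValueError("threshold must be positive")
    fg = volume.suv >= threshold_suv
    if physiological_mask is not None:
        fg &= ~physiological_mask
    raw_labels, n = ndimage.label(fg, structure=_STRUCT_26)
    voxel_ml = volume.voxel_volume_ml

    if n == 0:
        return LesionSet(label_map=np.zeros_like(raw_labels, dtype=np.int32),
                         spacing_mm=volume.spacing_mm, threshold_suv=threshold_suv)

    ids = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones(volume.suv.shape, dtype=np.int64), raw_labels, ids)
    order = np.argsort(-counts, kind="stable")           # decreasing size, stable ties
    keep = [int(ids[i]) for i in order if counts[i] >= min_voxels]

    remap = np.zeros(n + 1, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        remap[old_id] = new_id
    label_map = remap[raw_labels]

    coms = ndimage.center_of_mass(np.ones(volume.suv.shape), raw_labels, keep)
    peaks = ndimage.maximum(volume.suv, raw_labels, keep)
    lesions = []
    for new_id, (old_id, com, peak) in enumerate(zip(keep, coms, peaks), start=1):
        cnt = int(counts[old_id - 1])
        centroid = tuple((np.asarray(com) + 0.5) * np.asarray(volume.spacing_mm))
        lesions.append(Lesion(id=new_id, voxel_count=cnt, volume_ml=cnt * voxel_ml,
                              centroid_mm=centroid, suv_peak=float(peak)))
    return LesionSet(label_map=label_map, lesions=lesions,
                     spacing_mm=volume.spacing_mm, threshold_suv=threshold_suv)


def dmax_bulk(lesions: LesionSet, surface_to_surface: bool = False) -> float:
    """Dissemination feature: distance (cm) from the largest lesion to the
    farthest other lesion; 0 when there are fewer than two lesions.

    The largest lesion is the one with the largest volume (ties broken by
    lower id).  Distances are centroid-to-centroid by default; with
    ``surface_to_surface`` each pairwise distance is reduced by both radii
    of volume-equivalent spheres (floored at 0).
    """
    if lesions.n_lesions <= 1:
        return 0.0
    volumes = [l.volume_ml for l in lesions.lesions]
    largest = int(np.argmax(volumes))    # argmax returns the first (lowest id) on ties
    ref = np.asarray(lesions.lesions[largest].centroid_mm)
    best = 0.0
    for i, les in enumerate(lesions.lesions):
        if i == largest:
            continue
        d = float(np.linalg.norm(np.asarray(les.centroid_mm) - ref))
        if surface_to_surface:
            r_ref = (3.0 * volumes[largest] * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
            r_i = (3.0 * les.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
            d = max(d - r_ref - r_i, 0.0)
        best = max(best, d)
    return best / 10.0


def write_feature_table(rows: list[dict], path: str | Path) -> Path:
    """Write the per-patient feature CSV (patient_id, mtv_ml, dmax_bulk_cm, n_lesions)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["patient_id", "mtv_ml", "dmax_bulk_cm", "n_lesions"])
        w.writeheader()
        for r in rows:
            w.writerow({k: r[k] for k in w.fieldnames})
    return path
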