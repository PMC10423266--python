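"""Maximum-intensity projections on the fixed training canvas.

Every CNN input is a 2D maximum-intensity projection (MIP) of the SUV
volume — coronal (collapsing the anterior-posterior axis) or sagittal
(collapsing left-right) — resampled to 4 x 4 mm pixels and centred on a
fixed 275 x 200 canvas (110 cm x 80 cm), then normalized by a fixed SUV of
40 with truncation above the cap (so normalization is not driven by
high-uptake organs such as the bladder).

Four variants are produced: the regular MIP, the brain-removed MIP
(BR-MIP), the lesion MIP (tumour voxels only, intensities retained) and the
binary lesion mask.  A fifth, the tumour-ablated MIP, replaces lesion
pixels by the mean non-background intensity and is used to check that a
trained model's predictions actually depend on the tumours.

Processing order is fixed: project -> resample -> canvas -> normalize, so
interpolation always sees raw SUV and truncation happens last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume_io import PETVolume
from .lesion_features import LesionSet

logger = logging.getLogger(__name__)

CANVAS_SHAPE = (275, 200)     # rows (cranio-caudal) x columns (transverse)
CANVAS_PIXEL_MM = 4.0
SUV_CAP = 40.0                # fixed normalization maximum
BRAIN_SUV_THRESHOLD = 3.0     # supra-threshold level used to find the brain
BRAIN_TOP_FRACTION = 0.15     # brain centroid must lie in the top 15% of the occupied extent
BRAIN_VOLUME_RANGE_L = (0.5, 2.5)

VARIANTS = ("mip", "brain_removed", "lesion", "lesion_mask", "ablated")


@dataclass
class MIPImage:
    """A 275 x 200 single-channel projection image on the 4 mm canvas."""

    pixels: np.ndarray
    view: str                      # "coronal" | "sagittal"
    variant: str = "mip"
    normalized: bool = False
    pixel_size_mm: float = CANVAS_PIXEL_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != CANVAS_SHAPE:
            raise ValueError(f"canvas must be {CANVAS_SHAPE}, got {self.pixels.shape}")
        if self.view not in ("coronal", "sagittal"):
            raise ValueError(f"view must be coronal or sagittal, got {self.view!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.normalized and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("normalized image must lie in [0, 1]")
        if self.variant == "lesion_mask" and not np.isin(self.pixels, (0.0, 1.0)).all():
            raise ValueError("lesion_mask variant must be binary")


def project(volume: PETVolume, view: str) -> np.ndarray:
    """Maximum-intensity projection at native resolution.

    Coronal collapses the anterior-posterior (y) axis, sagittal the
    left-right (x) axis; the result has axes (cranio-caudal, transverse)
    with the head at row 0.
    """
    if view == "coronal":
        return volume.suv.max(axis=1)
    if view == "sagittal":
        return volume.suv.max(axis=2)
    raise ValueError(f"view must be coronal or sagittal, got {view!r}")


def to_canvas(projection: np.ndarray, source_spacing_mm: tuple[float, float],
              view: str = "coronal", variant: str = "mip",
              order: int = 1) -> MIPImage:
    """Resample a projection to 4 mm pixels and centre it on the zero canvas.

    Bilinear interpolation by default; masks use ``order=0`` to stay binary.
    Raises if the physical extent exceeds the 110 cm x 80 cm canvas.
    """
    projection = np.asarray(projection, dtype=np.float32)
    factors = tuple(s / CANVAS_PIXEL_MM for s in source_spacing_mm)
    if factors == (1.0, 1.0):
        resampled = projection
    else:
        resampled = ndimage.zoom(projection, factors, order=order,
                                 mode="grid-constant", grid_mode=True).astype(np.float32)
    h, w = resampled.shape
    H, W = CANVAS_SHAPE
    if h > H or w > W:
        need_r, need_c = max(h - H, 0), max(w - W, 0)
        raise ValueError(
            f"projection ({h}x{w} px at 4 mm) exceeds the {H}x{W} canvas; "
            f"a crop of {need_r} rows x {need_c} columns would be required")
    canvas = np.zeros(CANVAS_SHAPE, dtype=np.float32)
    r0, c0 = (H - h) // 2, (W - w) // 2
    canvas[r0:r0 + h, c0:c0 + w] = resampled
    return MIPImage(pixels=canvas, view=view, variant=variant, normalized=False)


def normalize(image: MIPImage, suv_cap: float = SUV_CAP) -> MIPImage:
    """Scale to [0, 1] by a fixed SUV cap, truncating values above it."""
    if suv_cap <= 0:
        raise ValueError("suv_cap must be positive")
    if image.normalized:
        return image
    pixels = np.minimum(image.pixels, suv_cap) / suv_cap
    return replace(image, pixels=pixels, normalized=True)


def _projection_spacing(volume: PETVolume, view: str) -> tuple[float, float]:
    sz, sy, sx = volume.spacing_mm
    return (sz, sx) if view == "coronal" else (sz, sy)


def make_mip(volume: PETVolume, view: str, variant: str = "mip",
             suv_cap: float = SUV_CAP) -> MIPImage:
    """Full chain for an intensity MIP: project -> canvas -> normalize."""
    img = to_canvas(project(volume, view), _projection_spacing(volume, view),
                    view=view, variant=variant)
    return normalize(img, suv_cap)


def lesion_mip(volume: PETVolume, lesions: LesionSet, view: str,
               suv_cap: float = SUV_CAP) -> MIPImage:
    """MIP containing only the tumours, with their intensities retained."""
    masked = volume.suv * (lesions.label_map > 0)
    vol = PETVolume(suv=masked, spacing_mm=volume.spacing_mm, patient_id=volume.patient_id)
    return make_mip(vol, view, variant="lesion", suv_cap=suv_cap)


def lesion_mask_mip(volume: PETVolume, lesions: LesionSet, view: str) -> MIPImage:
    """Binary indicator of rays that intersect any lesion (no intensity)."""
    binary = (lesions.label_map > 0).astype(np.float32)
    proj = binary.max(axis=1) if view == "coronal" else binary.max(axis=2)
    img = to_canvas(proj, _projection_spacing(volume, view), view=view,
                    variant="lesion_mask", order=0)
    return replace(img, normalized=True)


def remove_brain(volume: PETVolume,
                 lesion_label_map: Optional[np.ndarray] = None) -> PETVolume:
    """Zero the brain in 3D so both projected views are consistently brainless.

    The brain is identified as the 26-connected component of voxels with
    SUV > 3 whose centroid lies within the top 15% of the occupied
    cranio-caudal extent and whose volume falls in [0.5, 2.5] L.  If no
    component qualifies (e.g. the head was not scanned) the volume is
    returned unchanged with a logged notice.  Lesions overlapping the
    removed region are flagged in the log (truncation risk).
    """
    occupied = np.flatnonzero((volume.suv > 0).any(axis=(1, 2)))
    if occupied.size == 0:
        logger.info("patient %s: empty volume, no brain removed", volume.patient_id)
        return volume
    z_lo, z_hi = int(occupied[0]), int(occupied[-1])
    z_top = z_lo + BRAIN_TOP_FRACTION * (z_hi - z_lo + 1)

    labels, n = ndimage.label(volume.suv > BRAIN_SUV_THRESHOLD, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        logger.info("patient %s: no supra-threshold component, no brain removed",
                    volume.patient_id)
        return volume
    ids = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones(volume.suv.shape, np.int64), labels, ids)
    volumes_l = counts * volume.voxel_volume_ml / 1000.0
    coms_z = np.array([c[0] for c in ndimage.center_of_mass(
        np.ones(volume.suv.shape), labels, ids)])
    lo_l, hi_l = BRAIN_VOLUME_RANGE_L
    candidates = [i for i in range(n)
                  if coms_z[i] <= z_top and lo_l <= volumes_l[i] <= hi_l]
    if not candidates:
        logger.info("patient %s: no brain-like component found (head may be absent), "
                    "volume unchanged", volume.patient_id)
        return volume
    # if several qualify, remove the largest (the brain dominates the head)
    best = max(candidates, key=lambda i: counts[i])
    brain_mask = labels == ids[best]

    if lesion_label_map is not None:
        overlapped = np.unique(lesion_label_map[brain_mask])
        overlapped = overlapped[overlapped > 0]
        if overlapped.size:
            logger.warning(
                "patient %s: lesion(s) %s overlap the removed brain region - "
                "truncation risk, clinician review advised",
                volume.patient_id, overlapped.tolist())

    suv = volume.suv.copy()
    suv[brain_mask] = 0.0
    return PETVolume(suv=suv, spacing_mm=volume.spacing_mm, patient_id=volume.patient_id)


def ablate_tumours(mip: MIPImage, lesion_mask: MIPImage) -> MIPImage:
    """Replace tumour pixels by the mean in-body intensity.

    Pixels under the mask become the mean of non-background pixels
    (pixels > 0) outside the mask, simulating a tumour-free scan; all other
    pixels are unchanged.  Idempotent: re-ablating changes nothing.
    """
    if mip.view != lesion_mask.view:
        raise ValueError("mip and mask views differ")
    if not mip.normalized:
        raise ValueError("ablation expects a normalized MIP")
    mask = lesion_mask.pixels > 0
    if not mask.any():
        return replace(mip, variant="ablated")
    body = (mip.pixels > 0) & ~mask
    if not body.any():
        raise ValueError("mask covers all non-background pixels: no reference intensity")
    fill = float(mip.pixels[body].mean())
    pixels = mip.pixels.copy()
    pixels[mask] = fill
    return replace(mip, pixels=pixels, variant="ablated")
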