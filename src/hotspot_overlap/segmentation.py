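"""Relative-SUVmax sub-volume delineation and uptake metrics.

A sub-volume at threshold x is the set of voxels inside the lesion search
region whose SUV is >= x * SUVmax(region), restricted to the 26-connected
component containing the SUVmax voxel.  Baseline scans are delineated at
x = 30 ... 90 % (A_30 ... A_90), recurrence scans at 40 and 70 % (R_40,
R_70).  MTV is the volume of the 40 % sub-volume and TLG = SUVmean x MTV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BoundingBox, ScalarVolume, VoiMask

__all__ = [
    "UptakeMetrics",
    "delineate_voi",
    "delineate_all",
    "compute_uptake_metrics",
]

logger = logging.getLogger(__name__)

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class UptakeMetrics:
    """SUVmax, SUVmean, metabolic tumor volume and total lesion glycolysis.

    ``mtv_cc`` is the volume of the 40 % SUVmax sub-volume; ``suv_mean`` is
    the mean SUV over that mask; ``tlg_g = suv_mean * mtv_cc``.
    """

    suv_max: float
    suv_mean: float
    mtv_cc: float
    tlg_g: float

    def __post_init__(self) -> None:
        if self.suv_mean > self.suv_max + 1e-12:
            raise ValueError("suv_mean cannot exceed suv_max")
        if self.mtv_cc < 0:
            raise ValueError("mtv_cc must be >= 0")
        if not np.isclose(self.tlg_g, self.suv_mean * self.mtv_cc, rtol=1e-12, atol=0):
            raise ValueError("tlg_g must equal suv_mean * mtv_cc")


def _threshold_component(
    pet: ScalarVolume, region: BoundingBox, threshold_fraction: float
) -> np.ndarray:
    """Thresholded region restricted to the SUVmax voxel's 26-component."""
    if not (0 < threshold_fraction < 1):
        raise ValueError(
            f"threshold_fraction must lie in (0, 1), got {threshold_fraction}"
        )
    sl = region.to_slices(pet)
    sub = pet.data[sl]
    suv_max = float(sub.max())
    if suv_max <= 0:
        raise ValueError("search region has no positive SUV; cannot delineate")
    # argmax resolves ties at the lowest linear index; log when ties exist.
    flat_max = int(np.argmax(sub))
    if np.count_nonzero(sub == suv_max) > 1:
        logger.info(
            "SUVmax tie in region (%d voxels at %.6g); using lowest linear index",
            int(np.count_nonzero(sub == suv_max)),
            suv_max,
        )
    # Inclusive threshold with a tiny relative tolerance: keeps delineation
    # exactly invariant under positive rescaling of the PET (a voxel sitting
    # on the threshold must not flip with the rounding of x * SUVmax).
    above = sub >= threshold_fraction * suv_max * (1.0 - 1e-9)
    labels, _ = ndimage.label(above, structure=_CONNECTIVITY_26)
    seed_label = labels[np.unravel_index(flat_max, sub.shape)]
    component = labels == seed_label
    full = np.zeros(pet.shape, dtype=bool)
    full[sl] = component
    return full


def delineate_voi(
    pet: ScalarVolume,
    region: BoundingBox,
    threshold_fraction: float,
    label: str | None = None,
) -> VoiMask:
    """Delineate one relative-SUVmax sub-volume on a PET scan.

    Parameters
    ----------
    pet
        PET volume in SUV.
    region
        Physical bounding box of the lesion search region (mm).
    threshold_fraction
        Relative cut x in (0, 1); the mask keeps voxels with
        SUV >= x * SUVmax(region), in the SUVmax voxel's 26-connected
        component.
    label
        Mask label; defaults to ``voi_<percent>``.
    """
    mask = _threshold_component(pet, region, threshold_fraction)
    if label is None:
        label = f"voi_{round(threshold_fraction * 100)}"
    return VoiMask(
        mask=mask,
        spacing=pet.spacing,
        origin=pet.origin,
        direction=pet.direction,
        label=label,
        threshold_fraction=threshold_fraction,
    )


def delineate_all(
    pet_a: ScalarVolume,
    pet_r: ScalarVolume,
    region_a: BoundingBox,
    region_r: BoundingBox,
    study,
) -> dict[str, VoiMask]:
    """All study sub-volumes for one case: A_X on the baseline scan and R_X
    on the recurrence scan (defaults: 7 + 2 masks)."""
    masks: dict[str, VoiMask] = {}
    for pct in study.baseline_thresholds:
        lbl = f"A_{pct}"
        masks[lbl] = delineate_voi(pet_a, region_a, pct / 100.0, label=lbl)
    for pct in study.recurrence_thresholds:
        lbl = f"R_{pct}"
        masks[lbl] = delineate_voi(pet_r, region_r, pct / 100.0, label=lbl)
    return masks


def compute_uptake_metrics(
    pet: ScalarVolume, region: BoundingBox, mtv_threshold_fraction: float = 0.40
) -> UptakeMetrics:
    """Uptake metrics of one lesion: SUVmax over the search region, and
    SUVmean/MTV/TLG over the 40 % SUVmax sub-volume."""
    sl = region.to_slices(pet)
    suv_max = float(pet.data[sl].max())
    mask = _threshold_component(pet, region, mtv_threshold_fraction)
    voxels = pet.data[mask]
    mtv_cc = voxels.size * float(np.prod(pet.spacing)) / 1000.0
    suv_mean = float(voxels.mean()) if voxels.size else 0.0
    return UptakeMetrics(
        suv_max=suv_max,
        suv_mean=suv_mean,
        mtv_cc=mtv_cc,
        tlg_g=suv_mean * mtv_cc,
    )
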