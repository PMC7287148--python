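"""Volume-overlap indices between baseline and recurrence sub-volumes.

Five indices are computed for each (A_X, R_X) mask pair, all in [0, 1]:
Dice 2|A∩R|/(|A|+|R|), Jaccard |A∩R|/|A∪R|, the overlap fraction
OF = |A∩R|/min(|A|,|R|), and the two directed fractions |A∩R|/|A| and
|A∩R|/|R|.  Index magnitudes are banded into the conventional agreement
labels (poor/fair/moderate/good/very good) at 0.2-wide cutpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volumes import VoiMask

__all__ = [
    "OverlapResult",
    "INDEX_NAMES",
    "compute_overlap",
    "overlap_matrix",
    "classify_agreement",
    "AGREEMENT_BANDS",
]

INDEX_NAMES = ("dice", "jaccard", "of", "common_over_a", "common_over_r")

# Band edges chosen so that values reported to two decimals fall in the
# conventional 0-0.20 / 0.21-0.40 / 0.41-0.60 / 0.61-0.80 / 0.81-1.00 bins.
AGREEMENT_BANDS = (
    (0.205, "poor"),
    (0.405, "fair"),
    (0.605, "moderate"),
    (0.805, "good"),
    (1.0, "very good"),
)


@dataclass(frozen=True)
class OverlapResult:
    """The five overlap indices plus component volumes for one mask pair."""

    case_id: str
    position_group: str
    method: str
    a_label: str
    r_label: str
    dice: float
    jaccard: float
    of: float
    common_over_a: float
    common_over_r: float
    vol_a_cc: float
    vol_r_cc: float
    vol_common_cc: float

    def __post_init__(self) -> None:
        for name in INDEX_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"index {name}={v} outside [0, 1]")
        if self.vol_common_cc > min(self.vol_a_cc, self.vol_r_cc) + 1e-9:
            raise ValueError("common volume exceeds a component volume")

    def indices(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"empty denominator for {what}; defining ratio as 0", stacklevel=3)
        return 0.0
    return num / den


def compute_overlap(
    mask_a: VoiMask,
    mask_r: VoiMask,
    *,
    case_id: str = "",
    position_group: str = "",
    method: str = "",
) -> OverlapResult:
    """Compute the five overlap indices for one (A, R) mask pair.

    Both masks must live on the same grid (the canonical baseline grid once
    recurrence masks have been mapped across sessions) and at least one must
    be non-empty.  Indices are 1 for identical masks and 0 for disjoint
    masks; ratios with an empty denominator are defined as 0 with a warning.
    """
    if not mask_a.same_grid(mask_r):
        raise ValueError(
            f"masks {mask_a.label!r} and {mask_r.label!r} are on different grids"
        )
    n_a = mask_a.voxel_count
    n_r = mask_r.voxel_count
    if n_a == 0 and n_r == 0:
        raise ValueError(
            f"both masks empty ({mask_a.label!r}, {mask_r.label!r}); overlap undefined"
        )
    inter = int(np.count_nonzero(mask_a.mask & mask_r.mask))
    union = n_a + n_r - inter
    vox_cc = mask_a.voxel_volume_mm3 / 1000.0
    pair = f"({mask_a.label}, {mask_r.label})"
    return OverlapResult(
        case_id=case_id,
        position_group=position_group,
        method=method,
        a_label=mask_a.label,
        r_label=mask_r.label,
        dice=_safe_ratio(2 * inter, n_a + n_r, f"dice{pair}"),
        jaccard=_safe_ratio(inter, union, f"jaccard{pair}"),
        of=_safe_ratio(inter, min(n_a, n_r), f"of{pair}"),
        common_over_a=_safe_ratio(inter, n_a, f"common_over_a{pair}"),
        common_over_r=_safe_ratio(inter, n_r, f"common_over_r{pair}"),
        vol_a_cc=n_a * vox_cc,
        vol_r_cc=n_r * vox_cc,
        vol_common_cc=inter * vox_cc,
    )


def overlap_matrix(
    case_id: str,
    position_group: str,
    method: str,
    a_masks: dict[str, VoiMask],
    r_masks: dict[str, VoiMask],
) -> list[OverlapResult]:
    """All (A-threshold, R-threshold) overlaps for one case and method.

    Masks must already sit on the canonical comparison grid for the given
    method.  With the default 7 x 2 threshold grid this yields 14 results
    (70 index values) per method, 140 index values per case over both
    registration methods.
    """
    results = []
    for a_label in sorted(a_masks, key=_label_sort_key):
        for r_label in sorted(r_masks, key=_label_sort_key):
            results.append(
                compute_overlap(
                    a_masks[a_label],
                    r_masks[r_label],
                    case_id=case_id,
                    position_group=position_group,
                    method=method,
                )
            )
    return results


def _label_sort_key(label: str):
    prefix, _, pct = label.partition("_")
    try:
        return (prefix, int(pct))
    except ValueError:
        return (prefix, label)


def classify_agreement(value: float) -> str:
    """Band an index value: poor / fair / moderate / good / very good.

    Cutpoints are half-open at 0.205, 0.405, 0.605 and 0.805, so continuous
    values agree with the two-decimal banding 0-0.20, 0.21-0.40, 0.41-0.60,
    0.61-0.80, 0.81-1.00.
    """
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"agreement value must lie in [0, 1], got {value}")
    for upper, band in AGREEMENT_BANDS:
        if value < upper:
            return band
    return "very good"  # value == 1.0
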