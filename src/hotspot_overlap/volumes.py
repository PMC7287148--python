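"""Core in-memory containers for 3D scalar volumes and binary sub-volumes.

Arrays are indexed ``[i, j, k]`` along the (x, y, z) axes.  Physical
coordinates are in millimetres and refer to voxel *centers*: the center of
voxel ``(i, j, k)`` sits at ``origin + direction @ (spacing * (i, j, k))``.
Volumes of masks are reported in cc (cm^3) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ScalarVolume",
    "VoiMask",
    "BoundingBox",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when volume geometry is missing, invalid or inconsistent."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise GeometryError(f"{name} must have 3 components, got {v.size}")
    return v


@dataclass
class ScalarVolume:
    """A 3D intensity grid (PET in SUV or CT in HU) with physical geometry.

    Parameters
    ----------
    data
        3D float array, indexed ``[x, y, z]``.
    spacing
        Per-axis voxel size in mm; strictly positive.
    origin
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal direction-cosine matrix (rows map index axes to
        physical axes). Defaults to identity.
    modality
        ``"PET"`` (values in SUV, must be >= 0) or ``"CT"`` (values in HU).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    modality: str
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(
                f"volume data must be 3D, got {self.data.ndim}D"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise GeometryError("direction matrix is not orthonormal")
        if self.modality not in ("PET", "CT"):
            raise ValueError(f"modality must be 'PET' or 'CT', got {self.modality!r}")
        if self.modality == "PET" and np.any(self.data < 0):
            raise ValueError("PET volume contains negative SUV values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ScalarVolume | VoiMask", tol: float = 1e-6) -> bool:
        """Whether *other* lives on the same physical grid as this volume."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def index_to_physical(self, idx) -> np.ndarray:
        """Physical coordinate (mm) of voxel center(s) ``idx`` (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def physical_to_index(self, pos) -> np.ndarray:
        """Continuous voxel index of physical point(s) ``pos`` (..., 3)."""
        pos = np.asarray(pos, dtype=float)
        return ((pos - self.origin) @ self.direction) / self.spacing

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical x/y/z coordinate arrays, each of the volume's shape.

        Only defined for identity-direction grids, which is all the phantom
        generator produces.
        """
        if not np.allclose(self.direction, np.eye(3), atol=1e-9):
            raise GeometryError("coordinate_grids requires an identity direction matrix")
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]

    def to_sitk(self) -> sitk.Image:
        """Convert to a SimpleITK image (which indexes arrays ``[z, y, x]``)."""
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, modality: str) -> "ScalarVolume":
        if img.GetDimension() != 3:
            raise GeometryError(
                f"expected a 3D image, got {img.GetDimension()}D"
            )
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            data=data,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
            modality=modality,
        )


@dataclass
class VoiMask:
    """A binary sub-volume tied to a reference grid, with threshold provenance.

    ``label`` is one of the study labels (``A_30`` ... ``A_90``, ``R_40``,
    ``R_70``) or a ground-truth label; ``threshold_fraction`` is the relative
    SUVmax cut x in (0, 1), or ``None`` for ground-truth masks.
    """

    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    label: str
    threshold_fraction: float | None = None
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise GeometryError(f"mask must be 3D, got {self.mask.ndim}D")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.threshold_fraction is not None and not (0 < self.threshold_fraction < 1):
            raise ValueError(
                f"threshold_fraction must lie in (0, 1), got {self.threshold_fraction}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        """Mask volume in cc: voxel count x voxel volume (mm^3) / 1000."""
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0

    def centroid_mm(self) -> np.ndarray:
        """Physical centroid (mm) of the mask; error if empty."""
        if self.voxel_count == 0:
            raise ValueError(f"mask {self.label!r} is empty; centroid undefined")
        idx = np.argwhere(self.mask).mean(axis=0)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def same_grid(self, other, tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.mask.astype(np.uint8).transpose(2, 1, 0))
        )
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img


@dataclass(frozen=True)
class BoundingBox:
    """An axis-aligned physical box [lo, hi] in mm used as a search region."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = _as_vec3(self.lo, "lo")
        hi = _as_vec3(self.hi, "hi")
        if np.any(hi <= lo):
            raise ValueError(f"empty bounding box: lo={tuple(lo)}, hi={tuple(hi)}")
        object.__setattr__(self, "lo", tuple(float(v) for v in lo))
        object.__setattr__(self, "hi", tuple(float(v) for v in hi))

    @classmethod
    def around(cls, center, half_extent) -> "BoundingBox":
        c = _as_vec3(center, "center")
        h = _as_vec3(half_extent, "half_extent")
        return cls(tuple(c - h), tuple(c + h))

    def to_slices(self, vol: ScalarVolume | VoiMask) -> tuple[slice, slice, slice]:
        """Voxel-index slices of the box on *vol*'s grid (clipped to the grid).

        Requires an identity direction matrix; a voxel is included when its
        center falls inside the box.
        """
        if not np.allclose(vol.direction, np.eye(3), atol=1e-9):
            raise GeometryError("bounding-box cropping requires an identity direction matrix")
        lo_idx = np.ceil((np.asarray(self.lo) - vol.origin) / vol.spacing - 1e-9)
        hi_idx = np.floor((np.asarray(self.hi) - vol.origin) / vol.spacing + 1e-9)
        lo_idx = np.clip(lo_idx, 0, np.asarray(vol.shape) - 1).astype(int)
        hi_idx = np.clip(hi_idx, 0, np.asarray(vol.shape) - 1).astype(int)
        if np.any(hi_idx < lo_idx):
            raise ValueError("bounding box does not intersect the volume grid")
        return tuple(slice(int(a), int(b) + 1) for a, b in zip(lo_idx, hi_idx))  # type: ignore[return-value]

    def region_mask(self, vol: ScalarVolume | VoiMask) -> np.ndarray:
        """Boolean array marking voxels whose centers lie inside the box."""
        out = np.zeros(vol.shape, dtype=bool)
        out[self.to_slices(vol)] = True
        return out
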