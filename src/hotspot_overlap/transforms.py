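"""Rigid transforms and dense deformation fields.

Both types represent *resampling* maps from the baseline (fixed) space to
the recurrence (moving) space: to bring a recurrence-session mask onto the
baseline grid, each baseline voxel center is mapped through the transform
and the recurrence image is interpolated there.

Rigid convention: ``p' = R (p - c) + c + t`` with ``R = Rz @ Ry @ Rx``
(intrinsic rotations about the fixed axes, angles in radians), rotation
center ``c`` and translation ``t`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = ["RigidTransform", "DeformationField", "rigid_discrepancy"]


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid map ``p -> R (p - c) + c + t``.

    ``rotation_rad`` holds the (x, y, z) Euler angles of ``R = Rz @ Ry @ Rx``.
    Zero parameters give the identity.
    """

    rotation_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("rotation_rad", "translation_mm", "center_mm"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            if v.size != 3 or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be 3 finite components")
            object.__setattr__(self, name, tuple(float(x) for x in v))

    @property
    def matrix(self) -> np.ndarray:
        ax, ay, az = self.rotation_rad
        return _rot_z(az) @ _rot_y(ay) @ _rot_x(ax)

    @property
    def is_identity(self) -> bool:
        return all(v == 0.0 for v in self.rotation_rad + self.translation_mm)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map physical points (..., 3) through the transform."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (p - c) @ self.matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        t = np.asarray(self.translation_mm)
        return RigidTransform.from_matrix(R.T, -R.T @ t, self.center_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply *other* first), centered at origin."""
        M = self.matrix @ other.matrix
        offset = self.apply(other.apply(np.zeros(3)))
        return RigidTransform.from_matrix(
            M, offset, (0.0, 0.0, 0.0), translation_is_offset=True
        )

    @staticmethod
    def euler_zyx_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
        """Recover (ax, ay, az) with ``R = Rz(az) @ Ry(ay) @ Rx(ax)``."""
        ay = float(np.arcsin(np.clip(-R[2, 0], -1.0, 1.0)))
        if abs(np.cos(ay)) > 1e-8:
            ax = float(np.arctan2(R[2, 1], R[2, 2]))
            az = float(np.arctan2(R[1, 0], R[0, 0]))
        else:  # gimbal lock: fold everything into ax
            ax = float(np.arctan2(-R[1, 2], R[1, 1]))
            az = 0.0
        return ax, ay, az

    @classmethod
    def from_matrix(
        cls,
        R: np.ndarray,
        translation: np.ndarray,
        center=(0.0, 0.0, 0.0),
        *,
        translation_is_offset: bool = False,
    ) -> "RigidTransform":
        """Build from a rotation matrix.

        With ``translation_is_offset=True``, *translation* is the affine
        offset ``o`` of ``p -> R p + o`` and the stored translation is
        derived for the given center.
        """
        R = np.asarray(R, dtype=float).reshape(3, 3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("matrix is not a proper rotation")
        c = np.asarray(center, dtype=float)
        o = np.asarray(translation, dtype=float)
        if translation_is_offset:
            t = o + R @ c - c
        else:
            t = o
        angles = cls.euler_zyx_from_matrix(R)
        return cls(angles, tuple(t), tuple(c))

    def to_sitk(self) -> sitk.Transform:
        tfm = sitk.AffineTransform(3)
        tfm.SetMatrix(tuple(self.matrix.flatten()))
        tfm.SetCenter(self.center_mm)
        tfm.SetTranslation(self.translation_mm)
        return tfm

    @classmethod
    def from_sitk_euler(cls, tfm: sitk.Euler3DTransform) -> "RigidTransform":
        R = np.asarray(tfm.GetMatrix()).reshape(3, 3)
        t = np.asarray(tfm.GetTranslation())
        c = np.asarray(tfm.GetCenter())
        return cls.from_matrix(R, t, tuple(c))

    def to_dict(self) -> dict:
        return {
            "rotation_rad": list(self.rotation_rad),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            tuple(d["rotation_rad"]),
            tuple(d["translation_mm"]),
            tuple(d["center_mm"]),
        )


def rigid_discrepancy(a: RigidTransform, b: RigidTransform, probe_radius_mm: float = 0.0):
    """(rotation angle in degrees, translation in mm) separating two rigids.

    Rotation: geodesic angle of ``Ra @ Rb.T``.  Translation: distance between
    the images of b's rotation center (plus, if ``probe_radius_mm`` > 0, the
    worst case over axis probes at that radius).
    """
    Ra, Rb = a.matrix, b.matrix
    M = Ra @ Rb.T
    cos_ang = np.clip((np.trace(M) - 1.0) / 2.0, -1.0, 1.0)
    rot_deg = float(np.degrees(np.arccos(cos_ang)))
    probes = [np.asarray(b.center_mm)]
    if probe_radius_mm > 0:
        for ax in np.eye(3):
            probes.append(np.asarray(b.center_mm) + probe_radius_mm * ax)
    trans_mm = max(float(np.linalg.norm(a.apply(p) - b.apply(p))) for p in probes)
    return rot_deg, trans_mm


@dataclass
class DeformationField:
    """Dense displacement field on the baseline (fixed) grid.

    ``displacement[i, j, k]`` is the non-rigid residual u (mm) on top of the
    rigid initialization: the baseline point p at that voxel center maps to
    ``init(p) + u(p)``.  A zero field composed with an identity ``init`` is
    the identity map, and a zero field reproduces the rigid result exactly.
    """

    displacement: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    control_spacing_mm: float
    init: RigidTransform = field(default_factory=RigidTransform)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError(
                f"displacement must have shape (nx, ny, nz, 3), got {self.displacement.shape}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        """Per-voxel magnitude (mm) of the non-rigid residual."""
        return np.linalg.norm(self.displacement, axis=-1)

    def grid_points(self) -> np.ndarray:
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def total_displacement(self) -> np.ndarray:
        """Total displacement d with mapped point = p + d(p) (rigid folded in)."""
        pts = self.grid_points()
        return self.init.apply(pts) - pts + self.displacement

    def mapped_points(self) -> np.ndarray:
        """Mapped positions init(p) + u(p) of every grid voxel center."""
        return self.grid_points() + self.total_displacement()

    def _field_image(self, total: bool) -> sitk.Image:
        data = self.total_displacement() if total else self.displacement
        arr = np.ascontiguousarray(data.transpose(2, 1, 0, 3))
        img = sitk.GetImageFromArray(arr, isVector=True)
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    def to_sitk_image(self) -> sitk.Image:
        """The residual field as a NIfTI-writable vector image."""
        return self._field_image(total=False)

    def to_sitk(self) -> sitk.Transform:
        """The full resampling transform (rigid init + residual field)."""
        return sitk.DisplacementFieldTransform(
            sitk.Cast(self._field_image(total=True), sitk.sitkVectorFloat64)
        )

    def jacobian_determinant(self) -> np.ndarray:
        """Per-voxel Jacobian determinant of the full map."""
        det = sitk.DisplacementFieldJacobianDeterminant(
            sitk.Cast(self._field_image(total=True), sitk.sitkVectorFloat64)
        )
        return sitk.GetArrayFromImage(det).transpose(2, 1, 0)
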