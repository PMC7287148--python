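"""Synthetic paired-session PET/CT phantoms with known ground truth.

Each case emulates one patient with a focal head-and-neck-like lesion: a
baseline session (PET_A/CT_A) carrying a two-compartment lesion (high-uptake
core inside a lower-uptake rim) and a recurrence session (PET_R/CT_R) in
which the anatomy has been rigidly repositioned — and, for the
non-treatment-position (NTP) group, smoothly deformed — and the baseline
lesion is replaced by a smaller recurrence lesion offset from the baseline
hotspot.  Treatment-position (TP) cases have small repositioning errors and
no deformation, mimicking acquisition in a radiotherapy immobilization
device.

The scene is analytic: every image is the scene evaluated at (inverse-
mapped) voxel centers, so ground-truth masks and transforms are exact and a
given config + seed reproduces the case bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .transforms import DeformationField, RigidTransform
from .volumes import ScalarVolume, VoiMask

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "generate_case",
    "generate_cohort",
    "generate_baseline_session",
]

# CT compartment densities (HU) and body layout, fixed across the study.
_HU_AIR = -1000.0
_HU_SOFT = 40.0
_HU_BONE = 700.0
_HU_LESION = 60.0


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one synthetic case.

    All physical quantities are in mm and SUV.  ``rigid_error`` is the
    forward patient motion between sessions: 3 rotations (degrees, about
    x/y/z through the grid center) and 3 translations (mm).
    ``recurrence_offset_mm`` displaces the recurrence-lesion centroid from
    the *deformed* baseline hotspot centroid, i.e. it is the biological
    relapse shift on top of the purely geometric session mismatch.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    lesion_center_mm: tuple[float, float, float] = (72.0, 60.0, 72.0)
    lesion_radius_mm: float = 11.0
    hotspot_radius_mm: float = 5.0
    suv_background: float = 1.0
    suv_rim: float = 8.0
    suv_core: float = 20.0
    recurrence_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    recurrence_radius_mm: float = 7.0
    rigid_error: tuple[float, float, float, float, float, float] = (0, 0, 0, 0, 0, 0)
    deformation_amplitude_mm: float = 0.0
    deformation_wavelength_mm: float = 80.0
    noise_sd: float = 0.0
    ct_noise_hu: float = 0.0
    position_group: Literal["TP", "NTP"] = "TP"
    seed: int = 0
    case_id: str = "case_000"
    # Recurrence lesion uptake defaults to the baseline lesion's levels.
    recurrence_suv_rim: float | None = None
    recurrence_suv_core: float | None = None

    def __post_init__(self) -> None:
        if not (self.suv_core > self.suv_rim > self.suv_background >= 0):
            raise ValueError(
                "uptake levels must satisfy suv_core > suv_rim > suv_background >= 0, "
                f"got core={self.suv_core}, rim={self.suv_rim}, "
                f"background={self.suv_background}"
            )
        for name in ("lesion_radius_mm", "hotspot_radius_mm", "recurrence_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hotspot_radius_mm >= self.lesion_radius_mm:
            raise ValueError("hotspot_radius_mm must be smaller than lesion_radius_mm")
        if self.noise_sd < 0 or self.ct_noise_hu < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.deformation_amplitude_mm < 0:
            raise ValueError("deformation_amplitude_mm must be >= 0")
        if self.deformation_wavelength_mm <= 0:
            raise ValueError("deformation_wavelength_mm must be > 0")
        if self.position_group not in ("TP", "NTP"):
            raise ValueError(f"position_group must be 'TP' or 'NTP', got {self.position_group!r}")
        if len(self.rigid_error) != 6:
            raise ValueError("rigid_error must be (rx_deg, ry_deg, rz_deg, tx, ty, tz)")

    @property
    def physical_extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm)

    @property
    def grid_center_mm(self) -> np.ndarray:
        return self.physical_extent_mm / 2.0

    def forward_rigid(self) -> RigidTransform:
        """The rigid part of the baseline -> recurrence motion."""
        rx, ry, rz, tx, ty, tz = self.rigid_error
        return RigidTransform(
            rotation_rad=tuple(np.radians([rx, ry, rz])),
            translation_mm=(tx, ty, tz),
            center_mm=tuple(self.grid_center_mm),
        )


@dataclass
class PhantomCase:
    """One synthetic patient: four volumes, ground truth, and provenance."""

    pet_a: ScalarVolume
    ct_a: ScalarVolume
    pet_r: ScalarVolume
    ct_r: ScalarVolume
    true_rigid: RigidTransform
    true_deformation: DeformationField
    true_lesion_a: VoiMask
    true_lesion_r: VoiMask
    position_group: str
    case_id: str
    config: PhantomConfig

    def __post_init__(self) -> None:
        for a, b in ((self.pet_a, self.ct_a), (self.pet_r, self.ct_r)):
            if not a.same_grid(b):
                raise ValueError("PET and CT of one session must share grid geometry")


class _Scene:
    """Analytic baseline scene: body ellipsoid, bone landmarks, lesion.

    The soft tissue carries a smooth sinusoidal HU texture (anatomical
    detail) so that intensity-based registration is constrained away from
    compartment edges; the texture deforms with the anatomy because the
    scene is evaluated at inverse-mapped points.
    """

    def __init__(self, cfg: PhantomConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        if rng is None:
            rng = np.random.default_rng(0)
        # Strong, smooth soft-tissue heterogeneity (fat/muscle/vessel scale)
        # so free-form registration is constrained throughout the body.  A
        # randomly oriented orthonormal triple guarantees texture gradients
        # along every spatial direction (purely random directions can land
        # nearly coplanar, leaving one displacement component unobservable);
        # two extra random waves break the lattice regularity.
        basis, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        extra = rng.normal(size=(2, 3))
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
        self.texture_dirs = np.vstack([basis, extra])
        self.texture_phases = rng.uniform(0, 2 * np.pi, size=len(self.texture_dirs))
        self.texture_amplitude_hu = 120.0
        self.texture_wavelength_mm = 25.0
        c = cfg.grid_center_mm
        ext = cfg.physical_extent_mm
        self.body_center = c
        self.body_radii = ext * np.array([0.44, 0.44, 0.48])
        lc = np.asarray(cfg.lesion_center_mm)
        # Bone landmarks near the lesion: a spine-like cylinder along z and
        # an off-axis sphere, both inside the registration focus region.
        self.spine_xy = lc[:2] + np.array([-24.0, 18.0])
        self.spine_radius = 7.0
        self.bone_sphere_center = lc + np.array([18.0, -22.0, 15.0])
        self.bone_sphere_radius = 8.0

    # -- geometry helpers (pts: (..., 3) physical mm) -----------------
    def _in_body(self, pts):
        d = (pts - self.body_center) / self.body_radii
        return np.einsum("...i,...i->...", d, d) <= 1.0

    def _in_sphere(self, pts, center, radius):
        d = pts - np.asarray(center)
        return np.einsum("...i,...i->...", d, d) <= radius**2

    def _in_spine(self, pts):
        d = pts[..., :2] - self.spine_xy
        return np.einsum("...i,...i->...", d, d) <= self.spine_radius**2

    def lesion_mask(self, pts, center, rim_radius):
        return self._in_sphere(pts, center, rim_radius)

    def pet(self, pts, lesion_center=None, rim_radius=None, core_radius=None,
            suv_rim=None, suv_core=None):
        """PET scene in SUV; pass ``lesion_center=None`` for lesion-free anatomy."""
        cfg = self.cfg
        out = np.where(self._in_body(pts), cfg.suv_background, 0.0)
        if lesion_center is not None:
            rim = self._in_sphere(pts, lesion_center, rim_radius)
            core = self._in_sphere(pts, lesion_center, core_radius)
            out = np.where(rim, suv_rim, out)
            out = np.where(core, suv_core, out)
        return out

    def _texture(self, pts):
        k = 2.0 * np.pi / self.texture_wavelength_mm
        out = np.zeros(pts.shape[:-1])
        for wave in range(len(self.texture_phases)):
            out += np.sin(k * np.einsum("...i,i->...", pts, self.texture_dirs[wave])
                          + self.texture_phases[wave])
        return self.texture_amplitude_hu / len(self.texture_phases) * out

    def ct(self, pts, lesion_center=None, rim_radius=None):
        body = self._in_body(pts)
        out = np.where(body, _HU_SOFT + self._texture(pts), _HU_AIR)
        out = np.where(body & self._in_spine(pts), _HU_BONE, out)
        out = np.where(
            body & self._in_sphere(pts, self.bone_sphere_center, self.bone_sphere_radius),
            _HU_BONE,
            out,
        )
        if lesion_center is not None:
            # tumors are heterogeneous on CT: keep the texture inside the
            # lesion so registration stays constrained there
            out = np.where(
                self._in_sphere(pts, lesion_center, rim_radius),
                _HU_LESION + self._texture(pts),
                out,
            )
        return out


def _sinusoid_field(cfg: PhantomConfig, rng: np.random.Generator):
    """Smooth displacement components for the recurrence->baseline map.

    Per-axis sinusoids with random unit wave-vectors and phases; each axis
    amplitude is amplitude/sqrt(3) so the field magnitude never exceeds
    ``deformation_amplitude_mm`` (keeping the map invertible at the
    amplitude/wavelength ratios used: A * 2*pi / lambda < 1).
    """
    amp = cfg.deformation_amplitude_mm / np.sqrt(3.0)
    k = 2.0 * np.pi / cfg.deformation_wavelength_mm
    dirs = rng.normal(size=(3, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=3)

    def displacement(pts: np.ndarray) -> np.ndarray:
        if cfg.deformation_amplitude_mm == 0:
            return np.zeros_like(pts)
        out = np.empty_like(pts, dtype=float)
        for ax in range(3):
            phase = k * np.einsum("...i,i->...", pts, dirs[ax]) + phases[ax]
            out[..., ax] = amp * np.sin(phase)
        return out

    return displacement


def _check_inside(cfg: PhantomConfig, center, radius, what: str) -> None:
    lo = np.asarray(center) - radius
    hi = np.asarray(center) + radius
    if np.any(lo < 0) or np.any(hi > cfg.physical_extent_mm):
        raise ValueError(
            f"{what} (center {np.round(np.asarray(center), 1).tolist()} mm, "
            f"radius {radius} mm) extends outside the grid "
            f"(extent {cfg.physical_extent_mm.tolist()} mm)"
        )


def _grid_points(cfg: PhantomConfig) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(cfg.grid_shape, cfg.spacing_mm)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack(mesh, axis=-1)


def generate_case(config: PhantomConfig) -> PhantomCase:
    """Generate one paired-session phantom case with exact ground truth.

    The recurrence images are the baseline scene pulled through the inverse
    session motion (rigid + sinusoidal deformation), with the baseline
    lesion replaced by the recurrence lesion and independent Gaussian noise
    added per session.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng_anatomy = np.random.default_rng(ss[0])
    rng_noise = np.random.default_rng(ss[1])

    scene = _Scene(cfg, rng_anatomy)
    lc = np.asarray(cfg.lesion_center_mm, dtype=float)
    _check_inside(cfg, lc, cfg.lesion_radius_mm, "baseline lesion")

    pts = _grid_points(cfg)  # (nx, ny, nz, 3) baseline physical coords
    spacing = np.asarray(cfg.spacing_mm)
    origin = np.zeros(3)

    pet_a_data = scene.pet(
        pts,
        lesion_center=lc,
        rim_radius=cfg.lesion_radius_mm,
        core_radius=cfg.hotspot_radius_mm,
        suv_rim=cfg.suv_rim,
        suv_core=cfg.suv_core,
    )
    ct_a_data = scene.ct(pts, lesion_center=lc, rim_radius=cfg.lesion_radius_mm)

    # Session motion: forward map M (baseline -> recurrence) has rigid part
    # M_rig; image synthesis needs the inverse map G (recurrence -> baseline)
    # which we define analytically as G(p) = M_rig^-1(p) + D(p).
    m_rig = cfg.forward_rigid()
    g_rigid = m_rig.inverse()
    disp = _sinusoid_field(cfg, rng_anatomy)

    def g_map(p: np.ndarray) -> np.ndarray:
        return g_rigid.apply(p) + disp(p)

    # Forward-map a baseline point into recurrence space by inverting G
    # (fixed-point iteration; D is a contraction at the amplitudes allowed).
    def forward_point(q: np.ndarray) -> np.ndarray:
        p = m_rig.apply(q)
        R = m_rig.matrix
        for _ in range(40):
            err = g_map(p) - q
            p = p - err @ R.T
            if np.max(np.abs(err)) < 1e-10:
                break
        return p

    # Recurrence lesion: centered at the forward-mapped baseline hotspot
    # centroid plus the configured biological offset, in recurrence coords.
    rec_center = forward_point(lc) + np.asarray(cfg.recurrence_offset_mm, dtype=float)
    _check_inside(cfg, rec_center, cfg.recurrence_radius_mm, "recurrence lesion")
    rec_rim_suv = cfg.recurrence_suv_rim if cfg.recurrence_suv_rim is not None else cfg.suv_rim
    rec_core_suv = cfg.recurrence_suv_core if cfg.recurrence_suv_core is not None else cfg.suv_core
    rec_core_radius = cfg.hotspot_radius_mm * cfg.recurrence_radius_mm / cfg.lesion_radius_mm

    q_back = g_map(pts)  # baseline coords sampled by each recurrence voxel
    pet_r_data = scene.pet(q_back)  # lesion-free anatomy
    rec_rim = scene._in_sphere(pts, rec_center, cfg.recurrence_radius_mm)
    rec_core = scene._in_sphere(pts, rec_center, rec_core_radius)
    pet_r_data = np.where(rec_rim, rec_rim_suv, pet_r_data)
    pet_r_data = np.where(rec_core, rec_core_suv, pet_r_data)
    ct_r_data = scene.ct(q_back)
    # the recurrence lesion's internal texture rides along with the deformed
    # anatomy (texture sampled at the pulled-back coordinates)
    ct_r_data = np.where(rec_rim, _HU_LESION + scene._texture(q_back), ct_r_data)

    if cfg.noise_sd > 0:
        pet_a_data = pet_a_data + rng_noise.normal(0, cfg.noise_sd, pet_a_data.shape)
        pet_r_data = pet_r_data + rng_noise.normal(0, cfg.noise_sd, pet_r_data.shape)
    if cfg.ct_noise_hu > 0:
        ct_a_data = ct_a_data + rng_noise.normal(0, cfg.ct_noise_hu, ct_a_data.shape)
        ct_r_data = ct_r_data + rng_noise.normal(0, cfg.ct_noise_hu, ct_r_data.shape)
    pet_a_data = np.clip(pet_a_data, 0, None)
    pet_r_data = np.clip(pet_r_data, 0, None)

    def vol(data, modality):
        return ScalarVolume(data=data, spacing=spacing, origin=origin, modality=modality)

    # Ground-truth masks, rasterized by center-of-voxel inclusion.
    lesion_a = scene._in_sphere(pts, lc, cfg.lesion_radius_mm)
    lesion_r = rec_rim

    # Ground-truth resampling map (baseline -> recurrence): rigid part plus
    # the non-rigid residual of G^-1, sampled on the baseline grid.
    if cfg.deformation_amplitude_mm > 0:
        flat = pts.reshape(-1, 3)
        p = m_rig.apply(flat)
        R = m_rig.matrix
        for _ in range(60):
            err = g_map(p) - flat
            p = p - err @ R.T
            if np.max(np.abs(err)) < 1e-9:
                break
        residual = (p - m_rig.apply(flat)).reshape(cfg.grid_shape + (3,))
    else:
        residual = np.zeros(cfg.grid_shape + (3,))

    true_deformation = DeformationField(
        displacement=residual,
        spacing=spacing,
        origin=origin,
        control_spacing_mm=cfg.deformation_wavelength_mm,
        init=m_rig,
    )

    return PhantomCase(
        pet_a=vol(pet_a_data, "PET"),
        ct_a=vol(ct_a_data, "CT"),
        pet_r=vol(pet_r_data, "PET"),
        ct_r=vol(ct_r_data, "CT"),
        true_rigid=m_rig,
        true_deformation=true_deformation,
        true_lesion_a=VoiMask(lesion_a, spacing, origin, label="true_lesion_a"),
        true_lesion_r=VoiMask(lesion_r, spacing, origin, label="true_lesion_r"),
        position_group=cfg.position_group,
        case_id=cfg.case_id,
        config=cfg,
    )


def generate_baseline_session(config: PhantomConfig):
    """Baseline PET/CT only (no registration targets); used for uptake
    cohorts where only PET_A metrics are needed."""
    case = generate_case(replace(config, rigid_error=(0, 0, 0, 0, 0, 0),
                                 deformation_amplitude_mm=0.0))
    return case.pet_a, case.ct_a, case.true_lesion_a


# ----------------------------------------------------------------------
# Cohort sampling


def _sample_case_config(study, group: str, case_idx: int, seed: int) -> PhantomConfig:
    """Draw one case's geometry and motion from the study's group ranges."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    r = study.ranges

    lesion_radius = rng.uniform(*r.lesion_radius_mm)
    hotspot_radius = lesion_radius * rng.uniform(*r.hotspot_fraction)
    suv_rim = rng.uniform(*r.suv_rim)
    suv_core = suv_rim * rng.uniform(*r.core_rim_ratio)
    rec_radius = rng.uniform(*r.recurrence_radius_mm)
    offset_dir = rng.normal(size=3)
    offset_dir /= np.linalg.norm(offset_dir)
    offset = offset_dir * rng.uniform(*r.recurrence_offset_mm)
    center_jitter = rng.uniform(-r.center_jitter_mm, r.center_jitter_mm, size=3)

    if group == "TP":
        rot = rng.uniform(-r.tp_max_rot_deg, r.tp_max_rot_deg, size=3)
        trans = rng.uniform(-r.tp_max_trans_mm, r.tp_max_trans_mm, size=3)
        deform_amp = 0.0
    else:
        # NTP: one dominant axis each for rotation and translation, in the
        # configured large-error band, small errors on the other axes.
        rot = rng.uniform(-2.0, 2.0, size=3)
        trans = rng.uniform(-2.0, 2.0, size=3)
        rot[rng.integers(3)] = rng.choice([-1, 1]) * rng.uniform(*r.ntp_rot_deg)
        trans[rng.integers(3)] = rng.choice([-1, 1]) * rng.uniform(*r.ntp_trans_mm)
        deform_amp = rng.uniform(*r.ntp_deformation_amplitude_mm)

    base = PhantomConfig()
    # nominal lesion position: slightly off-center, scaled to this grid
    extent = (np.asarray(study.grid_shape) - 1) * np.asarray(study.spacing_mm)
    nominal_center = extent / 2 + extent * np.array([0.07, -0.03, 0.01])
    return replace(
        base,
        grid_shape=tuple(study.grid_shape),
        spacing_mm=tuple(study.spacing_mm),
        lesion_center_mm=tuple(nominal_center + center_jitter),
        lesion_radius_mm=lesion_radius,
        hotspot_radius_mm=hotspot_radius,
        suv_rim=suv_rim,
        suv_core=suv_core,
        recurrence_offset_mm=tuple(offset),
        recurrence_radius_mm=rec_radius,
        rigid_error=tuple(rot) + tuple(trans),
        deformation_amplitude_mm=deform_amp,
        deformation_wavelength_mm=rng.uniform(*r.deformation_wavelength_mm),
        noise_sd=r.noise_sd,
        ct_noise_hu=r.ct_noise_hu,
        position_group=group,
        seed=seed,
        case_id=f"{group.lower()}_{case_idx:03d}",
    )


def generate_cohort(study) -> list[PhantomCase]:
    """Generate the study cohort (default: 15 TP + 28 NTP relapse cases).

    Per-case seeds are spawned deterministically from the study seed, so the
    case_id -> seed mapping (and every volume) is a pure function of the
    study configuration.
    """
    if study.n_tp + study.n_ntp < 1:
        raise ValueError("cohort must contain at least one case")
    groups = ["TP"] * study.n_tp + ["NTP"] * study.n_ntp
    children = np.random.SeedSequence(study.seed).spawn(len(groups))
    cases = []
    for idx, (group, child) in enumerate(zip(groups, children)):
        case_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = _sample_case_config(study, group, idx, case_seed)
        cases.append(generate_case(cfg))
    return cases
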