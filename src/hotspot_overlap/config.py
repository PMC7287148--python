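"""Study-level configuration: thresholds, methods, cohort sizes, phantom ranges."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhantomRanges:
    """Per-case sampling ranges for the synthetic cohort.

    The TP/NTP bands encode the positioning contrast the study design
    hinges on: TP cases are immobilized (sub-2 mm/degree repositioning
    error, no tissue deformation) while NTP cases combine a 5-8 mm / 5-8
    degree dominant-axis rigid error with a 3-6 mm smooth deformation
    standing in for weight loss and post-therapeutic tissue distortion.
    """

    lesion_radius_mm: tuple[float, float] = (8.0, 14.0)
    hotspot_fraction: tuple[float, float] = (0.35, 0.55)
    suv_rim: tuple[float, float] = (6.0, 10.0)
    core_rim_ratio: tuple[float, float] = (2.2, 2.8)
    recurrence_radius_mm: tuple[float, float] = (5.0, 9.0)
    recurrence_offset_mm: tuple[float, float] = (2.0, 6.0)
    center_jitter_mm: float = 4.0
    tp_max_rot_deg: float = 1.5
    tp_max_trans_mm: float = 1.5
    ntp_rot_deg: tuple[float, float] = (5.0, 8.0)
    ntp_trans_mm: tuple[float, float] = (5.0, 8.0)
    ntp_deformation_amplitude_mm: tuple[float, float] = (3.0, 6.0)
    deformation_wavelength_mm: tuple[float, float] = (60.0, 100.0)
    noise_sd: float = 0.3
    ct_noise_hu: float = 3.0


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full overlap study run.

    Thresholds are percentages of SUVmax (labels ``A_30`` ... ``A_90``,
    ``R_40``, ``R_70`` follow from them); the default cohort mirrors the
    clinical local-relapse group: 15 treatment-position and 28
    non-treatment-position cases.
    """

    baseline_thresholds: tuple[int, ...] = (30, 40, 50, 60, 70, 80, 90)
    recurrence_thresholds: tuple[int, ...] = (40, 70)
    methods: tuple[str, ...] = ("RR", "ER")
    n_tp: int = 15
    n_ntp: int = 28
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    ranges: PhantomRanges = field(default_factory=PhantomRanges)

    def __post_init__(self) -> None:
        for name in ("baseline_thresholds", "recurrence_thresholds"):
            ts = getattr(self, name)
            if not ts:
                raise ValueError(f"{name} must be non-empty")
            if any(not (0 < t < 100) for t in ts):
                raise ValueError(f"{name} must lie strictly inside (0, 100): {ts}")
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError(f"{name} must be strictly increasing: {ts}")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        if any(m not in ("RR", "ER") for m in self.methods):
            raise ValueError(f"methods must be drawn from {{'RR', 'ER'}}: {self.methods}")
        if self.n_tp < 0 or self.n_ntp < 0:
            raise ValueError("cohort counts must be >= 0")

    @property
    def n_cases(self) -> int:
        return self.n_tp + self.n_ntp

    @property
    def baseline_labels(self) -> tuple[str, ...]:
        return tuple(f"A_{t}" for t in self.baseline_thresholds)

    @property
    def recurrence_labels(self) -> tuple[str, ...]:
        return tuple(f"R_{t}" for t in self.recurrence_thresholds)
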