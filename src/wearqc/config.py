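"""Quality-assessment configuration.

Every numeric threshold of the on-body and signal-quality procedures lives
here so a run is fully described by one serialized object.  The defaults are
the published operating point of the method; all of them can be overridden
from a YAML/JSON config file or CLI flags.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from enum import Enum

from .model import ValidationError


class CombinePolicy(str, Enum):
    """How per-modality on-body votes are merged into one wear status."""

    ANY = "any"        # on iff at least one modality votes on (default)
    MAJORITY = "majority"
    ALL = "all"


@dataclass
class QualityConfig:
    """Thresholds and window lengths for on-body detection and signal quality.

    Attributes
    ----------
    acc_std_threshold_g
        Activity level (10-s moving std of the ACC axis sum, in g) at or
        above which an ACC sample counts as on-body movement.
    acc_std_window_s
        Length of the moving-std window for the ACC activity level.
    eda_onbody_min_uS
        EDA amplitude below which electrodes are assumed off-skin.
    temp_min_C, temp_max_C
        Plausible skin-temperature band while worn (inclusive).
    window_min_fraction
        Minimum fraction of in-range samples for a 1-min window to count
        as on-body (the 1% rule).
    combine_policy
        How the three modality votes combine into a single wear status.
    rac_window_s
        Rate-of-amplitude-change window length for EDA/TEMP quality.
    rac_threshold
        RAC at or above which a window is bad quality (>20% swing in 2 s).
    bvp_entropy_window_s
        Spectral-entropy window length for BVP quality.
    bvp_entropy_overlap
        Fractional overlap of consecutive entropy windows.
    bvp_spectrum_avg
        Number of consecutive overlapped windows whose periodograms are
        averaged (Welch-style) before the entropy; must be odd.  A single
        periodogram biases the entropy of broadband noise well below the
        theoretical endpoint 1 with the few bins the band leaves.
    bvp_band_hz
        Frequency band retained for the entropy (pulse fundamentals and
        harmonics live here).
    bvp_entropy_threshold
        Normalized entropy strictly above which BVP is poor quality.
    minute_s
        Scoring window: quality flags average to one score per minute.
    day_start_h, day_end_h
        Local wall-clock hours delimiting daytime, half-open
        ``[day_start, day_end)``.
    """

    acc_std_threshold_g: float = 0.2
    acc_std_window_s: float = 10.0
    eda_onbody_min_uS: float = 0.05
    temp_min_C: float = 25.0
    temp_max_C: float = 40.0
    window_min_fraction: float = 0.01
    combine_policy: CombinePolicy = CombinePolicy.ANY
    rac_window_s: float = 2.0
    rac_threshold: float = 0.2
    bvp_entropy_window_s: float = 4.0
    bvp_entropy_overlap: float = 0.5
    bvp_spectrum_avg: int = 3
    bvp_band_hz: tuple[float, float] = (0.1, 5.0)
    bvp_entropy_threshold: float = 0.8
    minute_s: float = 60.0
    day_start_h: float = 8.0
    day_end_h: float = 20.0

    def __post_init__(self) -> None:
        self.combine_policy = CombinePolicy(self.combine_policy)
        self.bvp_band_hz = (float(self.bvp_band_hz[0]), float(self.bvp_band_hz[1]))
        positive = (
            "acc_std_threshold_g", "acc_std_window_s", "eda_onbody_min_uS",
            "temp_min_C", "temp_max_C", "window_min_fraction", "rac_window_s",
            "rac_threshold", "bvp_entropy_window_s", "bvp_entropy_threshold",
            "minute_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.temp_min_C >= self.temp_max_C:
            raise ValidationError("temp_min_C must be < temp_max_C")
        if not (0 <= self.bvp_entropy_overlap < 1):
            raise ValidationError("bvp_entropy_overlap must be in [0, 1)")
        if self.bvp_spectrum_avg < 1 or self.bvp_spectrum_avg % 2 == 0:
            raise ValidationError("bvp_spectrum_avg must be a positive odd integer")
        if self.bvp_band_hz[0] >= self.bvp_band_hz[1]:
            raise ValidationError("bvp_band_hz must be (low, high) with low < high")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["combine_policy"] = self.combine_policy.value
        d["bvp_band_hz"] = list(self.bvp_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "QualityConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "QualityConfig":
        d = self.to_dict()
        d.update(kwargs)
        return QualityConfig.from_dict(d)
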