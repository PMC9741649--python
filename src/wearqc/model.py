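"""Core data model for multimodal wrist-wearable recordings.

A recording session from a wrist-worn biosensor (Empatica-E4-style) carries
four raw modalities — tri-axial accelerometry (ACC), electrodermal activity
(EDA), blood volume pulse (BVP, raw photoplethysmography) and peripheral
skin temperature (TEMP) — each sampled at its own nominal rate.  Data loss
is structural here: a modality is stored as an ordered list of contiguous
:class:`Segment` objects, and any time between segments simply has no
samples.  Data completeness is defined by the presence and absence of
samples, so absence is represented by absent samples rather than NaN
padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "Modality",
    "Placement",
    "RecordingMode",
    "Status",
    "NOMINAL_RATE_HZ",
    "UNITS",
    "Segment",
    "ModalitySeries",
    "Recording",
    "OnBodyMask",
    "SampleQuality",
    "MinuteScores",
    "CompletenessResult",
    "RecordingSummary",
    "MetricStats",
    "CohortSummary",
    "GroupComparison",
    "minute_grid",
]


class ValidationError(ValueError):
    """An object violates a model invariant (overlapping segments, empty data, ...)."""


class FormatError(ValueError):
    """An input file does not conform to the expected on-disk dialect."""


class Modality(str, Enum):
    ACC = "ACC"
    EDA = "EDA"
    BVP = "BVP"
    TEMP = "TEMP"


class Placement(str, Enum):
    WRIST = "wrist"
    ANKLE = "ankle"
    UNKNOWN = "unknown"


class RecordingMode(str, Enum):
    DEVICE = "device"
    STREAMING = "streaming"
    UNKNOWN = "unknown"


class Status(IntEnum):
    """Tri-state wear status of one 1-minute window."""

    NO_DATA = -1
    OFF = 0
    ON = 1


#: Nominal sample rates of the device, Hz.
NOMINAL_RATE_HZ = {
    Modality.ACC: 32.0,
    Modality.EDA: 4.0,
    Modality.BVP: 64.0,
    Modality.TEMP: 4.0,
}

#: Physical units of the stored sample values.
UNITS = {
    Modality.ACC: "g",
    Modality.EDA: "uS",
    Modality.BVP: "a.u.",
    Modality.TEMP: "degC",
}

#: Accelerometer full-scale range in g.
ACC_RANGE_G = 2.0


@dataclass
class Segment:
    """A contiguous run of recorded samples.

    Parameters
    ----------
    start_time
        UTC time of the first sample, seconds since the epoch.
    values
        Sample values, shape ``(n,)`` for scalar modalities or ``(n, 3)``
        for ACC (in g).
    """

    start_time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValidationError("segment has no samples")
        if self.values.ndim not in (1, 2):
            raise ValidationError("segment values must be 1-D or 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("segment contains non-finite values")
        self.start_time = float(self.start_time)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def end_time(self, sample_rate: float) -> float:
        """UTC time of the last sample in this segment."""
        return self.start_time + (self.n - 1) / sample_rate

    def times(self, sample_rate: float) -> np.ndarray:
        return self.start_time + np.arange(self.n) / sample_rate


@dataclass
class ModalitySeries:
    """All samples of one modality: an ordered, non-overlapping segment list."""

    modality: Modality
    sample_rate: float
    segments: list[Segment]

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.sample_rate = float(self.sample_rate)
        if self.sample_rate <= 0:
            raise ValidationError(f"{self.modality.value}: sample_rate must be > 0")
        if not self.segments:
            raise ValidationError(f"{self.modality.value}: series has no segments")
        self.segments = sorted(self.segments, key=lambda s: s.start_time)
        for a, b in zip(self.segments, self.segments[1:]):
            # next segment must start strictly after the last sample of the previous
            if b.start_time <= a.end_time(self.sample_rate):
                raise ValidationError(
                    f"{self.modality.value}: overlapping segments at t={b.start_time}"
                )
        expect_cols = 2 if self.modality is Modality.ACC else 1
        for seg in self.segments:
            if seg.values.ndim != expect_cols:
                raise ValidationError(
                    f"{self.modality.value}: expected "
                    f"{'3-axis' if expect_cols == 2 else 'scalar'} samples"
                )
            if self.modality is Modality.ACC and seg.values.shape[1] != 3:
                raise ValidationError("ACC samples must be 3-vectors")

    @property
    def n_rec(self) -> int:
        """Total number of recorded samples."""
        return sum(seg.n for seg in self.segments)

    @property
    def t_start(self) -> float:
        return self.segments[0].start_time

    @property
    def t_end(self) -> float:
        """Time of the last recorded sample."""
        return self.segments[-1].end_time(self.sample_rate)

    @property
    def duration_s(self) -> float:
        """Recorded duration N_rec / F_s, seconds."""
        return self.n_rec / self.sample_rate

    def sample_times(self) -> np.ndarray:
        return np.concatenate([seg.times(self.sample_rate) for seg in self.segments])

    def sample_values(self) -> np.ndarray:
        return np.concatenate([seg.values for seg in self.segments])


@dataclass
class Recording:
    """One wearable session: metadata plus per-modality series."""

    recording_id: str = "recording"
    placement: Placement = Placement.UNKNOWN
    mode: RecordingMode = RecordingMode.UNKNOWN
    utc_offset: float = 0.0  # signed hours, local = UTC + offset
    site: str = ""
    series: dict[Modality, ModalitySeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.placement = Placement(self.placement)
        self.mode = RecordingMode(self.mode)
        if not self.series:
            raise ValidationError("recording has no modalities")
        self.series = {Modality(k): v for k, v in self.series.items()}
        for mod, ser in self.series.items():
            if ser.modality is not mod:
                raise ValidationError(f"series keyed {mod.value} holds {ser.modality.value}")

    @property
    def t_start(self) -> float:
        return min(s.t_start for s in self.series.values())

    @property
    def t_end(self) -> float:
        return max(s.t_end for s in self.series.values())

    @property
    def span_s(self) -> float:
        return self.t_end - self.t_start


def minute_grid(t_start: float, t_end: float, window_s: float = 60.0) -> np.ndarray:
    """Wall-clock-aligned window start times covering ``[t_start, t_end]``.

    Windows are aligned to multiples of ``window_s`` (UTC) so that on-body
    windows, minute scores and the day/night grid all coincide.
    """
    first = np.floor(t_start / window_s) * window_s
    last = np.floor(t_end / window_s) * window_s
    n = int(round((last - first) / window_s)) + 1
    return first + window_s * np.arange(n)


@dataclass
class OnBodyMask:
    """Per-1-minute tri-state wear status, per modality and combined."""

    window_starts: np.ndarray
    per_modality: dict[Modality, np.ndarray]
    combined: np.ndarray
    window_s: float = 60.0

    @property
    def onbody_fraction(self) -> float:
        """Fraction of scoreable (non-``no_data``) windows marked on."""
        scoreable = self.combined != Status.NO_DATA
        if not scoreable.any():
            return float("nan")
        return float(np.mean(self.combined[scoreable] == Status.ON))


@dataclass
class SampleQuality:
    """Per-sample binary quality flags aligned to a :class:`ModalitySeries`."""

    modality: Modality
    flags: list[np.ndarray]  # one boolean array per segment

    def all_flags(self) -> np.ndarray:
        return np.concatenate(self.flags)


@dataclass
class MinuteScores:
    """Per-minute quality scores in [0, 1]; NaN where undefined.

    Scores exist only for minutes the on-body mask marks as worn; off-body
    and no-data minutes are NaN for every modality.
    """

    window_starts: np.ndarray
    scores: dict[Modality, np.ndarray]
    window_s: float = 60.0

    def mean_score(self, modality: Modality) -> float:
        s = self.scores[modality]
        if np.all(np.isnan(s)):
            return float("nan")
        return float(np.nanmean(s))


@dataclass
class CompletenessResult:
    per_modality_ratio: dict[Modality, float]
    completeness: float
    duration_s: float
    span_s: float


@dataclass
class RecordingSummary:
    """Recording-level metric row: percentages plus duration and metadata."""

    recording_id: str
    completeness_pct: float
    onbody_pct: float
    eda_pct: float  # NaN when no scoreable minutes
    bvp_pct: float
    temp_pct: float
    duration_s: float
    placement: Placement = Placement.UNKNOWN
    mode: RecordingMode = RecordingMode.UNKNOWN
    site: str = ""


@dataclass
class MetricStats:
    mean: float
    median: float
    std: float
    min: float
    max: float
    n: int


@dataclass
class CohortSummary:
    """Cohort-level aggregate: mean/median/std/min/max per metric."""

    metrics: dict[str, MetricStats]
    n_recordings: int
    n_patients: int
    total_duration_s: float


@dataclass
class GroupComparison:
    """Two-tailed two-sample t-test result."""

    t_value: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
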