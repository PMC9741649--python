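"""Seeded synthetic multimodal recordings with ground-truth annotations.

The generator emulates the signal structure the quality metrics assume —
quasi-periodic BVP (a few harmonics of the beat frequency with mild
beat-to-beat variability), tonic-plus-phasic EDA, slowly drifting skin
temperature, and gravity-plus-bout accelerometry — at the device's nominal
rates, and injects artifacts with known extents:

``off_body``
    EDA drops to 0 (electrodes off skin), TEMP relaxes exponentially
    toward ambient, BVP becomes broadband noise, ACC freezes.
``gap``
    Samples are deleted outright: recording gaps are structural (segment
    splits), never NaN fills.
``motion`` / ``light`` / ``translation_rotation``
    Broadband (and, for the rhythmic kinds, periodic) components are
    superimposed on BVP, plus ACC bursts and EDA fluctuations for the
    motion kinds.

Identical seeds produce bit-identical recordings; every random draw flows
from one :func:`numpy.random.default_rng` generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .e4_io import write_session
from .model import (
    Modality,
    ModalitySeries,
    NOMINAL_RATE_HZ,
    Placement,
    Recording,
    RecordingMode,
    Segment,
    ValidationError,
)

ARTIFACT_KINDS = ("off_body", "gap", "motion", "light", "translation_rotation")

#: A UTC midnight on a minute boundary; diurnal fixtures start here so the
#: local day/night grid lines up with the recording start.
DEFAULT_START_UTC = 1_600_041_600.0  # 2020-09-14 00:00:00 UTC


@dataclass
class ArtifactInterval:
    """One artifact stretch, in seconds relative to the recording start."""

    start: float
    end: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValidationError(f"unknown artifact kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"malformed interval [{self.start}, {self.end})")


@dataclass
class SimulationSpec:
    """Conditions for one synthetic session.

    Defaults are a resting adult wearer: 72 bpm pulse, 2 μS tonic skin
    conductance with a couple of phasic responses per minute, 33 °C wrist
    temperature drifting by ±0.5 °C, occasional movement bouts, 22 °C
    ambient for off-body stretches.
    """

    duration_s: float = 3600.0
    seed: int = 0
    start_time: float = DEFAULT_START_UTC
    utc_offset: float = 0.0
    heart_rate_bpm: float = 72.0
    bvp_amplitude: float = 40.0
    bvp_noise: float = 0.5
    eda_tonic_uS: float = 2.0
    eda_phasic_rate_per_min: float = 2.0
    temp_base_C: float = 33.0
    temp_drift_C: float = 0.5
    ambient_temp_C: float = 22.0
    activity_bouts_per_h: float = 6.0
    artifacts: list[ArtifactInterval] = field(default_factory=list)
    recording_id: str = "synthetic"
    placement: str = "wrist"
    mode: str = "device"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        for a in self.artifacts:
            if a.end > self.duration_s + 1e-9:
                raise ValidationError(
                    f"artifact [{a.start}, {a.end}) exceeds duration {self.duration_s}"
                )
        if self.eda_phasic_rate_per_min < 0 or self.activity_bouts_per_h < 0:
            raise ValidationError("rates must be non-negative")

    def intervals(self, kind: str) -> list[tuple[float, float]]:
        return [(a.start, a.end) for a in self.artifacts if a.kind == kind]


@dataclass
class GroundTruth:
    """What was injected where, for use as a test oracle (UTC seconds)."""

    off_body: list[tuple[float, float]]
    gaps: list[tuple[float, float]]
    artifacts: dict[str, list[tuple[float, float]]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "off_body": self.off_body,
                "gaps": self.gaps,
                "artifacts": self.artifacts,
            },
            indent=1,
        )


def _interval_mask(t: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(t), dtype=bool)
    for s, e in intervals:
        mask |= (t >= s) & (t < e)
    return mask


def _clean_bvp(t: np.ndarray, rng: np.random.Generator, spec: SimulationSpec,
               fs: float) -> np.ndarray:
    # slow sinusoidal HRV plus a touch of phase noise keeps the spectrum
    # concentrated on the beat harmonics without being a perfect tone
    f0 = spec.heart_rate_bpm / 60.0
    freq = f0 * (1.0 + 0.02 * np.sin(2 * np.pi * t / 73.0 + rng.uniform(0, 2 * np.pi)))
    phase = 2 * np.pi * np.cumsum(freq) / fs
    a = spec.bvp_amplitude
    x = a * (np.sin(phase)
             + 0.4 * np.sin(2 * phase + 0.7)
             + 0.15 * np.sin(3 * phase + 1.9))
    return x + rng.normal(0.0, spec.bvp_noise, len(t))


def _clean_eda(t: np.ndarray, rng: np.random.Generator, spec: SimulationSpec,
               fs: float) -> np.ndarray:
    tonic = spec.eda_tonic_uS * (
        1.0 + 0.05 * np.sin(2 * np.pi * t / 1800.0 + rng.uniform(0, 2 * np.pi))
    )
    x = tonic + rng.normal(0.0, 0.003, len(t))
    n_events = rng.poisson(spec.eda_phasic_rate_per_min * spec.duration_s / 60.0)
    onsets = np.sort(rng.uniform(0.0, spec.duration_s, n_events))
    amps = rng.uniform(0.05, 0.25, n_events)
    # phasic response: ~0.75 s rise, ~4 s exponential recovery
    k_t = np.arange(0.0, 12.0, 1.0 / fs)
    kernel = (1.0 - np.exp(-k_t / 0.75)) * np.exp(-k_t / 4.0)
    kernel /= kernel.max()
    for onset, amp in zip(onsets, amps):
        i0 = int(np.round(onset * fs))
        if i0 >= len(x):
            continue
        m = min(len(kernel), len(x) - i0)
        x[i0:i0 + m] += amp * kernel[:m]
    return np.clip(x, 0.0, None)


def _clean_temp(t: np.ndarray, rng: np.random.Generator, spec: SimulationSpec) -> np.ndarray:
    drift = spec.temp_drift_C * np.sin(2 * np.pi * t / 7200.0 + rng.uniform(0, 2 * np.pi))
    return spec.temp_base_C + drift + rng.normal(0.0, 0.01, len(t))


def _bout_intervals(rng: np.random.Generator, spec: SimulationSpec) -> list[tuple[float, float]]:
    n = rng.poisson(spec.activity_bouts_per_h * spec.duration_s / 3600.0)
    starts = np.sort(rng.uniform(0.0, spec.duration_s, n))
    durs = rng.uniform(60.0, 180.0, n)
    return [(float(s), float(min(s + d, spec.duration_s))) for s, d in zip(starts, durs)]


def _clean_acc(t: np.ndarray, rng: np.random.Generator, spec: SimulationSpec,
               bouts: list[tuple[float, float]]) -> np.ndarray:
    n = len(t)
    gravity = np.array([0.05, -0.02, 1.0])
    acc = gravity + rng.normal(0.0, 0.01, (n, 3))
    bout_mask = _interval_mask(t, bouts)
    acc[bout_mask] += rng.normal(0.0, 0.3, (int(bout_mask.sum()), 3))
    return acc


def _apply_offbody_temp(temp: np.ndarray, t: np.ndarray, spec: SimulationSpec,
                        tau_off: float = 60.0, tau_on: float = 300.0) -> np.ndarray:
    """Exponential relaxation toward ambient during off-body stretches.

    Skin-temperature sensors lag: cooling toward ambient uses a 60-s time
    constant, and re-warming toward the clean trace a slower 300-s one.
    An off stretch that begins at t=0 starts at ambient (never donned).
    """
    out = temp.copy()
    intervals = sorted(spec.intervals("off_body"))
    for i, (s, e) in enumerate(intervals):
        off = (t >= s) & (t < e)
        if not off.any():
            continue
        i0 = np.argmax(off)
        t0 = t[off][0]
        start_val = spec.ambient_temp_C if i0 == 0 else out[i0 - 1]
        out[off] = spec.ambient_temp_C + (start_val - spec.ambient_temp_C) * np.exp(
            -(t[off] - t0) / tau_off
        )
        next_start = intervals[i + 1][0] if i + 1 < len(intervals) else np.inf
        rec = (t >= e) & (t < next_start)
        if rec.any():
            last_val = out[off][-1]
            dt = t[rec] - e
            out[rec] = temp[rec] + (last_val - temp[rec][0]) * np.exp(-dt / tau_on)
    return out


def _segments_from(values: np.ndarray, t: np.ndarray, keep: np.ndarray,
                   start_time: float, fs: float) -> list[Segment]:
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValidationError("gap intervals delete an entire modality")
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    segs = []
    for chunk in np.split(idx, breaks):
        segs.append(Segment(start_time=start_time + chunk[0] / fs, values=values[chunk]))
    return segs


def simulate_recording(spec: SimulationSpec) -> tuple[Recording, GroundTruth]:
    """Generate one annotated synthetic session.

    Returns the :class:`Recording` plus a :class:`GroundTruth` with the
    injected off-body, gap and artifact intervals in absolute UTC seconds.
    """
    rng = np.random.default_rng(spec.seed)
    off = spec.intervals("off_body")
    gaps = spec.intervals("gap")
    motion = spec.intervals("motion")
    light = spec.intervals("light")
    rot = spec.intervals("translation_rotation")

    series: dict[Modality, ModalitySeries] = {}
    bouts = _bout_intervals(rng, spec)

    for mod in (Modality.ACC, Modality.EDA, Modality.BVP, Modality.TEMP):
        fs = NOMINAL_RATE_HZ[mod]
        t = np.arange(int(round(spec.duration_s * fs))) / fs
        if mod is Modality.BVP:
            x = _clean_bvp(t, rng, spec, fs)
            a = spec.bvp_amplitude
            for s, e in motion:
                m = (t >= s) & (t < e)
                x[m] += rng.normal(0.0, 3.0 * a, int(m.sum()))
            for s, e in light:
                m = (t >= s) & (t < e)
                x[m] += rng.normal(0.0, 3.0 * a, int(m.sum())) + 2.0 * a * np.sin(
                    2 * np.pi * 0.05 * t[m]
                )
            for s, e in rot:
                m = (t >= s) & (t < e)
                x[m] += 2.0 * a * np.sin(2 * np.pi * 1.3 * t[m]) + rng.normal(
                    0.0, 1.5 * a, int(m.sum())
                )
            m = _interval_mask(t, off)
            x[m] = rng.normal(0.0, 0.5 * a, int(m.sum()))
        elif mod is Modality.EDA:
            x = _clean_eda(t, rng, spec, fs)
            for s, e in motion + rot:
                m = (t >= s) & (t < e)
                x[m] = np.clip(x[m] + rng.normal(0.0, 0.5, int(m.sum())), 0.0, None)
            x[_interval_mask(t, off)] = 0.0
        elif mod is Modality.TEMP:
            x = _clean_temp(t, rng, spec)
            x = _apply_offbody_temp(x, t, spec)
        else:  # ACC
            x = _clean_acc(t, rng, spec, bouts)
            for s, e in motion + rot:
                m = (t >= s) & (t < e)
                x[m] += rng.normal(0.0, 0.5, (int(m.sum()), 3))
            m = _interval_mask(t, off)
            x[m] = np.array([0.05, -0.02, 1.0])  # frozen on the table
            x = np.clip(x, -2.0, 2.0)
        keep = ~_interval_mask(t, gaps)
        series[mod] = ModalitySeries(
            modality=mod,
            sample_rate=fs,
            segments=_segments_from(x, t, keep, spec.start_time, fs),
        )

    rec = Recording(
        recording_id=spec.recording_id,
        placement=Placement(spec.placement),
        mode=RecordingMode(spec.mode),
        utc_offset=spec.utc_offset,
        series=series,
    )
    t0 = spec.start_time
    truth = GroundTruth(
        off_body=[(t0 + s, t0 + e) for s, e in off],
        gaps=[(t0 + s, t0 + e) for s, e in gaps],
        artifacts={
            kind: [(t0 + s, t0 + e) for s, e in spec.intervals(kind)]
            for kind in ("motion", "light", "translation_rotation")
        },
    )
    return rec, truth


def diurnal_spec(seed: int = 0, hours: float = 24.0, utc_offset: float = 0.0,
                 motion_min_per_burst: float = 5.0, bursts_per_hour: int = 2,
                 recording_id: str = "diurnal") -> SimulationSpec:
    """A day/night fixture: motion bursts only during local daytime.

    The session starts at local midnight and injects ``bursts_per_hour``
    motion bursts into every daytime hour (local 08:00–20:00), emulating
    the movement-driven quality loss of waking hours; nights stay clean.
    """
    artifacts = []
    for h in range(int(hours)):
        local_h = h % 24.0  # the session starts at local midnight
        if not (8.0 <= local_h < 20.0):
            continue
        for b in range(bursts_per_hour):
            start = h * 3600.0 + 300.0 + b * (3600.0 / bursts_per_hour)
            artifacts.append(
                ArtifactInterval(start, start + motion_min_per_burst * 60.0, "motion")
            )
    return SimulationSpec(
        duration_s=hours * 3600.0,
        seed=seed,
        start_time=DEFAULT_START_UTC - utc_offset * 3600.0,  # local midnight
        utc_offset=utc_offset,
        artifacts=artifacts,
        recording_id=recording_id,
    )


def write_fixture_suite(out_dir: str | Path, base_seed: int = 0,
                        session_hours: float = 1.0,
                        diurnal_hours: float = 48.0) -> dict:
    """Write the standard battery of annotated fixture sessions.

    Five sessions — clean, off-body, gappy, motion-laden, and a diurnal
    multi-day one — each in the E4 CSV dialect with its ground truth JSON
    beside it.  Returns (and writes as ``fixtures.json``) a manifest
    listing every session with its seed and artifact plan.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = session_hours * 3600.0
    specs = {
        "clean": SimulationSpec(duration_s=d, seed=base_seed, recording_id="clean"),
        "offbody": SimulationSpec(
            duration_s=d, seed=base_seed + 1, recording_id="offbody",
            artifacts=[ArtifactInterval(0.0, d / 6.0, "off_body")],
        ),
        "gappy": SimulationSpec(
            duration_s=d, seed=base_seed + 2, recording_id="gappy",
            artifacts=[
                ArtifactInterval(0.2 * d, 0.3 * d, "gap"),
                ArtifactInterval(0.6 * d, 0.7 * d, "gap"),
            ],
        ),
        "motion": SimulationSpec(
            duration_s=d, seed=base_seed + 3, recording_id="motion",
            artifacts=[
                ArtifactInterval(0.25 * d, 0.35 * d, "motion"),
                ArtifactInterval(0.55 * d, 0.60 * d, "translation_rotation"),
                ArtifactInterval(0.80 * d, 0.85 * d, "light"),
            ],
        ),
        "diurnal": diurnal_spec(seed=base_seed + 4, hours=diurnal_hours),
    }
    manifest = {"sessions": []}
    for name, spec in specs.items():
        rec, truth = simulate_recording(spec)
        session_dir = out_dir / name
        write_session(rec, session_dir)
        (session_dir / "ground_truth.json").write_text(truth.to_json() + "\n")
        manifest["sessions"].append(
            {
                "name": name,
                "path": str(session_dir),
                "seed": spec.seed,
                "duration_s": spec.duration_s,
                "artifacts": [
                    {"start": a.start, "end": a.end, "kind": a.kind}
                    for a in spec.artifacts
                ],
            }
        )
    (out_dir / "fixtures.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
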