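"""Shared builders for small in-memory recordings."""

from __future__ import annotations

import numpy as np
import pytest

from wearqc.model import Modality, ModalitySeries, Recording, Segment


def make_series(
    modality: Modality,
    values,
    sample_rate: float | None = None,
    start: float = 0.0,
) -> ModalitySeries:
    """Single-segment series; rate defaults to the device's nominal rate."""
    from wearqc.model import NOMINAL_RATE_HZ

    rate = sample_rate if sample_rate is not None else NOMINAL_RATE_HZ[modality]
    return ModalitySeries(
        modality=modality,
        sample_rate=rate,
        segments=[Segment(start_time=start, values=np.asarray(values, dtype=float))],
    )


def make_gappy_series(
    modality: Modality,
    values,
    keep: np.ndarray,
    sample_rate: float,
    start: float = 0.0,
) -> ModalitySeries:
    """Series with samples deleted wherever ``keep`` is False (segment splits)."""
    values = np.asarray(values, dtype=float)
    idx = np.flatnonzero(keep)
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    segments = [
        Segment(start_time=start + chunk[0] / sample_rate, values=values[chunk])
        for chunk in np.split(idx, breaks)
    ]
    return ModalitySeries(modality=modality, sample_rate=sample_rate, segments=segments)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_recording(rng) -> Recording:
    """Ten minutes of plausible resting data, all four modalities."""
    n_eda = 600 * 4
    eda = 2.0 + 0.05 * np.sin(np.arange(n_eda) / 600) + rng.normal(0, 0.003, n_eda)
    temp = 33.0 + rng.normal(0, 0.01, n_eda)
    n_bvp = 600 * 64
    t = np.arange(n_bvp) / 64
    bvp = 40 * np.sin(2 * np.pi * 1.2 * t) + rng.normal(0, 0.5, n_bvp)
    n_acc = 600 * 32
    acc = np.array([0.05, -0.02, 1.0]) + rng.normal(0, 0.01, (n_acc, 3))
    start = 1_600_041_600.0
    return Recording(
        recording_id="small",
        series={
            Modality.EDA: make_series(Modality.EDA, eda, start=start),
            Modality.TEMP: make_series(Modality.TEMP, temp, start=start),
            Modality.BVP: make_series(Modality.BVP, bvp, start=start),
            Modality.ACC: make_series(Modality.ACC, acc, start=start),
        },
    )
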