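"""RAC, spectral entropy, per-sample quality and minute scores."""

import numpy as np
import pytest

from wearqc import signal_quality as sq
from wearqc.config import QualityConfig
from wearqc.model import (
    MinuteScores,
    Modality,
    ModalitySeries,
    OnBodyMask,
    Recording,
    Segment,
    Status,
    ValidationError,
)

from conftest import make_series

CFG = QualityConfig()


def rac_oracle(values: np.ndarray, w: int) -> np.ndarray:
    """Brute-force per-sample RAC: max/min/first-extreme per window."""
    out = np.empty(len(values))
    for start in range(0, len(values), w):
        win = values[start:start + w]
        vmax, vmin = win.max(), win.min()
        if vmax == vmin:
            r = 0.0
        else:
            d = vmax if int(np.argmax(win)) < int(np.argmin(win)) else vmin
            r = np.inf if d == 0 else (vmax - vmin) / d
        out[start:start + w] = r
    return out


def band_power_oracle(x: np.ndarray, fs: float, band=(0.1, 5.0)) -> np.ndarray:
    """In-band power spectrum by direct-summation DFT with a Hann taper."""
    n = len(x)
    xt = x * np.hanning(n)
    k = np.arange(n // 2 + 1)
    # explicit DFT: X[k] = sum_m x[m] e^{-2 pi i k m / n}
    m = np.arange(n)
    dft = np.exp(-2j * np.pi * np.outer(k, m) / n) @ xt
    power = np.abs(dft) ** 2
    freqs = k * fs / n
    return power[(freqs >= band[0]) & (freqs <= band[1])]


def shannon_entropy_oracle(pw: np.ndarray) -> float:
    """Explicit -sum p log p over a band power mass, normalized to [0, 1]."""
    if pw.sum() == 0:
        return 1.0
    p = pw / pw.sum()
    h = 0.0
    for pi in p:
        if pi > 0:
            h -= pi * np.log(pi)
    return h / np.log(len(pw))


def entropy_windows_oracle(x: np.ndarray, fs: float, n: int = 256, hop: int = 128,
                           avg: int = 3) -> tuple[list, list]:
    """Per-window entropy oracle mirroring the documented estimator: the
    Hann periodograms of ``avg`` consecutive overlapped windows averaged
    (truncated at the edges) before the explicit entropy."""
    raw = [band_power_oracle(x[s:s + n], fs) for s in range(0, len(x) - n + 1, hop)]
    centers, ents = [], []
    half = avg // 2
    for j in range(len(raw)):
        block = raw[max(0, j - half):j + half + 1]
        ents.append(shannon_entropy_oracle(np.mean(block, axis=0)))
        centers.append(j * hop + (n - 1) / 2.0)
    return centers, ents


class TestRAC:
    def test_min_first_denominator(self):
        # 3-sample 2-s window at 1.5 Hz: [1.0, 1.3, 1.1], min at index 0
        ser = make_series(Modality.EDA, [1.0, 1.3, 1.1], sample_rate=1.5)
        (rac,) = sq.rac_values(ser)
        assert np.allclose(rac, 0.3 / 1.0)

    def test_max_first_denominator(self):
        ser = make_series(Modality.EDA, [1.3, 1.0, 1.1], sample_rate=1.5)
        (rac,) = sq.rac_values(ser)
        assert np.allclose(rac, 0.3 / 1.3)

    def test_constant_window_is_zero(self):
        ser = make_series(Modality.TEMP, np.full(8, 33.0), sample_rate=4.0)
        (rac,) = sq.rac_values(ser)
        assert np.all(rac == 0.0)

    def test_zero_denominator_is_infinite(self):
        ser = make_series(Modality.EDA, [0.0, 0.04], sample_rate=1.0)
        (rac,) = sq.rac_values(ser)
        assert np.all(np.isinf(rac))

    def test_matches_bruteforce_oracle_exactly(self, rng):
        # coarse values produce repeated extremes, exact zeros and constants
        values = np.round(rng.uniform(-0.3, 2.0, 1000), 1).clip(0, None)
        ser = make_series(Modality.EDA, values)  # 4 Hz -> 8-sample windows
        (rac,) = sq.rac_values(ser)
        expected = rac_oracle(values, 8)
        assert np.array_equal(rac, expected)

    def test_windows_are_segment_aligned(self):
        segs = [Segment(0.0, np.array([1.0, 1.3])), Segment(100.0, np.array([1.0, 1.3]))]
        ser = ModalitySeries(Modality.EDA, 1.0, segs)
        racs = sq.rac_values(ser)
        assert len(racs) == 2
        assert np.allclose(racs[0], racs[1])

    def test_bvp_rejected(self):
        with pytest.raises(ValidationError):
            sq.rac_values(make_series(Modality.BVP, np.ones(64)))


class TestEdaTempQuality:
    def test_constant_eda_in_range_all_good(self):
        flags = sq.eda_quality(make_series(Modality.EDA, np.full(240, 2.0))).all_flags()
        assert flags.all()

    def test_zero_line_all_bad(self):
        flags = sq.eda_quality(make_series(Modality.EDA, np.zeros(240))).all_flags()
        assert not flags.any()

    def test_step_within_window_is_bad(self):
        # 1.0 -> 1.3 inside one 2-s window: RAC 0.3 >= 0.2
        values = np.array([1.0] * 4 + [1.3] * 4 + [1.3] * 8)
        flags = sq.eda_quality(make_series(Modality.EDA, values)).all_flags()
        assert not flags[:8].any()
        assert flags[8:].all()

    def test_ambient_temperature_all_bad(self):
        flags = sq.temp_quality(make_series(Modality.TEMP, np.full(240, 22.0))).all_flags()
        assert not flags.any()

    def test_constant_skin_temperature_all_good(self):
        flags = sq.temp_quality(make_series(Modality.TEMP, np.full(240, 33.0))).all_flags()
        assert flags.all()

    def test_fast_temperature_ramp_is_bad(self):
        # 30 -> 37 degC within 2 s: RAC = 7/30 = 0.233
        values = np.concatenate([np.linspace(30, 37, 8), np.full(8, 37.0)])
        flags = sq.temp_quality(make_series(Modality.TEMP, values)).all_flags()
        assert not flags[:8].any()
        assert flags[8:].all()

    def test_conjunction_contained_in_both_passes(self, rng):
        values = np.abs(rng.normal(1.0, 1.0, 960))
        ser = make_series(Modality.EDA, values)
        good = sq.eda_quality(ser).all_flags()
        range_pass = values >= CFG.eda_onbody_min_uS
        rac_pass = np.concatenate(sq.rac_values(ser)) < CFG.rac_threshold
        assert not np.any(good & ~range_pass)
        assert not np.any(good & ~rac_pass)


class TestSpectralEntropy:
    def test_pure_tone_entropy_is_low(self):
        t = np.arange(30 * 64) / 64.0
        ser = make_series(Modality.BVP, np.sin(2 * np.pi * 1.25 * t))
        (ent,) = sq.bvp_spectral_entropy(ser)
        assert np.nanmax(ent) < 0.3

    def test_white_noise_entropy_is_high(self, rng):
        ser = make_series(Modality.BVP, rng.normal(size=30 * 64))
        (ent,) = sq.bvp_spectral_entropy(ser)
        assert np.nanmin(ent) > 0.9

    def test_windows_match_direct_summation_oracle(self, rng):
        x = np.sin(2 * np.pi * 1.2 * np.arange(12 * 64) / 64.0) + 0.3 * rng.normal(size=12 * 64)
        ser = make_series(Modality.BVP, x)
        (ent,) = sq.bvp_spectral_entropy(ser)
        centers, oracle = entropy_windows_oracle(x, 64.0)
        expected = np.interp(np.arange(len(x)), centers, oracle)
        assert np.allclose(ent, expected, atol=1e-9)

    def test_amplitude_scale_invariance(self, rng):
        x = rng.normal(size=8 * 64)
        e1 = sq.bvp_spectral_entropy(make_series(Modality.BVP, x))[0]
        e2 = sq.bvp_spectral_entropy(make_series(Modality.BVP, 10.0 * x))[0]
        assert np.allclose(e1, e2, atol=1e-9)

    def test_monotone_in_noise_fraction(self, rng):
        t = np.arange(20 * 64) / 64.0
        tone = np.sin(2 * np.pi * 1.2 * t)
        noise = rng.normal(size=len(t))
        means = []
        for alpha in (0.0, 0.1, 0.3, 0.6, 1.0):
            x = (1 - alpha) * tone + alpha * noise
            means.append(np.nanmean(sq.bvp_spectral_entropy(make_series(Modality.BVP, x))[0]))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_short_segment_has_no_entropy(self):
        ser = make_series(Modality.BVP, np.ones(100))  # < 4 s at 64 Hz
        (ent,) = sq.bvp_spectral_entropy(ser)
        assert np.all(np.isnan(ent))


class TestBvpQuality:
    @pytest.mark.parametrize("entropy,good", [(0.79, True), (0.80, True), (0.81, False)])
    def test_threshold_is_strictly_above(self, entropy, good):
        ser = make_series(Modality.BVP, np.ones(256))
        flags = sq.bvp_quality(ser, CFG, entropy=[np.full(256, entropy)]).all_flags()
        assert flags.all() == good

    def test_missing_entropy_is_bad(self):
        ser = make_series(Modality.BVP, np.ones(100))
        assert not sq.bvp_quality(ser, CFG).all_flags().any()


def _mask_all_on(n: int, start: float = 0.0) -> OnBodyMask:
    grid = start + 60.0 * np.arange(n)
    on = np.full(n, Status.ON, dtype=np.int8)
    return OnBodyMask(window_starts=grid, per_modality={Modality.EDA: on}, combined=on.copy())


class TestMinuteScores:
    def _recording(self, values):
        return Recording(series={Modality.EDA: make_series(Modality.EDA, values)})

    def test_all_good_minute_scores_one(self):
        rec = self._recording(np.full(240, 2.0))
        quality = {Modality.EDA: sq.eda_quality(rec.series[Modality.EDA])}
        scores = sq.minute_scores(rec, quality, _mask_all_on(1))
        assert scores.scores[Modality.EDA][0] == 1.0

    def test_offbody_minute_is_missing_regardless_of_flags(self):
        rec = self._recording(np.full(480, 2.0))
        quality = {Modality.EDA: sq.eda_quality(rec.series[Modality.EDA])}
        mask = _mask_all_on(2)
        mask.combined[1] = Status.OFF
        scores = sq.minute_scores(rec, quality, mask)
        assert scores.scores[Modality.EDA][0] == 1.0
        assert np.isnan(scores.scores[Modality.EDA][1])

    def test_half_good_minute_scores_half(self):
        # 120 good then 120 below-range samples; the step sits on a window edge
        values = np.concatenate([np.full(120, 2.0), np.zeros(120)])
        rec = self._recording(values)
        quality = {Modality.EDA: sq.eda_quality(rec.series[Modality.EDA])}
        scores = sq.minute_scores(rec, quality, _mask_all_on(1))
        assert scores.scores[Modality.EDA][0] == pytest.approx(0.5)

    def test_score_equals_one_minus_bad_fraction(self, rng):
        values = np.abs(rng.normal(1.0, 1.5, 240 * 5))
        rec = self._recording(values)
        squal = sq.eda_quality(rec.series[Modality.EDA])
        scores = sq.minute_scores(rec, {Modality.EDA: squal}, _mask_all_on(5))
        flags = squal.all_flags()
        for minute in range(5):
            window = flags[minute * 240:(minute + 1) * 240]
            bad_fraction = 1 - window.mean()
            assert scores.scores[Modality.EDA][minute] == pytest.approx(1 - bad_fraction)

    def test_minute_without_samples_is_missing(self):
        ser = ModalitySeries(
            Modality.EDA, 4.0,
            [Segment(0.0, np.full(240, 2.0)), Segment(120.0, np.full(240, 2.0))],
        )
        rec = Recording(series={Modality.EDA: ser})
        quality = {Modality.EDA: sq.eda_quality(ser)}
        scores = sq.minute_scores(rec, quality, _mask_all_on(3))
        col = scores.scores[Modality.EDA]
        assert col[0] == 1.0 and np.isnan(col[1]) and col[2] == 1.0
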