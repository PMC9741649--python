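"""Per-sample signal-quality scoring for EDA, TEMP and BVP.

EDA and TEMP share one scheme, their sensors being closely related: a
plausible-range test (EDA ≥ 0.05 μS; TEMP within 25–40 °C) combined by
logical conjunction with a rate-of-amplitude-change (RAC) screen.  The RAC
of a 2-s window is

    RAC = (max - min) / d,

where ``d`` is the window maximum if it occurs before the minimum and the
minimum otherwise ("whichever comes first").  Neither signal changes by
>20% within 2 s under normal physiology — even phasic EDA responses stay
below that — so windows with RAC ≥ 0.2 are artifacts (electrode lift-off,
motion) and every sample in them is bad.

BVP quality uses the normalized spectral entropy of 4-s windows restricted
to the 0.1–5 Hz band where the pulse wave and its harmonics live: 0 for a
single spectral component (clean quasi-periodic pulse), 1 for a flat
spectrum (broadband noise from motion or light).  Samples whose
interpolated entropy exceeds 0.8 are poor quality.

Per-sample flags are averaged per wall-clock minute into scores in [0, 1],
defined only on minutes the on-body mask marks as worn.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import QualityConfig
from .model import (
    MinuteScores,
    Modality,
    ModalitySeries,
    OnBodyMask,
    Recording,
    SampleQuality,
    Status,
    ValidationError,
)

QUALITY_MODALITIES = (Modality.EDA, Modality.BVP, Modality.TEMP)


def _window_rac(values: np.ndarray) -> float:
    """RAC of a single window of samples."""
    vmax = values.max()
    vmin = values.min()
    if vmax == vmin:
        return 0.0
    d = vmax if int(np.argmax(values)) < int(np.argmin(values)) else vmin
    if d == 0:
        return float("inf")
    return float((vmax - vmin) / d)


def rac_values(series: ModalitySeries, cfg: QualityConfig | None = None) -> list[np.ndarray]:
    """Per-sample RAC, one array per segment.

    Windows are non-overlapping and aligned to each segment's start; every
    sample inherits the RAC of its window.  A trailing partial window is
    evaluated over the samples it has.  A zero denominator yields +inf
    (always flagged bad downstream).
    """
    cfg = cfg or QualityConfig()
    if series.modality not in (Modality.EDA, Modality.TEMP):
        raise ValidationError("RAC applies to EDA and TEMP series")
    w = max(int(round(cfg.rac_window_s * series.sample_rate)), 1)
    out: list[np.ndarray] = []
    for seg in series.segments:
        x = seg.values
        n = len(x)
        n_full = n // w
        per_window = np.empty(int(np.ceil(n / w)))
        if n_full:
            blocks = x[: n_full * w].reshape(n_full, w)
            vmax = blocks.max(axis=1)
            vmin = blocks.min(axis=1)
            imax = blocks.argmax(axis=1)
            imin = blocks.argmin(axis=1)
            d = np.where(imax < imin, vmax, vmin)
            num = vmax - vmin
            with np.errstate(divide="ignore", invalid="ignore"):
                rac = np.where(num == 0, 0.0, num / d)
            rac[(num > 0) & (d == 0)] = np.inf
            per_window[:n_full] = rac
        if n % w:
            per_window[-1] = _window_rac(x[n_full * w:])
        out.append(np.repeat(per_window, w)[:n])
    return out


def _range_rac_quality(series: ModalitySeries, range_ok: list[np.ndarray],
                       cfg: QualityConfig) -> SampleQuality:
    rac = rac_values(series, cfg)
    flags = [ok & (r < cfg.rac_threshold) for ok, r in zip(range_ok, rac)]
    return SampleQuality(modality=series.modality, flags=flags)


def eda_quality(series: ModalitySeries, cfg: QualityConfig | None = None) -> SampleQuality:
    """Good iff amplitude ≥ 0.05 μS (above the zero-line of lost contact)
    and the 2-s window RAC is below 0.2."""
    cfg = cfg or QualityConfig()
    if series.modality is not Modality.EDA:
        raise ValidationError("eda_quality requires an EDA series")
    range_ok = [seg.values >= cfg.eda_onbody_min_uS for seg in series.segments]
    return _range_rac_quality(series, range_ok, cfg)


def temp_quality(series: ModalitySeries, cfg: QualityConfig | None = None) -> SampleQuality:
    """Good iff within the 25–40 °C skin-temperature band (inclusive) and
    the 2-s window RAC is below 0.2."""
    cfg = cfg or QualityConfig()
    if series.modality is not Modality.TEMP:
        raise ValidationError("temp_quality requires a TEMP series")
    range_ok = [
        (seg.values >= cfg.temp_min_C) & (seg.values <= cfg.temp_max_C)
        for seg in series.segments
    ]
    return _range_rac_quality(series, range_ok, cfg)


def spectral_entropy_window(x: np.ndarray, sample_rate: float,
                            band_hz: tuple[float, float] = (0.1, 5.0)) -> float:
    """Normalized spectral entropy of one window of samples.

    Hann-tapered magnitude-squared DFT, restricted to ``band_hz``
    (inclusive), normalized to a probability mass ``p``; the entropy
    ``-Σ p log p / log(#bins)`` lies in [0, 1].  A window with no in-band
    power is assigned 1.0 (no distinguishable spectral structure).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    taper = np.hanning(n)
    power = np.abs(np.fft.rfft(x * taper)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    nbins = int(band.sum())
    if nbins < 2:
        raise ValidationError("entropy band holds fewer than 2 DFT bins")
    pw = power[band]
    total = pw.sum()
    if total == 0:
        return 1.0
    p = pw / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / np.log(nbins))


def bvp_spectral_entropy(series: ModalitySeries,
                         cfg: QualityConfig | None = None) -> list[np.ndarray]:
    """Per-sample spectral entropy in [0, 1], one array per segment.

    Entropy is evaluated on 4-s windows with 50% overlap; each window's
    power spectrum is a Welch-style average of its own Hann periodogram
    and those of its immediately overlapping neighbors
    (``cfg.bvp_spectrum_avg`` windows, truncated at segment edges), which
    debiases the plug-in entropy toward the theoretical 0/1 endpoints.
    Window entropies are assigned to the window centers and linearly
    interpolated to every sample time (constant extrapolation at segment
    edges).  Segments shorter than one window get NaN throughout (no
    computable entropy).
    """
    cfg = cfg or QualityConfig()
    if series.modality is not Modality.BVP:
        raise ValidationError("bvp_spectral_entropy requires a BVP series")
    fs = series.sample_rate
    n = int(round(cfg.bvp_entropy_window_s * fs))
    hop = max(int(round(n * (1.0 - cfg.bvp_entropy_overlap))), 1)
    half_avg = cfg.bvp_spectrum_avg // 2
    taper = np.hanning(n)
    out: list[np.ndarray] = []
    for seg in series.segments:
        x = seg.values
        if len(x) < n:
            out.append(np.full(len(x), np.nan))
            continue
        wins = np.lib.stride_tricks.sliding_window_view(x, n)[::hop]
        power = np.abs(np.fft.rfft(wins * taper, axis=1)) ** 2
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        band = (freqs >= cfg.bvp_band_hz[0]) & (freqs <= cfg.bvp_band_hz[1])
        nbins = int(band.sum())
        if nbins < 2:
            raise ValidationError("entropy band holds fewer than 2 DFT bins")
        raw = power[:, band]
        if half_avg:
            csum = np.cumsum(raw, axis=0)
            csum = np.vstack([np.zeros(nbins), csum])
            m = len(raw)
            lo = np.clip(np.arange(m) - half_avg, 0, m)
            hi = np.clip(np.arange(m) + half_avg + 1, 0, m)
            pw = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
        else:
            pw = raw
        totals = pw.sum(axis=1)
        ent = np.ones(len(pw))
        ok = totals > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            p = pw[ok] / totals[ok, None]
            logp = np.where(p > 0, np.log(p), 0.0)
        ent[ok] = -(p * logp).sum(axis=1) / np.log(nbins)
        centers = np.arange(len(pw)) * hop + (n - 1) / 2.0
        out.append(np.interp(np.arange(len(x)), centers, ent))
    return out


def bvp_quality(series: ModalitySeries, cfg: QualityConfig | None = None,
                entropy: list[np.ndarray] | None = None) -> SampleQuality:
    """Good iff spectral entropy ≤ 0.8 (strictly above is poor quality).

    Samples without computable entropy (segment shorter than one window)
    are bad: unusable signal is exactly the condition the score measures.
    """
    cfg = cfg or QualityConfig()
    if entropy is None:
        entropy = bvp_spectral_entropy(series, cfg)
    flags = []
    for e in entropy:
        with np.errstate(invalid="ignore"):
            flags.append(np.nan_to_num(e, nan=np.inf) <= cfg.bvp_entropy_threshold)
    return SampleQuality(modality=Modality.BVP, flags=flags)


def quality_flags(rec: Recording, cfg: QualityConfig | None = None) -> dict[Modality, SampleQuality]:
    """Per-sample quality for every scoreable modality present (EDA/BVP/TEMP)."""
    cfg = cfg or QualityConfig()
    out: dict[Modality, SampleQuality] = {}
    if Modality.EDA in rec.series:
        out[Modality.EDA] = eda_quality(rec.series[Modality.EDA], cfg)
    if Modality.TEMP in rec.series:
        out[Modality.TEMP] = temp_quality(rec.series[Modality.TEMP], cfg)
    if Modality.BVP in rec.series:
        out[Modality.BVP] = bvp_quality(rec.series[Modality.BVP], cfg)
    return out


def minute_scores(rec: Recording, quality: dict[Modality, SampleQuality],
                  mask: OnBodyMask, cfg: QualityConfig | None = None) -> MinuteScores:
    """Average per-sample flags into per-minute scores on on-body minutes.

    Per on-body minute and modality, the score is the fraction of good
    samples among the recorded samples of that minute.  Minutes that are
    off-body or ``no_data``, and minutes without recorded samples of a
    modality, are NaN.
    """
    cfg = cfg or QualityConfig()
    grid = mask.window_starts
    n = len(grid)
    scores: dict[Modality, np.ndarray] = {}
    on = np.asarray(mask.combined) == Status.ON
    for mod, sq in quality.items():
        series = rec.series.get(mod)
        if series is None:
            raise ValidationError(f"quality flags for {mod.value} but no series in recording")
        times = series.sample_times()
        flags = sq.all_flags().astype(float)
        if len(times) != len(flags):
            raise ValidationError(f"{mod.value}: quality flags not aligned to series")
        idx = np.floor((times - grid[0]) / mask.window_s).astype(int)
        valid = (idx >= 0) & (idx < n)
        if not valid.all():
            raise ValidationError(f"{mod.value}: samples fall outside the mask's minute grid")
        counts = np.bincount(idx, minlength=n)
        good = np.bincount(idx, weights=flags, minlength=n)
        s = np.full(n, np.nan)
        ok = on & (counts > 0)
        s[ok] = good[ok] / counts[ok]
        scores[mod] = s
    return MinuteScores(window_starts=grid.copy(), scores=scores, window_s=mask.window_s)


def scores_to_frame(scores: MinuteScores, mask: OnBodyMask | None = None) -> pd.DataFrame:
    """Minute scores as a DataFrame for CSV export (NaN → empty field)."""
    cols: dict[str, object] = {
        "window_start_iso": pd.to_datetime(scores.window_starts, unit="s", utc=True)
    }
    if mask is not None:
        cols["onbody"] = [Status(int(s)).name.lower() for s in mask.combined]
    for mod in QUALITY_MODALITIES:
        if mod in scores.scores:
            cols[f"{mod.value.lower()}_score"] = scores.scores[mod]
    return pd.DataFrame(cols)
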