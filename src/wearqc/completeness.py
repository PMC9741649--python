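"""Data completeness: recorded vs. expected samples.

Completeness is strictly about the presence and absence of data samples —
the device being off, out of Bluetooth range, or otherwise not recording —
regardless of the quality of the samples that exist.  Per modality it is
the ratio of recorded duration to expected duration,

    completeness = N_rec / (F_s * (t_end - t_start)),

with ``N_rec`` the recorded sample count, ``F_s`` the sample rate and
``t_start``/``t_end`` the first and last sample times.  The recording-level
score averages the per-modality ratios; the recording duration is the
maximum over modalities of ``N_rec / F_s``.
"""

from __future__ import annotations

import logging

from .model import (
    CompletenessResult,
    Modality,
    ModalitySeries,
    Recording,
    RecordingSummary,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Inclusive minimum recorded duration per setting, seconds.
DURATION_THRESHOLDS_S = {"inpatient": 3600.0, "outpatient": 86400.0}


def modality_completeness(series: ModalitySeries) -> float:
    """Fraction of expected samples actually recorded, in [0, 1].

    The device's sampling-rate drift can push the raw ratio marginally
    above 1; such values are clamped to 1 with a logged warning.  A
    single-sample series has zero span and returns 1.0 by convention.
    """
    n_rec = series.n_rec
    span = series.t_end - series.t_start
    if span == 0:
        if n_rec > 1:
            raise ValidationError(
                f"{series.modality.value}: {n_rec} samples but zero time span"
            )
        return 1.0
    ratio = n_rec / (series.sample_rate * span)
    if ratio > 1.0:
        # a contiguous n-sample run spans (n-1)/Fs, so ratios slightly
        # above 1 are expected; only warn when beyond that bookkeeping
        if ratio > n_rec / max(n_rec - 1, 1):
            log.warning(
                "%s: completeness %.4f > 1 (sampling-rate drift?); clamping",
                series.modality.value, ratio,
            )
        ratio = 1.0
    return float(ratio)


def recording_completeness(rec: Recording) -> CompletenessResult:
    """Recording-level completeness: mean ratio, max recorded duration.

    The mean is unweighted, over the modalities present in the recording.
    """
    if not rec.series:
        raise ValidationError("recording has no modalities")
    ratios = {mod: modality_completeness(ser) for mod, ser in rec.series.items()}
    duration = max(ser.duration_s for ser in rec.series.values())
    return CompletenessResult(
        per_modality_ratio=ratios,
        completeness=float(sum(ratios.values()) / len(ratios)),
        duration_s=float(duration),
        span_s=float(rec.span_s),
    )


def duration_filter(
    summaries: list[RecordingSummary],
    setting: str,
    thresholds_s: dict[str, float] | None = None,
) -> list[RecordingSummary]:
    """Keep recordings long enough for the given setting.

    Inpatient recordings need at least 1 h of data, outpatient at least
    24 h; both boundaries are inclusive ("at least").  ``thresholds_s``
    overrides the defaults.
    """
    thresholds = dict(DURATION_THRESHOLDS_S)
    if thresholds_s:
        thresholds.update(thresholds_s)
    if setting not in thresholds:
        raise ValidationError(
            f"unknown setting {setting!r}; expected one of {sorted(thresholds)}"
        )
    cutoff = thresholds[setting]
    return [s for s in summaries if s.duration_s >= cutoff]
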