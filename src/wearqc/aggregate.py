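"""Recording- and cohort-level aggregation, grouping and comparison.

Minute scores roll up to one row per recording (completeness %, on-body %,
per-modality quality % over on-body minutes, duration); recordings roll up
to cohort statistics (mean, median, std, min, max per metric).  Every
recording weighs equally — scores are averaged per recording first, then
across recordings.  Groups (day vs. night, wrist vs. ankle, ...) are
compared with a two-tailed two-sample t-test reporting t, the degrees of
freedom and p.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import QualityConfig
from .model import (
    CohortSummary,
    CompletenessResult,
    GroupComparison,
    MetricStats,
    MinuteScores,
    Modality,
    OnBodyMask,
    RecordingSummary,
    ValidationError,
)

METRIC_FIELDS = ("completeness_pct", "onbody_pct", "eda_pct", "bvp_pct", "temp_pct", "duration_s")


def summarize_recording(
    comp: CompletenessResult,
    mask: OnBodyMask,
    scores: MinuteScores,
    recording_id: str = "recording",
    placement: str = "unknown",
    mode: str = "unknown",
    site: str = "",
) -> RecordingSummary:
    """One summary row for a recording.

    Quality percentages are means of the non-missing minute scores; with
    zero scoreable minutes they are NaN but the summary is still produced.
    """

    def pct(mod: Modality) -> float:
        if mod not in scores.scores:
            return float("nan")
        return 100.0 * scores.mean_score(mod)

    onbody = mask.onbody_fraction
    return RecordingSummary(
        recording_id=recording_id,
        completeness_pct=100.0 * comp.completeness,
        onbody_pct=100.0 * onbody if np.isfinite(onbody) else float("nan"),
        eda_pct=pct(Modality.EDA),
        bvp_pct=pct(Modality.BVP),
        temp_pct=pct(Modality.TEMP),
        duration_s=comp.duration_s,
        placement=placement,
        mode=mode,
        site=site,
    )


def _stats(values: np.ndarray) -> MetricStats:
    v = values[np.isfinite(values)]
    if v.size == 0:
        nan = float("nan")
        return MetricStats(nan, nan, nan, nan, nan, 0)
    std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return MetricStats(
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        std=std,
        min=float(np.min(v)),
        max=float(np.max(v)),
        n=int(v.size),
    )


def summarize_cohort(
    summaries: list[RecordingSummary],
    patient_ids: list[str] | None = None,
) -> CohortSummary:
    """Cohort statistics over recording summaries, ignoring missing values.

    ``std`` is the sample standard deviation (0 for a single recording).
    ``patient_ids``, when given, maps 1:1 onto ``summaries`` and determines
    ``n_patients`` (some patients contribute several recordings).
    """
    if not summaries:
        raise ValidationError("cannot summarize an empty cohort")
    metrics = {
        name: _stats(np.array([getattr(s, name) for s in summaries], dtype=float))
        for name in METRIC_FIELDS
    }
    if patient_ids is not None and len(patient_ids) != len(summaries):
        raise ValidationError("patient_ids must align 1:1 with summaries")
    n_patients = len(set(patient_ids)) if patient_ids is not None else len(summaries)
    total = float(np.nansum([s.duration_s for s in summaries]))
    return CohortSummary(
        metrics=metrics,
        n_recordings=len(summaries),
        n_patients=n_patients,
        total_duration_s=total,
    )


def _local_hours(window_starts: np.ndarray, utc_offset: float) -> np.ndarray:
    local = np.asarray(window_starts, dtype=float) + utc_offset * 3600.0
    return (local % 86400.0) / 3600.0


def day_night_split(
    scores: MinuteScores,
    utc_offset: float = 0.0,
    cfg: QualityConfig | None = None,
) -> tuple[MinuteScores, MinuteScores]:
    """Partition minutes into daytime and nighttime by local wall clock.

    A minute belongs to the day iff its local start time lies in the
    half-open interval [08:00, 20:00); the partition is exhaustive and
    disjoint.  The device timezone enters through ``utc_offset`` (hours).
    """
    cfg = cfg or QualityConfig()
    hours = _local_hours(scores.window_starts, utc_offset)
    day = (hours >= cfg.day_start_h) & (hours < cfg.day_end_h)

    def take(sel: np.ndarray) -> MinuteScores:
        return MinuteScores(
            window_starts=scores.window_starts[sel],
            scores={m: v[sel] for m, v in scores.scores.items()},
            window_s=scores.window_s,
        )

    return take(day), take(~day)


def hourly_profile(
    scores_list: list[MinuteScores],
    utc_offsets: list[float] | float = 0.0,
) -> dict[Modality, np.ndarray]:
    """Mean minute score per local hour of day (24 bins) per modality.

    Bins without any non-missing minute are NaN.
    """
    if not scores_list:
        raise ValidationError("hourly_profile needs at least one recording")
    if np.isscalar(utc_offsets):
        utc_offsets = [float(utc_offsets)] * len(scores_list)
    if len(utc_offsets) != len(scores_list):
        raise ValidationError("one utc_offset per recording required")
    sums: dict[Modality, np.ndarray] = {}
    counts: dict[Modality, np.ndarray] = {}
    for scores, off in zip(scores_list, utc_offsets):
        hour_bin = _local_hours(scores.window_starts, off).astype(int)
        for mod, v in scores.scores.items():
            ok = np.isfinite(v)
            sums.setdefault(mod, np.zeros(24))
            counts.setdefault(mod, np.zeros(24))
            sums[mod] += np.bincount(hour_bin[ok], weights=v[ok], minlength=24)
            counts[mod] += np.bincount(hour_bin[ok], minlength=24)
    out = {}
    for mod in sums:
        with np.errstate(invalid="ignore"):
            out[mod] = np.where(counts[mod] > 0, sums[mod] / np.maximum(counts[mod], 1), np.nan)
    return out


def compare_groups(a, b, welch: bool = False) -> GroupComparison:
    """Two-tailed two-sample t-test between two groups of values.

    Pooled-variance (Student) by default with df = n_a + n_b − 2; Welch's
    unequal-variance form via ``welch=True``.  Two degenerate cases: zero
    variance in both groups with equal means gives t = 0, p = 1; zero
    variance with unequal means is an error (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("groups must be finite")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            df = len(a) + len(b) - 2
            return GroupComparison(0.0, float(df), 1.0,
                                   float(np.mean(a)), float(np.mean(b)), len(a), len(b))
        raise ValidationError("zero variance with unequal means: t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else float(len(a) + len(b) - 2)
    return GroupComparison(
        t_value=float(res.statistic),
        degrees_of_freedom=df,
        p_value=float(res.pvalue),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        n_a=len(a),
        n_b=len(b),
    )
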