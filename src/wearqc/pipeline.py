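"""End-to-end scoring of one recording.

Completeness is relative to the whole recording period; the on-body mask
restricts it further; the per-modality signal-quality scores are relative
to the on-body data only.  This module chains the steps so library users
and the CLI run exactly the same code.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import aggregate, completeness, onbody, signal_quality
from .config import QualityConfig
from .model import (
    CompletenessResult,
    MinuteScores,
    OnBodyMask,
    Recording,
    RecordingSummary,
)


@dataclass
class ScoreResult:
    completeness: CompletenessResult
    mask: OnBodyMask
    scores: MinuteScores
    summary: RecordingSummary


def score_recording(rec: Recording, cfg: QualityConfig | None = None) -> ScoreResult:
    """Run completeness → on-body → signal quality → summary for one recording."""
    cfg = cfg or QualityConfig()
    comp = completeness.recording_completeness(rec)
    mask = onbody.onbody_mask(rec, cfg)
    flags = signal_quality.quality_flags(rec, cfg)
    scores = signal_quality.minute_scores(rec, flags, mask, cfg)
    summary = aggregate.summarize_recording(
        comp,
        mask,
        scores,
        recording_id=rec.recording_id,
        placement=rec.placement,
        mode=rec.mode,
        site=rec.site,
    )
    return ScoreResult(completeness=comp, mask=mask, scores=scores, summary=summary)
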