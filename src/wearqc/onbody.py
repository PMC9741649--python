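"""On-body (wear) detection from ACC activity, EDA amplitude and TEMP range.

A device that records while lying on a table produces data but no
information.  Wear status is estimated per 1-minute wall-clock window from
the three modalities that have a defined off-body signature:

* ACC — activity level, the 10-s moving standard deviation of the
  per-sample sum of the three axes; off-body devices are still.
* EDA — skin conductance falls to ~0 μS once the electrodes leave the
  skin; samples at or above 0.05 μS count as on-body.
* TEMP — worn devices read skin temperature; 25–40 °C (inclusive) counts
  as on-body, ambient temperature does not.

BVP is excluded: off the body its reading is a function of incoming light
and has no defined range.  A window is on-body for a modality if at least
1% of its recorded samples are in range (the ``window_min_fraction`` rule);
windows with no recorded samples are ``no_data``.  The default combination
declares a window worn if at least one modality votes on-body.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CombinePolicy, QualityConfig
from .model import (
    Modality,
    ModalitySeries,
    OnBodyMask,
    Recording,
    Status,
    ValidationError,
    minute_grid,
)

ONBODY_MODALITIES = (Modality.ACC, Modality.EDA, Modality.TEMP)


def moving_std(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving population standard deviation, truncated at the edges.

    Sample ``i`` sees the window ``[i - (window-1)//2, i + window//2]``
    intersected with the array, so windows shrink near segment edges
    instead of lagging.  Computed from running sums; the global mean is
    removed first for numerical stability.
    """
    x = np.asarray(x, dtype=float)
    x0 = x - x.mean()
    n = len(x)
    i = np.arange(n)
    lo = np.clip(i - (window - 1) // 2, 0, n)
    hi = np.clip(i + window // 2 + 1, 0, n)
    c1 = np.concatenate([[0.0], np.cumsum(x0)])
    c2 = np.concatenate([[0.0], np.cumsum(x0 * x0)])
    cnt = hi - lo
    mean = (c1[hi] - c1[lo]) / cnt
    var = (c2[hi] - c2[lo]) / cnt - mean**2
    return np.sqrt(np.maximum(var, 0.0))


def acc_activity(series: ModalitySeries, cfg: QualityConfig | None = None) -> list[np.ndarray]:
    """Per-sample activity level in g, one array per segment.

    The activity level is the moving std (10-s centered window, truncated
    at segment edges) of the per-sample sum x+y+z, computed independently
    per segment so gaps never bleed into the estimate.
    """
    cfg = cfg or QualityConfig()
    if series.modality is not Modality.ACC:
        raise ValidationError("acc_activity requires an ACC series")
    window = max(int(round(cfg.acc_std_window_s * series.sample_rate)), 1)
    return [moving_std(seg.values.sum(axis=1), window) for seg in series.segments]


def _in_range_flags(series: ModalitySeries, cfg: QualityConfig) -> list[np.ndarray]:
    """Per-sample on-body-range indicators, one boolean array per segment."""
    mod = series.modality
    if mod is Modality.ACC:
        return [a >= cfg.acc_std_threshold_g for a in acc_activity(series, cfg)]
    if mod is Modality.EDA:
        return [seg.values >= cfg.eda_onbody_min_uS for seg in series.segments]
    if mod is Modality.TEMP:
        return [
            (seg.values >= cfg.temp_min_C) & (seg.values <= cfg.temp_max_C)
            for seg in series.segments
        ]
    raise ValidationError(f"{mod.value} is not used for on-body detection")


def modality_onbody_windows(
    series: ModalitySeries,
    cfg: QualityConfig | None = None,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Tri-state wear status per 1-minute window for one modality.

    ``grid`` is the shared array of wall-clock-aligned window start times;
    when omitted it is derived from the series itself.  Returns an int8
    array of :class:`~wearqc.model.Status` values.
    """
    cfg = cfg or QualityConfig()
    if series.modality not in ONBODY_MODALITIES:
        raise ValidationError(
            f"{series.modality.value} is not used in the on-body assessment"
        )
    if grid is None:
        grid = minute_grid(series.t_start, series.t_end, cfg.minute_s)
    flags = _in_range_flags(series, cfg)
    times = series.sample_times()
    inrange = np.concatenate(flags).astype(float)

    idx = np.floor((times - grid[0]) / cfg.minute_s).astype(int)
    valid = (idx >= 0) & (idx < len(grid))
    counts = np.bincount(idx[valid], minlength=len(grid))
    hits = np.bincount(idx[valid], weights=inrange[valid], minlength=len(grid))

    status = np.full(len(grid), Status.NO_DATA, dtype=np.int8)
    has = counts > 0
    frac = np.zeros(len(grid))
    frac[has] = hits[has] / counts[has]
    status[has & (frac >= cfg.window_min_fraction)] = Status.ON
    status[has & (frac < cfg.window_min_fraction)] = Status.OFF
    return status


def combine_onbody(
    per_modality: dict[Modality, np.ndarray],
    policy: CombinePolicy | str = CombinePolicy.ANY,
    window_starts: np.ndarray | None = None,
    window_s: float = 60.0,
) -> OnBodyMask:
    """Merge per-modality wear votes into a single tri-state mask.

    ``no_data`` modalities abstain; a window where every modality is
    ``no_data`` stays ``no_data``.  Policies: ``any`` (default, at least
    one on-body vote), ``majority`` (more than half of the voting
    modalities), ``all`` (every voting modality).
    """
    policy = CombinePolicy(policy)
    if not per_modality:
        raise ValidationError("no per-modality statuses to combine")
    lengths = {len(v) for v in per_modality.values()}
    if len(lengths) != 1:
        raise ValidationError(f"mismatched window grids: lengths {sorted(lengths)}")
    n = lengths.pop()
    if window_starts is None:
        window_starts = window_s * np.arange(n)
    elif len(window_starts) != n:
        raise ValidationError("window_starts length does not match status lists")

    stack = np.stack([np.asarray(v, dtype=np.int8) for v in per_modality.values()])
    voting = stack != Status.NO_DATA
    n_voting = voting.sum(axis=0)
    n_on = (stack == Status.ON).sum(axis=0)

    combined = np.full(n, Status.NO_DATA, dtype=np.int8)
    has_vote = n_voting > 0
    if policy is CombinePolicy.ANY:
        on = n_on >= 1
    elif policy is CombinePolicy.MAJORITY:
        on = n_on * 2 > n_voting
    else:  # ALL
        on = has_vote & (n_on == n_voting)
    combined[has_vote & on] = Status.ON
    combined[has_vote & ~on] = Status.OFF
    return OnBodyMask(
        window_starts=np.asarray(window_starts, dtype=float),
        per_modality={Modality(k): np.asarray(v, dtype=np.int8) for k, v in per_modality.items()},
        combined=combined,
        window_s=window_s,
    )


def onbody_mask(rec: Recording, cfg: QualityConfig | None = None) -> OnBodyMask:
    """Full on-body mask for a recording on its shared minute grid."""
    cfg = cfg or QualityConfig()
    grid = minute_grid(rec.t_start, rec.t_end, cfg.minute_s)
    per_modality = {
        mod: modality_onbody_windows(rec.series[mod], cfg, grid)
        for mod in ONBODY_MODALITIES
        if mod in rec.series
    }
    if not per_modality:
        raise ValidationError("recording has none of the on-body modalities (ACC/EDA/TEMP)")
    return combine_onbody(
        per_modality, cfg.combine_policy, window_starts=grid, window_s=cfg.minute_s
    )


def mask_to_frame(mask: OnBodyMask) -> pd.DataFrame:
    """Mask as a DataFrame for CSV export (ISO window starts, status names)."""
    cols = {"window_start_iso": pd.to_datetime(mask.window_starts, unit="s", utc=True)}
    for mod in ONBODY_MODALITIES:
        if mod in mask.per_modality:
            cols[mod.value.lower()] = [Status(int(s)).name.lower() for s in mask.per_modality[mod]]
    cols["combined"] = [Status(int(s)).name.lower() for s in mask.combined]
    return pd.DataFrame(cols)
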