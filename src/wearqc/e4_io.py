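"""Reading and writing Empatica-E4-style CSV session archives.

The on-disk dialect, per modality file (``ACC.csv``, ``BVP.csv``,
``EDA.csv``, ``TEMP.csv``):

* line 1 — UNIX start timestamp of the first sample (UTC seconds, float);
  repeated once per channel for multi-channel files,
* line 2 — sample rate in Hz (float), same repetition,
* remaining lines — one sample per line, comma-separated channels for ACC.

ACC files store raw integer counts at 1/64 g per count; the internal model
holds g so the device's ±2 g range is literal.  Non-ACC values are written
with enough digits (``%.17g``) that write→read is lossless on float64,
slightly more precise than the stock export.

A streaming-mode recording with dropped packets is a set of sibling segment
directories; :func:`read_session` merges them into one multi-segment
:class:`~wearqc.model.ModalitySeries` per modality.  Derived-channel files
(``IBI.csv``, ``HR.csv``, ``tags.csv``) are ignored with a logged notice.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    FormatError,
    Modality,
    ModalitySeries,
    Placement,
    Recording,
    RecordingMode,
    Segment,
    ValidationError,
)

log = logging.getLogger(__name__)

MODALITY_FILES = {m: f"{m.value}.csv" for m in Modality}
IGNORED_FILES = ("IBI.csv", "HR.csv", "tags.csv")
ACC_COUNTS_PER_G = 64.0
MANIFEST_NAME = "manifest.json"


def _parse_header_line(path: Path, lineno: int, text: str) -> float:
    token = text.split(",")[0].strip()
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}: line {lineno}: expected a number, got {token!r}") from None


def _read_modality_file(path: Path, modality: Modality) -> Segment | None:
    """Parse one E4 CSV into a segment; return None for a sample-less file."""
    with open(path) as fh:
        l1 = fh.readline()
        l2 = fh.readline()
    if not l1 or not l2:
        raise FormatError(f"{path}: missing header rows")
    start = _parse_header_line(path, 1, l1)
    rate = _parse_header_line(path, 2, l2)
    if rate <= 0:
        raise FormatError(f"{path}: line 2: sample rate must be > 0, got {rate}")
    try:
        data = pd.read_csv(
            path, skiprows=2, header=None, float_precision="round_trip"
        ).to_numpy(dtype=float)
    except pd.errors.EmptyDataError:
        return None
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric sample data ({exc})") from None
    if modality is Modality.ACC:
        if data.shape[1] != 3:
            raise FormatError(f"{path}: ACC rows must have 3 values, got {data.shape[1]}")
        values = data / ACC_COUNTS_PER_G
    else:
        if data.shape[1] != 1:
            raise FormatError(f"{path}: expected 1 value per row, got {data.shape[1]}")
        values = data[:, 0]
    seg = Segment(start_time=start, values=values)
    seg.sample_rate = rate  # stashed for the caller; not a model field
    return seg


def _segment_dirs(session_dir: Path) -> list[Path]:
    """The session dir itself if it holds modality CSVs, else its subdirs that do."""
    if any((session_dir / f).is_file() for f in MODALITY_FILES.values()):
        return [session_dir]
    subs = [
        d for d in sorted(session_dir.iterdir())
        if d.is_dir() and any((d / f).is_file() for f in MODALITY_FILES.values())
    ]
    return subs


def read_session(session_dir: str | Path) -> Recording:
    """Read an E4-style session directory into a :class:`Recording`.

    ``session_dir`` may contain the modality CSVs directly, or several
    sibling segment directories (one per contiguous stretch of a streaming
    session); the latter are merged, ordered by start time.

    Raises
    ------
    FileNotFoundError
        Missing directory, or no modality CSV anywhere under it.
    FormatError
        Malformed header or sample rows.
    ValidationError
        Overlapping segments for one modality, or inconsistent rates.
    """
    session_dir = Path(session_dir)
    if not session_dir.is_dir():
        raise FileNotFoundError(f"session directory not found: {session_dir}")
    seg_dirs = _segment_dirs(session_dir)
    if not seg_dirs:
        raise FileNotFoundError(f"no modality CSV files under {session_dir}")

    for d in seg_dirs:
        for name in IGNORED_FILES:
            if (d / name).is_file():
                log.info("ignoring derived-channel file %s", d / name)

    series: dict[Modality, ModalitySeries] = {}
    for modality, fname in MODALITY_FILES.items():
        segments: list[Segment] = []
        rates: list[float] = []
        for d in seg_dirs:
            path = d / fname
            if not path.is_file():
                continue
            seg = _read_modality_file(path, modality)
            if seg is None:
                continue
            rates.append(seg.sample_rate)
            segments.append(seg)
        if not segments:
            continue
        if len(set(rates)) > 1:
            raise ValidationError(
                f"{modality.value}: segment files disagree on sample rate: {sorted(set(rates))}"
            )
        series[modality] = ModalitySeries(
            modality=modality, sample_rate=rates[0], segments=segments
        )

    if not series:
        raise FormatError(f"no samples in any modality file under {session_dir}")

    meta = _read_manifest(session_dir)
    return Recording(
        recording_id=meta.get("recording_id", session_dir.name),
        placement=Placement(meta.get("placement", "unknown")),
        mode=RecordingMode(meta.get("mode", "unknown")),
        utc_offset=float(meta.get("utc_offset", 0.0)),
        site=meta.get("site", ""),
        series=series,
    )


def _read_manifest(session_dir: Path) -> dict:
    path = session_dir / MANIFEST_NAME
    if not path.is_file():
        return {}
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON manifest ({exc})") from None


def _write_modality_file(path: Path, modality: Modality, seg: Segment, rate: float) -> None:
    ncols = 3 if modality is Modality.ACC else 1
    header1 = ", ".join([f"{seg.start_time:.6f}"] * ncols)
    header2 = ", ".join([f"{rate:.6f}"] * ncols)
    if modality is Modality.ACC:
        counts = np.rint(seg.values * ACC_COUNTS_PER_G).astype(np.int64)
        body = pd.DataFrame(counts)
        fmt = None
    else:
        body = pd.DataFrame(seg.values)
        fmt = "%.17g"
    with open(path, "w") as fh:
        fh.write(header1 + "\n" + header2 + "\n")
        body.to_csv(fh, header=False, index=False, float_format=fmt, lineterminator="\n")


def write_session(rec: Recording, session_dir: str | Path) -> list[Path]:
    """Write a :class:`Recording` as an E4-style session directory.

    Single-segment recordings are written flat; a recording in which any
    modality has several segments is written as numbered segment
    subdirectories (``seg000``, ``seg001``, ...) holding one CSV per
    modality segment.  Returns the list of files written.
    """
    session_dir = Path(session_dir)
    session_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    multi = any(len(s.segments) > 1 for s in rec.series.values())
    for modality, ser in rec.series.items():
        for i, seg in enumerate(ser.segments):
            if multi:
                d = session_dir / f"seg{i:03d}"
                d.mkdir(exist_ok=True)
            else:
                d = session_dir
            path = d / MODALITY_FILES[modality]
            _write_modality_file(path, modality, seg, ser.sample_rate)
            written.append(path)

    manifest = {
        "recording_id": rec.recording_id,
        "placement": rec.placement.value,
        "mode": rec.mode.value,
        "utc_offset": rec.utc_offset,
        "site": rec.site,
    }
    mpath = session_dir / MANIFEST_NAME
    mpath.write_text(json.dumps(manifest, indent=1) + "\n")
    written.append(mpath)
    return written
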