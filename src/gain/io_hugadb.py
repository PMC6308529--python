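"""Reading, scaling, validation and writing of HuGaDB-style recordings.

The on-disk dialect is a tab-separated text file: optional ``#``-prefixed
``key=value`` metadata lines, one header row of channel names, then one row
per frame of integer samples with a trailing ``act`` activity column.
Inertial channels are int16 counts, EMG channels uint8 counts.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Nominal sampling rate of the wearable recording system, Hz.
DEFAULT_FS = 56.35

#: Body sites: right/left foot, shin (shank), thigh.
SITES = ("rf", "rs", "rt", "lf", "ls", "lt")
AXES = ("x", "y", "z")

INERTIAL_CHANNELS = tuple(
    f"{kind}_{site}_{axis}" for kind in ("acc", "gyro") for site in SITES for axis in AXES
)
EMG_CHANNELS = ("EMG_r", "EMG_l")
CHANNEL_VOCABULARY = INERTIAL_CHANNELS + EMG_CHANNELS

INT16_MIN, INT16_MAX = -32768, 32767
UINT8_MIN, UINT8_MAX = 0, 255

#: Activity label codes, in the order the database documents them.
ACTIVITIES = {
    1: "walking",
    2: "running",
    3: "going_up",
    4: "going_down",
    5: "sitting",
    6: "sitting_down",
    7: "standing_up",
    8: "standing",
}
ACTIVITY_CODES = {name: code for code, name in ACTIVITIES.items()}
UNLABELED = 0

#: Activities during which the wearer is in locomotion (gait inference runs).
MOVEMENT_ACTIVITIES = ("walking", "running", "going_up", "going_down")


class RecordingError(ValueError):
    """Raised for malformed recording files or invalid sample values."""


def _is_emg(name: str) -> bool:
    return name in EMG_CHANNELS


def _storage_range(name: str) -> tuple[int, int]:
    return (UINT8_MIN, UINT8_MAX) if _is_emg(name) else (INT16_MIN, INT16_MAX)


@dataclass
class RawRecording:
    """Integer-valued multichannel recording with per-frame activity labels."""

    channels: dict[str, np.ndarray]
    labels: np.ndarray
    fs: float = DEFAULT_FS
    participant_id: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise RecordingError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.labels)
        for name, series in self.channels.items():
            if name not in CHANNEL_VOCABULARY:
                raise RecordingError(f"unknown channel name {name!r}")
            if len(series) != n:
                raise RecordingError(
                    f"channel {name!r} has {len(series)} samples, labels have {n}"
                )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ScaledRecording:
    """Same layout as :class:`RawRecording` but with samples in [-1, 1]."""

    channels: dict[str, np.ndarray]
    labels: np.ndarray
    fs: float = DEFAULT_FS
    participant_id: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Issue:
    kind: str  # "saturation" | "unknown_label"
    channel: str | None
    message: str


def read_recording(
    path: str | Path,
    fs: float = DEFAULT_FS,
    column_map: dict[str, str] | None = None,
) -> RawRecording:
    """Parse a HuGaDB-style TSV file into a :class:`RawRecording`.

    ``column_map`` renames external header names to the canonical channel
    vocabulary before interpretation (HuGaDB releases differ in column
    naming); unknown columns are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    metadata: dict[str, str] = {}
    data_lines: list[str] = []
    header: list[str] | None = None
    header_lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            if header is None:
                header = line.split("\t")
                header_lineno = lineno
            else:
                data_lines.append(f"{lineno}\t{line}")
    if header is None:
        raise RecordingError(f"{path}: empty file (no header row)")
    if column_map:
        header = [column_map.get(name, name) for name in header]
    if "act" not in header:
        raise RecordingError(f"{path}: header (line {header_lineno}) lacks an 'act' column")

    keep: list[tuple[int, str]] = []
    for idx, name in enumerate(header):
        if name == "act" or name in CHANNEL_VOCABULARY:
            keep.append((idx, name))
        else:
            logger.warning("%s: ignoring unknown column %r", path, name)

    n_fields = len(header)
    rows = np.empty((len(data_lines), len(keep)), dtype=np.int64)
    keep_idx = [idx for idx, _ in keep]
    for r, tagged in enumerate(data_lines):
        parts = tagged.split("\t")
        lineno, fields = parts[0], parts[1:]
        if len(fields) != n_fields:
            raise RecordingError(
                f"{path}: line {lineno}: expected {n_fields} fields, found {len(fields)}"
            )
        try:
            rows[r] = [int(fields[i]) for i in keep_idx]
        except ValueError as exc:
            raise RecordingError(f"{path}: line {lineno}: non-numeric value ({exc})") from exc

    channels: dict[str, np.ndarray] = {}
    labels = np.zeros(len(data_lines), dtype=np.int64)
    for col, (_, name) in enumerate(keep):
        if name == "act":
            labels = rows[:, col].copy()
        else:
            channels[name] = rows[:, col].copy()
    return RawRecording(
        channels=channels,
        labels=labels,
        fs=fs,
        participant_id=metadata.get("participant_id", path.stem),
        metadata=metadata,
    )


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Emit ``rec`` in the dialect understood by :func:`read_recording`."""
    path = Path(path)
    names = [n for n in CHANNEL_VOCABULARY if n in rec.channels]
    buf = io.StringIO()
    meta = dict(rec.metadata)
    if rec.participant_id and "participant_id" not in meta:
        meta["participant_id"] = rec.participant_id
    for key, value in meta.items():
        buf.write(f"# {key}={value}\n")
    buf.write("\t".join(names + ["act"]) + "\n")
    if len(rec):
        table = np.column_stack([np.asarray(rec.channels[n], dtype=np.int64) for n in names]
                                + [np.asarray(rec.labels, dtype=np.int64)])
        np.savetxt(buf, table, fmt="%d", delimiter="\t")
    path.write_text(buf.getvalue())


def scale_raw(rec: RawRecording) -> ScaledRecording:
    """Map integer samples to [-1, 1].

    Inertial int16 counts are divided by 32768; EMG uint8 counts are
    midpoint-centered via (v - 127.5) / 127.5.
    """
    scaled: dict[str, np.ndarray] = {}
    for name, series in rec.channels.items():
        series = np.asarray(series)
        lo, hi = _storage_range(name)
        bad = np.flatnonzero((series < lo) | (series > hi))
        if bad.size:
            raise RecordingError(
                f"channel {name!r} frame {bad[0]}: value {series[bad[0]]} outside [{lo}, {hi}]"
            )
        if _is_emg(name):
            scaled[name] = (series - 127.5) / 127.5
        else:
            scaled[name] = series / 32768.0
    return ScaledRecording(
        channels=scaled,
        labels=np.asarray(rec.labels).copy(),
        fs=rec.fs,
        participant_id=rec.participant_id,
        metadata=dict(rec.metadata),
    )


def validate_recording(rec: RawRecording, saturation_fraction: float = 0.01) -> list[Issue]:
    """Report data-quality issues without mutating the recording.

    Flags channels whose fraction of samples pinned at the storage-range
    extremes reaches ``saturation_fraction`` (overflown sensors are a known
    failure mode of this kind of hardware), and label codes outside the
    activity vocabulary.
    """
    issues: list[Issue] = []
    for name, series in rec.channels.items():
        series = np.asarray(series)
        if not len(series):
            continue
        lo, hi = _storage_range(name)
        frac = np.mean((series == lo) | (series == hi))
        if frac >= saturation_fraction:
            issues.append(
                Issue(
                    kind="saturation",
                    channel=name,
                    message=f"channel {name!r}: {frac:.1%} of samples saturated at range extremes",
                )
            )
    labels = np.asarray(rec.labels)
    known = set(ACTIVITIES) | {UNLABELED}
    unknown = sorted(set(np.unique(labels).tolist()) - known)
    for code in unknown:
        issues.append(
            Issue(kind="unknown_label", channel=None, message=f"unknown activity label code {code}")
        )
    return issues
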