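"""On-disk formats: sensor time-series CSV, session annotation JSON,
clinical-score table, and PVT reaction-time log.

Conventions
-----------
* Time is seconds as float, 0 = recording start; annotations share the device
  clock (single-clock assumption).
* Gyroscope units are deg/s on disk and in memory; accelerometer m/s^2.
* Sensor CSV dialect: comma-separated, UTF-8, '.' decimal, a header line, and
  '#'-prefixed metadata lines carrying subject / body location / sample rate.
* Missing samples are encoded by timestamp gaps, never sentinel values; a gap
  longer than two sample periods splits a contiguous segment.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """File does not conform to the documented schema."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


BODY_LOCATIONS = frozenset({
    "chest", "left_ankle", "right_ankle", "left_wrist", "right_wrist",
    "left_thigh", "right_thigh", "lumbar",
})
# the sternum strap position is an alias of the chest location
_LOCATION_ALIASES = {"sternum": "chest"}

ANNOTATION_LABELS = frozenset({
    "stand", "balance_30s", "sit", "tug", "walk_2min", "pvt", "sleep", "other",
})

EDSS_GRID = frozenset(np.arange(0.0, 10.5, 0.5).tolist())


def normalize_location(location: str) -> str:
    loc = _LOCATION_ALIASES.get(location.strip().lower(), location.strip().lower())
    if loc not in BODY_LOCATIONS:
        raise ValidationError(f"unknown body location: {location!r}")
    return loc


# ---------------------------------------------------------------------------
# SensorRecording
# ---------------------------------------------------------------------------

@dataclass
class SensorRecording:
    """Time-aligned tri-axial accel/gyro (+ optional IBI) stream from one
    device at one body location.

    Attributes
    ----------
    t : (n,) seconds since recording start, strictly increasing.
    accel_xyz : (n, 3) m/s^2, device frame.
    gyro_xyz : (n, 3) deg/s, device frame.
    ibi : optional (m, 2) array of (t_s, inter-beat interval ms).
    """

    subject_id: str
    body_location: str
    sample_rate_hz: float
    t: np.ndarray
    accel_xyz: np.ndarray
    gyro_xyz: np.ndarray
    ibi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.body_location = normalize_location(self.body_location)
        self.t = np.asarray(self.t, dtype=float)
        self.accel_xyz = np.asarray(self.accel_xyz, dtype=float)
        self.gyro_xyz = np.asarray(self.gyro_xyz, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        n = self.t.shape[0]
        if self.accel_xyz.shape != (n, 3) or self.gyro_xyz.shape != (n, 3):
            raise ValidationError("channel arrays must all have length n x 3")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("non-monotone timestamps")
        if self.ibi is not None:
            self.ibi = np.asarray(self.ibi, dtype=float)
            if self.ibi.ndim != 2 or self.ibi.shape[1] != 2:
                raise ValidationError("ibi must be an (m, 2) array of (t, ms)")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def segments(self) -> list[slice]:
        """Contiguous index ranges; a gap > 2 sample periods splits them."""
        if self.t.size == 0:
            return []
        gap = 2.0 / self.sample_rate_hz
        breaks = np.where(np.diff(self.t) > gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks + 1, [self.t.size]])
        return [slice(int(a), int(b)) for a, b in zip(starts, stops)]

    def slice(self, start_s: float, end_s: float) -> "SensorRecording":
        """Half-open [start_s, end_s) sub-recording (sample times toward the
        window interior)."""
        mask = (self.t >= start_s) & (self.t < end_s)
        ibi = None
        if self.ibi is not None:
            m = (self.ibi[:, 0] >= start_s) & (self.ibi[:, 0] < end_s)
            ibi = self.ibi[m]
        return SensorRecording(
            self.subject_id, self.body_location, self.sample_rate_hz,
            self.t[mask], self.accel_xyz[mask], self.gyro_xyz[mask], ibi,
        )


_SENSOR_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


def read_sensor_csv(path: str | Path) -> SensorRecording:
    """Read a sensor CSV (see module docstring for the dialect).

    Metadata lines: ``# subject: S01``, ``# location: left_ankle``,
    ``# sample_rate_hz: 100``. Optional ``ibi_ms`` column: rows with a value
    there carry one inter-beat interval at that row's ``t``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip().lower()] = value.strip()
            else:
                body.append(line)
    for key in ("subject", "location", "sample_rate_hz"):
        if key not in meta:
            raise FormatError(f"missing metadata line '# {key}: ...' in {path}")
    df = pd.read_csv(io.StringIO("".join(body)))
    missing = [c for c in _SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing} in {path}")
    ibi = None
    if "ibi_ms" in df.columns:
        rows = df[df["ibi_ms"].notna()]
        if len(rows):
            ibi = rows[["t", "ibi_ms"]].to_numpy(dtype=float)
    try:
        rate = float(meta["sample_rate_hz"])
    except ValueError as exc:
        raise FormatError(f"bad sample rate {meta['sample_rate_hz']!r}") from exc
    return SensorRecording(
        subject_id=meta["subject"],
        body_location=meta["location"],
        sample_rate_hz=rate,
        t=df["t"].to_numpy(dtype=float),
        accel_xyz=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro_xyz=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        ibi=ibi,
    )


def write_sensor_csv(recording: SensorRecording, path: str | Path) -> None:
    """Write a recording; floats at 6 significant digits."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([recording.t, recording.accel_xyz, recording.gyro_xyz]),
        columns=_SENSOR_COLUMNS,
    )
    if recording.ibi is not None and len(recording.ibi):
        ser = pd.Series(np.nan, index=df.index)
        idx = np.searchsorted(recording.t, recording.ibi[:, 0])
        idx = np.clip(idx, 0, len(df) - 1)
        ser.iloc[idx] = recording.ibi[:, 1]
        df["ibi_ms"] = ser
        # IBIs are stored on the nearest sample row; exact round-trip of IBI
        # timestamps therefore requires them to lie on the sample grid
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# subject: {recording.subject_id}\n")
        fh.write(f"# location: {recording.body_location}\n")
        fh.write(f"# sample_rate_hz: {recording.sample_rate_hz:.6g}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# SessionAnnotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationInterval:
    label: str
    start_s: float
    end_s: float
    rep: int | None = None  # repeat index for tug (1-3)

    def __post_init__(self) -> None:
        if self.label not in ANNOTATION_LABELS:
            raise ValidationError(f"unknown annotation label: {self.label!r}")
        if not self.end_s > self.start_s:
            raise ValidationError("interval end must exceed start")
        if self.label == "balance_30s" and not (25.0 <= self.end_s - self.start_s <= 35.0):
            raise ValidationError("balance_30s interval must last 25-35 s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SessionAnnotation:
    """Ordered, non-overlapping task intervals for one device stream."""

    subject_id: str
    device: str
    intervals: list[AnnotationInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start_s)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(
                    f"overlapping intervals: {a.label} and {b.label}")

    def by_label(self, label: str) -> list[AnnotationInterval]:
        return [iv for iv in self.intervals if iv.label == label]

    @property
    def span(self) -> tuple[float, float] | None:
        if not self.intervals:
            return None
        return self.intervals[0].start_s, self.intervals[-1].end_s


def read_annotations(path: str | Path) -> SessionAnnotation:
    try:
        raw = json.loads(Path(path).read_text(encoding="utf-8") or "{}")
    except json.JSONDecodeError as exc:
        raise FormatError(f"bad annotation JSON: {exc}") from exc
    intervals = [
        AnnotationInterval(
            label=iv["label"], start_s=float(iv["start_s"]),
            end_s=float(iv["end_s"]), rep=iv.get("rep"),
        )
        for iv in raw.get("intervals", [])
    ]
    return SessionAnnotation(
        subject_id=raw.get("subject", ""), device=raw.get("device", ""),
        intervals=intervals,
    )


def write_annotations(annotation: SessionAnnotation, path: str | Path) -> None:
    payload = {
        "subject": annotation.subject_id,
        "device": annotation.device,
        "intervals": [
            {"label": iv.label, "start_s": iv.start_s, "end_s": iv.end_s,
             **({"rep": iv.rep} if iv.rep is not None else {})}
            for iv in annotation.intervals
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Clinical score table
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = ["subject", "visit", "edss", "t25fw_s", "nhpt_s",
                     "sdmt_correct", "lcva_correct"]


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Per-subject-visit raw clinical scores.

    Columns: subject, visit, edss, t25fw_s, nhpt_s, sdmt_correct,
    lcva_correct (+ optional extras, e.g. a daily fatigue ordinal).
    """
    df = pd.read_csv(path)
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing clinical columns {missing}")
    bad = [v for v in df["edss"] if not math.isnan(v) and v not in EDSS_GRID]
    if bad:
        raise ValidationError(
            f"EDSS values off the 0.5-step grid 0-10: {sorted(set(bad))}")
    for col in ("t25fw_s", "nhpt_s"):
        if (df[col].dropna() <= 0).any():
            raise ValidationError(f"{col} must be positive")
    for col in ("sdmt_correct", "lcva_correct"):
        if (df[col].dropna() < 0).any():
            raise ValidationError(f"{col} must be non-negative")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PVT log
# ---------------------------------------------------------------------------

@dataclass
class PvtLog:
    """Psychomotor Vigilance Task reaction-time log for one ~3-min session."""

    subject_id: str
    session_t: str | float
    delay_ms: np.ndarray
    false_start: np.ndarray

    def __post_init__(self) -> None:
        self.delay_ms = np.asarray(self.delay_ms, dtype=float)
        self.false_start = np.asarray(self.false_start, dtype=bool)
        if self.delay_ms.shape != self.false_start.shape:
            raise ValidationError("delay_ms and false_start lengths differ")
        if np.any(self.delay_ms[~self.false_start] < 0):
            raise ValidationError("delays must be non-negative")

    @property
    def valid_delays_ms(self) -> np.ndarray:
        return self.delay_ms[~self.false_start]


def read_pvt_log(path: str | Path) -> list[PvtLog]:
    """Read a PVT CSV (subject, session_t, challenge_idx, delay_ms,
    false_start); one ``PvtLog`` per (subject, session_t), challenges ordered
    by index."""
    df = pd.read_csv(path)
    needed = ["subject", "session_t", "challenge_idx", "delay_ms", "false_start"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"missing PVT columns {missing}")
    logs = []
    for (subject, session), grp in df.groupby(["subject", "session_t"], sort=True):
        grp = grp.sort_values("challenge_idx")
        logs.append(PvtLog(
            subject_id=str(subject), session_t=session,
            delay_ms=grp["delay_ms"].to_numpy(dtype=float),
            false_start=grp["false_start"].to_numpy(dtype=bool),
        ))
    return logs


def write_pvt_log(logs: Iterable[PvtLog], path: str | Path) -> None:
    rows = []
    for log in logs:
        for i, (d, fs_) in enumerate(zip(log.delay_ms, log.false_start)):
            rows.append({"subject": log.subject_id, "session_t": log.session_t,
                         "challenge_idx": i, "delay_ms": d, "false_start": fs_})
    pd.DataFrame(rows).to_csv(path, index=False)
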