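"""Slice an in-clinic recording into task analysis windows.

Annotation-driven slicing is exact (half-open [start, end), sample boundaries
rounded toward the window interior). When no annotation is available, a
signal-energy fallback finds alternating quiet/active windows from the 1-s
rolling RMS of the gravity-subtracted accelerometer magnitude and labels them
by the canonical protocol order: stand, 30-s balance, sit, three TUG repeats,
2-min walk. Auto labels are assigned by order, not content, and carry a
reduced confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SegmentationConfig
from .io_formats import SensorRecording, SessionAnnotation, ValidationError
from .synthetic_cohort import GRAVITY_MS2


@dataclass(frozen=True)
class TaskWindow:
    label: str
    start_s: float
    end_s: float
    source: str = "annotation"   # "annotation" | "auto"
    rep: int | None = None
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError("window end must exceed start")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError("confidence must be in [0, 1]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# canonical in-clinic protocol order used to label auto-detected windows
_CANONICAL_ACTIVE = ["tug", "tug", "tug", "walk_2min"]
_CANONICAL_QUIET = ["stand", "balance_30s", "sit"]
_AUTO_CONFIDENCE = 0.5


def segment_session(recording: SensorRecording,
                    annotation: SessionAnnotation | None = None,
                    config: SegmentationConfig | None = None) -> list[TaskWindow]:
    """Return ordered, non-overlapping task windows for one recording."""
    config = config or SegmentationConfig()
    if annotation is not None and annotation.intervals:
        span = annotation.span
        if span[0] < recording.t[0] - 1e-9 or span[1] > recording.t[-1] + 1.0 / recording.sample_rate_hz:
            raise ValidationError("annotation extends beyond the recording")
        return [TaskWindow(iv.label, iv.start_s, iv.end_s, "annotation", iv.rep)
                for iv in annotation.intervals]
    return _auto_segment(recording, config)


def _auto_segment(recording: SensorRecording,
                  config: SegmentationConfig) -> list[TaskWindow]:
    if recording.duration_s < config.min_auto_duration_s:
        raise ValidationError(
            f"auto segmentation needs >= {config.min_auto_duration_s:.0f} s of data")
    fs = recording.sample_rate_hz
    mag = np.linalg.norm(recording.accel_xyz, axis=1) - GRAVITY_MS2
    win = max(1, int(round(config.rms_window_s * fs)))
    # centered rolling RMS via cumulative sums
    sq = np.concatenate([[0.0], np.cumsum(mag ** 2)])
    idx = np.arange(mag.size)
    lo = np.clip(idx - win // 2, 0, mag.size)
    hi = np.clip(idx + win // 2 + 1, 0, mag.size)
    rms = np.sqrt((sq[hi] - sq[lo]) / np.maximum(hi - lo, 1))
    active = rms > config.active_threshold_ms2

    # contiguous runs of the binary activity signal
    changes = np.where(np.diff(active.astype(int)) != 0)[0] + 1
    starts = np.concatenate([[0], changes])
    stops = np.concatenate([changes, [active.size]])
    windows: list[TaskWindow] = []
    qi = ai = 0
    for a, b in zip(starts, stops):
        start_t = float(recording.t[a])
        end_t = float(recording.t[b - 1] + 1.0 / fs)
        if active[a]:
            label = _CANONICAL_ACTIVE[ai] if ai < len(_CANONICAL_ACTIVE) else "other"
            rep = ai + 1 if label == "tug" else None
            ai += 1
        else:
            label = _CANONICAL_QUIET[qi] if qi < len(_CANONICAL_QUIET) else "other"
            # an auto quiet window cannot satisfy the balance-duration
            # invariant unless it actually lasts 25-35 s
            if label == "balance_30s" and not 25.0 <= end_t - start_t <= 35.0:
                label = "other"
            rep = None
            qi += 1
        windows.append(TaskWindow(label, start_t, end_t, "auto", rep,
                                  _AUTO_CONFIDENCE))
    return windows
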