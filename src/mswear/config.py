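"""Configuration objects for every stage of the pipeline.

Each extractor has a small dataclass holding its thresholds; the defaults here
are the documented defaults used throughout the package and by the CLI.
``RunConfig`` bundles everything needed for an end-to-end run and round-trips
through YAML so a run's exact configuration can be archived with its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class GaitConfig:
    """Gait event detection from ankle sagittal angular velocity."""

    band_hz: tuple[float, float] = (0.5, 6.0)  # 4th-order zero-phase band-pass
    peak_threshold_deg_s: float = 40.0         # mid-swing peak height
    edge_threshold_deg_s: float = 10.0         # toe-off / heel-strike crossing
    min_peak_separation_s: float = 0.4
    refine_edges: bool = True                  # half-amplitude sub-sample refinement
    refine_lowpass_hz: float = 10.0            # shape-preserving smoother for edges
    min_fs_hz: float = 20.0
    min_strides_for_summary: int = 3


@dataclass
class TurnConfig:
    """Turn detection from chest or ankle yaw rate."""

    lowpass_hz: float = 1.5
    enter_threshold_deg_s: float = 15.0
    exit_threshold_deg_s: float = 5.0
    merge_gap_s: float = 0.2
    min_angle_deg: float = 45.0
    min_fs_hz: float = 10.0
    # mean velocity of a turn: |angle|/duration (default) or mean |yaw| in event
    mean_velocity_mode: str = "angle_over_duration"


@dataclass
class SwayConfig:
    """Postural sway during the 30-s balance window."""

    band_hz: tuple[float, float] = (0.1, 2.0)  # accelerometer path band-pass
    min_duration_s: float = 20.0


@dataclass
class SegmentationConfig:
    """Auto (annotation-free) segmentation of the clinic session."""

    rms_window_s: float = 1.0
    active_threshold_ms2: float = 0.5   # RMS of |a|-g above this -> active
    min_auto_duration_s: float = 60.0


@dataclass
class ActivityConfig:
    """Free-living activity classification (threshold classifier)."""

    window_s: float = 5.0
    hop_s: float = 5.0
    idle_var_threshold: float = 0.01      # (m/s^2)^2 accel-magnitude variance
    walk_band_hz: tuple[float, float] = (0.6, 1.4)
    run_band_hz: tuple[float, float] = (1.4, 3.5)
    periodicity_threshold: float = 0.25   # dominant-peak share of band power
    run_magnitude_threshold: float = 2.0  # accel-magnitude std for running
    smoothing_windows: int = 3            # majority vote
    wear_var_floor: float = 1e-4          # worn if var above this or gyro active
    min_strides_per_day: int = 10


@dataclass
class SleepConfig:
    """HRV epochs, REM staging stand-in, and leg-movement detection."""

    epoch_s: float = 300.0
    min_beats_per_epoch: int = 30
    ibi_valid_ms: tuple[float, float] = (300.0, 2000.0)
    ectopic_fraction: float = 0.20        # vs running median
    ectopic_median_window: int = 11
    rem_rmssd_threshold_ms: float = 32.5  # midpoint of planted NREM/REM RMSSD
    stage_smoothing_epochs: int = 3
    min_valid_epochs: int = 6
    movement_band_hz: tuple[float, float] = (0.5, 10.0)
    movement_threshold_ms2: float = 0.1
    movement_min_duration_s: float = 0.5
    movement_refractory_s: float = 5.0


@dataclass
class StatsConfig:
    """Correlation-table statistics."""

    qvalue_mode: str = "storey"        # "storey" or "bh" (pi0 forced to 1)
    nhpt_mode: str = "neg_z"           # "neg_z" or "inv_time" MSFC convention
    min_pairs: int = 4
    alpha_levels: tuple[float, float] = (0.05, 0.01)


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; serialized alongside the outputs."""

    seed: int = 0
    n_subjects: int = 23
    free_living_days: int = 56
    day_minutes: float = 120.0       # simulated daytime wear stream per day
    night_hours: float = 7.0
    fs_clinic_hz: float = 100.0
    fs_free_hz: float = 30.0
    effect_noise_scale: float = 1.0
    target_wear_hours_per_week: float = 84.0  # 12 h/day protocol target
    out_dir: str = "mswear_output"
    walk_test_duration_s: float = 120.0
    gait: GaitConfig = field(default_factory=GaitConfig)
    turns: TurnConfig = field(default_factory=TurnConfig)
    sway: SwayConfig = field(default_factory=SwayConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    sleep: SleepConfig = field(default_factory=SleepConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3 (correlation precondition)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        sub = {
            "gait": GaitConfig, "turns": TurnConfig, "sway": SwayConfig,
            "segmentation": SegmentationConfig, "activity": ActivityConfig,
            "sleep": SleepConfig, "stats": StatsConfig,
        }
        for key, value in raw.items():
            if key in sub:
                f = {x.name for x in dataclasses.fields(sub[key])}
                unknown = set(value) - f
                if unknown:
                    raise ValueError(f"unknown {key} config keys: {sorted(unknown)}")
                value = {k: tuple(v) if isinstance(v, list) else v for k, v in value.items()}
                kwargs[key] = sub[key](**value)
            elif key in {x.name for x in dataclasses.fields(cls)}:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key: {key}")
        return cls(**kwargs)
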