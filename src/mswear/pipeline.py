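"""End-to-end orchestration: simulate -> extract -> correlate -> report.

The clinic feature table carries exactly the 23 in-clinic biosensor and
structured-testing features, named as they are reported; the free-living
table carries the seven free-living features. Outputs are plain CSV plus a
manifest with SHA-256 checksums and the archived run configuration, so a
run is reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .balance import compute_sway
from .config import RunConfig
from .freeliving import DailyFeatures, compliance, summarize_day
from .gait import detect_gait_events
from .io_formats import (SensorRecording, read_annotations, read_clinical_table,
                         read_pvt_log, read_sensor_csv, write_annotations,
                         write_clinical_table, write_pvt_log, write_sensor_csv)
from .segmentation import segment_session
from .sleep_fatigue import (estimate_rem_percent, filter_ectopic, hrv_epochs,
                            leg_movement_rate, pvt_features)
from .stats import correlation_table, msfc4_scores, variability_vs_days
from .synthetic_cohort import (GYRO_SAGITTAL_AXIS, GYRO_YAW_AXIS, ClinicSession,
                               Cohort, EffectConfig, simulate_cohort)
from .turns import detect_turns, summarize_turns

logger = logging.getLogger("mswear")

CLINIC_FEATURES = [
    "Stance time", "Swing time", "Mobility activity time",
    "Turn angle—chest", "Turn duration—chest", "Turn velocity (max)—chest",
    "Turn velocity (mean)—chest", "Turn velocity (std)—chest",
    "Turn angle—ankle", "Turn duration—ankle", "Turn velocity (max)—ankle",
    "Turn velocity (mean)—ankle", "Turn velocity (std)—ankle",
    "Sway distance left–right", "Sway distance anterior–posterior",
    "Sway displacement left–right", "Sway displacement anterior–posterior",
    "Heart rate variability",
    "Mean PVT delay—Total", "Mean PVT delay—1 challenge",
    "Mean PVT delay—3 challenges", "Mean PVT delay—5 challenges",
    "Mean PVT delay—7 challenges",
]

FREELIVING_FEATURES = [
    "Stance time", "Turn angle—chest", "Swing time", "Mean PVT Delay",
    "Movement rate of legs during sleep", "REM percent", "Idle minutes",
]

CLINICAL_MEASURES = [
    "EDSS", "MSFC-4 z-score", "25 foot walk z-score",
    "9-hole peg test z-score", "Symbol-digit modality test z-score",
    "LCVA test z-score",
]


# ---------------------------------------------------------------------------
# Clinic feature extraction
# ---------------------------------------------------------------------------


def extract_clinic_features(session: ClinicSession,
                            config: RunConfig | None = None) -> dict[str, float]:
    """The 23 in-clinic features for one subject's structured session."""
    config = config or RunConfig()
    ankle_locs = [loc for loc in ("left_ankle", "right_ankle")
                  if loc in session.recordings]
    reference = session.recordings[ankle_locs[0] if ankle_locs else
                                   next(iter(session.recordings))]
    windows = segment_session(reference, session.annotation,
                              config.segmentation)
    tug_windows = [w for w in windows if w.label == "tug"]
    walk_windows = [w for w in windows if w.label == "walk_2min"]
    balance_windows = [w for w in windows if w.label == "balance_30s"]
    mobility = tug_windows + walk_windows

    out: dict[str, float] = {name: float("nan") for name in CLINIC_FEATURES}

    # gait: pooled over both ankles and all mobility windows
    stances, swings = [], []
    for loc in ankle_locs:
        rec = session.recordings[loc]
        for w in mobility:
            sub = rec.slice(w.start_s, w.end_s)
            if sub.t.size < int(2 * sub.sample_rate_hz):
                continue
            for s in detect_gait_events(sub.gyro_xyz[:, GYRO_SAGITTAL_AXIS],
                                        sub.sample_rate_hz, config.gait,
                                        t=sub.t, foot=loc.split("_")[0]):
                swings.append(s.swing_time_s)
                if s.complete:
                    stances.append(s.stance_time_s)
    if stances:
        out["Stance time"] = float(np.median(stances))
    if swings:
        out["Swing time"] = float(np.median(swings))
    if tug_windows:
        out["Mobility activity time"] = float(
            np.mean([w.duration_s for w in tug_windows]))

    # turns from chest and ankle yaw inside TUG windows
    for label, locs in (("chest", ["chest"]), ("ankle", ankle_locs[:1])):
        events = []
        for loc in locs:
            rec = session.recordings.get(loc)
            if rec is None:
                continue
            for w in tug_windows:
                sub = rec.slice(w.start_s, w.end_s)
                if sub.t.size < int(sub.sample_rate_hz):
                    continue
                events.extend(detect_turns(sub.gyro_xyz[:, GYRO_YAW_AXIS],
                                           sub.sample_rate_hz, config.turns,
                                           t=sub.t, source_location=label))
        summary = summarize_turns(events)
        if summary.n_turns:
            out[f"Turn angle—{label}"] = summary.mean_angle_deg
            out[f"Turn duration—{label}"] = summary.mean_duration_s
            out[f"Turn velocity (max)—{label}"] = summary.velocity_max_deg_s
            out[f"Turn velocity (mean)—{label}"] = summary.velocity_mean_deg_s
            out[f"Turn velocity (std)—{label}"] = summary.velocity_std_deg_s

    # postural sway from the chest accelerometer during balance
    chest = session.recordings.get("chest")
    if chest is not None and balance_windows:
        w = balance_windows[0]
        sub = chest.slice(w.start_s, w.end_s)
        metrics = compute_sway(sub.accel_xyz, sub.sample_rate_hz, w,
                               config.sway)
        out["Sway distance left–right"] = metrics.sway_distance_ml_mm
        out["Sway distance anterior–posterior"] = metrics.sway_distance_ap_mm
        out["Sway displacement left–right"] = metrics.sway_displacement_ml_mm
        out["Sway displacement anterior–posterior"] = metrics.sway_displacement_ap_mm

    # heart rate variability: session RMSSD of the chest IBI stream
    if chest is not None and chest.ibi is not None and len(chest.ibi) > 3:
        _, ibi = filter_ectopic(chest.ibi[:, 1], chest.ibi[:, 0], config.sleep)
        if ibi.size > 3:
            out["Heart rate variability"] = float(
                np.sqrt(np.mean(np.diff(ibi) ** 2)))

    pvt = pvt_features(session.pvt_log)
    out["Mean PVT delay—Total"] = pvt.mean_delay_total_ms
    out["Mean PVT delay—1 challenge"] = pvt.mean_delay_first_1_ms
    out["Mean PVT delay—3 challenges"] = pvt.mean_delay_first_3_ms
    out["Mean PVT delay—5 challenges"] = pvt.mean_delay_first_5_ms
    out["Mean PVT delay—7 challenges"] = pvt.mean_delay_first_7_ms
    return out


def clinic_feature_table(sessions: dict[str, ClinicSession],
                         config: RunConfig | None = None) -> pd.DataFrame:
    """Subjects x 23 clinic features; a failing subject is logged and
    excluded rather than aborting the run."""
    rows = {}
    for sid, session in sessions.items():
        try:
            rows[sid] = extract_clinic_features(session, config)
        except Exception:
            logger.exception("clinic extraction failed for %s; excluded", sid)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject"
    return df[CLINIC_FEATURES]


def clinical_measures_table(clinical: pd.DataFrame,
                            config: RunConfig | None = None) -> pd.DataFrame:
    """Subjects x 6 clinical measures (EDSS + MSFC-4 composite and
    subscore z-scores), cohort-referenced."""
    config = config or RunConfig()
    scored = msfc4_scores(clinical, config=config.stats)
    out = pd.DataFrame({
        "subject": scored["subject"],
        "EDSS": scored["edss"],
        "MSFC-4 z-score": scored["msfc4_composite"],
        "25 foot walk z-score": scored["z_25fw"],
        "9-hole peg test z-score": scored["z_9hpt"],
        "Symbol-digit modality test z-score": scored["z_sdmt"],
        "LCVA test z-score": scored["z_lcva"],
    }).set_index("subject")
    return out[CLINICAL_MEASURES]


# ---------------------------------------------------------------------------
# Free-living extraction
# ---------------------------------------------------------------------------


def freeliving_tables(cohort: Cohort, config: RunConfig | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject free-living feature table (period medians/means) and the
    per-day table used for the variability-vs-days analysis."""
    config = config or RunConfig()
    daily_rows = []
    feat_rows = {}
    for sid in sorted(cohort.days):
        days: list[DailyFeatures] = []
        for day in cohort.days[sid]:
            try:
                days.append(summarize_day(sid, day.day_index, day.recordings,
                                          config.activity, config.gait,
                                          config.turns))
            except Exception:
                logger.exception("day %s of %s failed; excluded",
                                 day.day_index, sid)
        for df_ in days:
            daily_rows.append({
                "subject": sid, "day_index": df_.day_index,
                "median_stance_time_s": df_.median_stance_time_s,
                "median_swing_time_s": df_.median_swing_time_s,
                "idle_minutes": df_.idle_minutes,
                "worn_hours": df_.worn_hours,
                "turn_mean_angle_deg": df_.turn_mean_angle_deg,
            })
        rem_percents, leg_rates = [], []
        for night in cohort.nights.get(sid, []):
            try:
                epochs = hrv_epochs(night.ibi_t_s, night.ibi_ms,
                                    config=config.sleep)
                rem, _ = estimate_rem_percent(epochs, config.sleep)
                rem_percents.append(rem)
                rate, _ = leg_movement_rate(night.ankle_accel, night.ankle_fs,
                                            config.sleep)
                leg_rates.append(rate)
            except Exception:
                logger.exception("night %s of %s failed; excluded",
                                 night.day_index, sid)
        pvt_means = [pvt_features(day.pvt_log).mean_delay_total_ms
                     for day in cohort.days[sid]]

        def _agg(values, fn) -> float:
            finite = [v for v in values if not np.isnan(v)]
            return float(fn(finite)) if finite else float("nan")

        feat_rows[sid] = {
            "Stance time": _agg([d.median_stance_time_s for d in days], np.median),
            "Turn angle—chest": _agg([d.turn_mean_angle_deg for d in days], np.mean),
            "Swing time": _agg([d.median_swing_time_s for d in days], np.median),
            "Mean PVT Delay": _agg(pvt_means, np.mean),
            "Movement rate of legs during sleep": _agg(leg_rates, np.mean),
            "REM percent": _agg(rem_percents, np.mean),
            "Idle minutes": _agg([d.idle_minutes for d in days], np.mean),
        }
    features = pd.DataFrame.from_dict(feat_rows, orient="index")
    features.index.name = "subject"
    if not features.empty:
        features = features[FREELIVING_FEATURES]
    return features, pd.DataFrame(daily_rows)


# ---------------------------------------------------------------------------
# Cohort file I/O (simulate subcommand output)
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write a cohort to disk in the package's on-disk formats, plus a
    manifest and a ground-truth sidecar."""
    out = Path(out_dir)
    (out / "clinic").mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def _note(p: Path) -> None:
        files.append(str(p.relative_to(out)))

    write_clinical_table(cohort.clinical, out / "clinical.csv")
    _note(out / "clinical.csv")
    pvt_logs = []
    for sid, session in cohort.sessions.items():
        for loc, rec in session.recordings.items():
            p = out / "clinic" / f"{sid}_{loc}.csv"
            write_sensor_csv(rec, p)
            _note(p)
        p = out / "clinic" / f"{sid}_annotation.json"
        write_annotations(session.annotation, p)
        _note(p)
        pvt_logs.append(session.pvt_log)
    if pvt_logs:
        write_pvt_log(pvt_logs, out / "clinic" / "pvt.csv")
        _note(out / "clinic" / "pvt.csv")
    if cohort.wear_hours_week is not None:
        cohort.wear_hours_week.to_csv(out / "wear_hours.csv", index=False)
        _note(out / "wear_hours.csv")
    truth = {
        "profiles": [vars(p) for p in cohort.profiles],
        "compliance": cohort.compliance_truth,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    _note(out / "ground_truth.json")
    manifest = {"files": sorted(files)}
    (out / "cohort_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_clinic_sessions(cohort_dir: str | Path) -> dict[str, ClinicSession]:
    """Re-assemble clinic sessions from a ``write_cohort`` directory."""
    root = Path(cohort_dir)
    pvt_by_subject = {log.subject_id: log
                      for log in read_pvt_log(root / "clinic" / "pvt.csv")}
    sessions: dict[str, ClinicSession] = {}
    for ann_path in sorted((root / "clinic").glob("*_annotation.json")):
        sid = ann_path.name.replace("_annotation.json", "")
        annotation = read_annotations(ann_path)
        recordings: dict[str, SensorRecording] = {}
        for csv_path in sorted((root / "clinic").glob(f"{sid}_*.csv")):
            rec = read_sensor_csv(csv_path)
            recordings[rec.body_location] = rec
        sessions[sid] = ClinicSession(sid, recordings, annotation,
                                      pvt_by_subject[sid], truth=None)
    return sessions


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Simulate, extract, correlate, and report; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    try:
        return _run_inner(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_inner(config: RunConfig, out: Path) -> dict:
    logger.info("simulating cohort: n=%d, %d free-living days",
                config.n_subjects, config.free_living_days)
    cohort = simulate_cohort(
        n_subjects=config.n_subjects,
        effect=EffectConfig(noise_scale=config.effect_noise_scale),
        seed=config.seed, clinic=True,
        free_living_days=config.free_living_days,
        day_minutes=config.day_minutes, night_hours=config.night_hours,
        fs_clinic=config.fs_clinic_hz, fs_free=config.fs_free_hz,
        walk_test_duration_s=config.walk_test_duration_s,
        target_wear_hours_per_week=config.target_wear_hours_per_week)

    outputs: list[Path] = []
    measures = clinical_measures_table(cohort.clinical, config)
    features = clinic_feature_table(cohort.sessions, config)
    clinic_corr = correlation_table(features, measures, config.stats)
    for name, df in (("clinical_measures.csv", measures),
                     ("clinic_features.csv", features),
                     ("clinic_correlations.csv", clinic_corr)):
        df.to_csv(out / name)
        outputs.append(out / name)

    if config.free_living_days > 0:
        fl_features, daily = freeliving_tables(cohort, config)
        # drop features too sparsely measured to correlate (short test runs)
        dense = [c for c in fl_features.columns
                 if fl_features[c].notna().sum() >= config.stats.min_pairs]
        if len(dense) < len(fl_features.columns):
            logger.warning("free-living features with too few subjects "
                           "excluded from correlation: %s",
                           sorted(set(fl_features.columns) - set(dense)))
        fl_corr = correlation_table(fl_features[dense], measures, config.stats)
        k_grid = [k for k in (1, 2, 3, 5, 7, 14, 28, 49)
                  if k <= config.free_living_days]
        daily_var = daily.rename(columns={"median_stance_time_s": "value"})
        curves = variability_vs_days(daily_var, k_grid, n_resamples=50,
                                     seed=config.seed)
        for name, df in (("freeliving_features.csv", fl_features),
                         ("freeliving_daily.csv", daily),
                         ("freeliving_correlations.csv", fl_corr),
                         ("variability_curves.csv", curves)):
            df.to_csv(out / name, index=(name == "freeliving_features.csv"))
            outputs.append(out / name)
        if cohort.wear_hours_week is not None:
            reports = []
            for sid, grp in cohort.wear_hours_week.groupby("subject"):
                rep = compliance(grp.sort_values("week")["worn_hours"].to_numpy(),
                                 config.target_wear_hours_per_week, sid)
                reports.append({"subject": sid, "group": rep.group})
            pd.DataFrame(reports).to_csv(out / "compliance.csv", index=False)
            outputs.append(out / "compliance.csv")
        _figures(out, features, measures, curves)
        for fig in ("fig_turn_velocity_vs_composite.png",
                    "fig_variability_vs_days.png"):
            if (out / fig).exists():
                outputs.append(out / fig)
    else:
        _figures(out, features, measures, None)
        if (out / "fig_turn_velocity_vs_composite.png").exists():
            outputs.append(out / "fig_turn_velocity_vs_composite.png")

    config.to_yaml(out / "config.yaml")
    outputs.append(out / "config.yaml")
    manifest = {"files": {str(p.relative_to(out)): _sha256(p)
                          for p in sorted(outputs)}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("run complete: %d output files", len(outputs))
    return manifest


def _figures(out: Path, features: pd.DataFrame, measures: pd.DataFrame,
             curves: pd.DataFrame | None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    joined = features.join(measures)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(joined["MSFC-4 z-score"], joined["Turn velocity (max)—chest"])
    ax.set_xlabel("MSFC-4 composite z-score")
    ax.set_ylabel("Mean max turn angular velocity (deg/s)")
    fig.tight_layout()
    fig.savefig(out / "fig_turn_velocity_vs_composite.png", dpi=100)
    plt.close(fig)

    if curves is not None and not curves.empty:
        cohort = curves[curves["subject"] == "__cohort__"]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(cohort["k_days"], cohort["se_median"], marker="o")
        ax.set_xlabel("days aggregated (k)")
        ax.set_ylabel("SE of k-day stance-time median (s)")
        fig.tight_layout()
        fig.savefig(out / "fig_variability_vs_days.png", dpi=100)
        plt.close(fig)
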