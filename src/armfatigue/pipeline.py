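"""End-to-end drivers: raw trial -> conditioned streams -> labeled
per-cycle feature table -> trained and ablated classifiers.

These are the functions the analysis scripts, the CLI and the
acceptance checks share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import modeling, signal_conditioning as sc
from .features import (SENSOR_BLOCKS, assemble_features,
                       canonical_feature_names, normalize_features)
from .modeling import ModelSpec, SplitPlan
from .segmentation import (StateBoundaries, detect_cycles, label_cycles,
                           slice_streams)
from .synthetic_cohort import SensorTrial

__all__ = [
    "ConditionedTrial",
    "condition_trial",
    "trial_features",
    "cohort_feature_table",
    "subject_trends",
    "run_classification",
]

METADATA_COLS = ("subject_id", "cycle", "borg", "state")


@dataclass
class ConditionedTrial:
    """Analysis-ready streams of one trial (native rates preserved)."""

    subject_id: str
    angle: sc.AngleSeries
    emg: sc.ConditionedEMG
    imu_wrist: pd.DataFrame
    imu_neck: pd.DataFrame
    borg_events: list[tuple[float, float]]


def condition_trial(trial: SensorTrial, angle_fc: float = 0.5,
                    emg_band: tuple[float, float] = (15.0, 450.0),
                    imu_window_ms: float = 30.0) -> ConditionedTrial:
    """Apply the full per-sensor conditioning chain to a raw trial."""
    cal = trial.calibration
    angle = sc.lowpass_angle(
        sc.calibrate_ofs(trial.ofs_voltage, cal, trial.fs_ofs), fc=angle_fc)
    emg = sc.condition_emg(trial.emg, cal.mvc_value, trial.fs_emg,
                           band=emg_band)
    wrist = sc.smooth_imu(
        sc.subtract_baseline(trial.imu_wrist, cal, "imu_wrist"),
        trial.fs_imu, imu_window_ms)
    neck = sc.smooth_imu(
        sc.subtract_baseline(trial.imu_neck, cal, "imu_neck"),
        trial.fs_imu, imu_window_ms)
    return ConditionedTrial(subject_id=trial.subject_id, angle=angle,
                            emg=emg, imu_wrist=wrist, imu_neck=neck,
                            borg_events=list(trial.borg_events))


def trial_features(trial: SensorTrial,
                   bounds: StateBoundaries = StateBoundaries(),
                   sensors=SENSOR_BLOCKS) -> pd.DataFrame:
    """Per-cycle labeled feature rows for one raw trial.

    Cycles are detected on the conditioned elbow angle; its peak times
    slice every other stream at its native rate.
    """
    cond = condition_trial(trial)
    windows = label_cycles(detect_cycles(cond.angle), cond.borg_events,
                           bounds)
    if not windows:
        return pd.DataFrame(columns=list(METADATA_COLS)
                            + canonical_feature_names(sensors))
    streams = {
        "angle": cond.angle.angle,
        "emg_bp": cond.emg.bandpassed,
        "emg_env": cond.emg.envelope_pct_mvc,
        "imu1": cond.imu_wrist,
        "imu2": cond.imu_neck,
    }
    rates = {"angle": cond.angle.rate, "emg_bp": cond.emg.rate,
             "emg_env": cond.emg.rate, "imu1": trial.fs_imu,
             "imu2": trial.fs_imu, "emg": cond.emg.rate}
    rows = []
    for segs in slice_streams(streams, rates, windows):
        w = segs["window"]
        feats = assemble_features(
            {"angle": segs["angle"], "emg_bp": segs["emg_bp"],
             "emg_env": segs["emg_env"], "imu1": segs["imu1"],
             "imu2": segs["imu2"], "duration": w.duration},
            rates, sensors=sensors)
        rows.append({"subject_id": trial.subject_id, "cycle": w.index,
                     "borg": w.borg, "state": w.state, **feats})
    return pd.DataFrame(rows)


def cohort_feature_table(trials, bounds: StateBoundaries = StateBoundaries(),
                         sensors=SENSOR_BLOCKS,
                         normalize: bool = True) -> pd.DataFrame:
    """Stacked per-cycle features for a cohort, first-cycle normalized.

    Normalization uses only each subject's own first cycle, so it can
    safely precede the train/test split without cross-subject leakage.
    """
    tables = [trial_features(t, bounds, sensors) for t in trials]
    table = pd.concat([t for t in tables if len(t)], ignore_index=True)
    if normalize:
        table = normalize_features(table)
    return table.reset_index(drop=True)


def subject_trends(table: pd.DataFrame,
                   columns=("EMG_mean", "EMG_IMNF", "FIB_tnorm", "FIB_ROM")
                   ) -> pd.DataFrame:
    """Per-subject linear trend slope of selected features over cycles.

    The slope sign is the fatigue fingerprint: EMG amplitude and cycle
    duration should rise with fatigue, EMG instantaneous frequency and
    range of motion should fall.
    """
    rows = []
    for subject, grp in table.groupby("subject_id"):
        grp = grp.sort_values("cycle")
        x = grp["cycle"].to_numpy(dtype=float)
        row = {"subject_id": subject}
        for col in columns:
            row[f"{col}_slope"] = float(np.polyfit(x, grp[col], 1)[0])
        rows.append(row)
    return pd.DataFrame(rows)


def run_classification(table: pd.DataFrame, seed: int = 0,
                       family: str = "lgbm", grid: dict | None = None,
                       ratio: float = 0.70, combos=None,
                       top_k: dict | None = None) -> dict:
    """Split, tune by LOOCV, evaluate, rank importance, ablate sensors.

    Returns a dict with the split plan, CV table, best hyperparameters,
    the all-sensor test report, the split-importance ranking and one
    report per sensor combo.
    """
    feature_cols = [c for c in canonical_feature_names()
                    if c in table.columns]
    plan = modeling.split_dataset(table["subject_id"], ratio=ratio,
                                  seed=seed)
    _assert_no_leakage(table, plan)
    spec = ModelSpec(family=family, grid=grid or {})
    search = modeling.loocv_grid_search(table, feature_cols, plan, spec,
                                        seed=seed)
    train_tab = table[table["subject_id"].isin(plan.train_subjects)]
    test_tab = table[table["subject_id"].isin(plan.test_subjects)]
    model = modeling.make_estimator(family, search.best_params, seed=seed)
    model.fit(train_tab[feature_cols], train_tab["state"])
    from .evaluation import build_report
    report = build_report(model, test_tab, feature_cols,
                          metadata={"sensor_combo": "all",
                                    "n_features": len(feature_cols),
                                    "family": family,
                                    "hyperparameters": search.best_params,
                                    "seed": seed})
    result = {"plan": plan, "cv_table": search.cv_table,
              "n_folds": search.n_folds,
              "best_params": search.best_params,
              "report_all_features": report}
    if family == "lgbm":
        result["importance"] = modeling.rank_importance(model, feature_cols)
        result["ablation"] = modeling.ablate_sensors(
            table, plan, search.best_params, combos=combos, top_k=top_k,
            seed=seed)
    return result


def _assert_no_leakage(table: pd.DataFrame, plan: SplitPlan) -> None:
    train = set(plan.train_subjects)
    test = set(plan.test_subjects)
    if train & test:
        raise AssertionError("subject leakage between partitions")
    uncovered = set(table["subject_id"]) - (train | test)
    if uncovered:
        warnings.warn(f"subjects outside both partitions: {uncovered}")
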