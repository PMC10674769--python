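"""On-disk cohort layout: one directory per subject of plain CSV/JSON.

Per subject: ``ofs.csv`` (time_s,voltage_v), ``emg.csv`` (time_s,emg_mv),
``imu_wrist.csv`` / ``imu_neck.csv`` (time_s + the six channel columns),
``borg.csv`` (time_s,rating) and ``calibration.json``; the cohort root
holds ``manifest.json`` with the seeds and parameters that regenerate it.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import (IMU_CHANNELS, CalibrationRecord, SensorTrial)

__all__ = ["write_cohort", "read_cohort", "write_trial", "read_trial"]


def write_trial(trial: SensorTrial, subject_dir: Path) -> None:
    subject_dir = Path(subject_dir)
    subject_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": trial.times("ofs"),
                  "voltage_v": trial.ofs_voltage}).to_csv(
        subject_dir / "ofs.csv", index=False)
    pd.DataFrame({"time_s": trial.times("emg"),
                  "emg_mv": trial.emg}).to_csv(
        subject_dir / "emg.csv", index=False)
    t_imu = trial.times("imu")
    for name, df in (("imu_wrist", trial.imu_wrist),
                     ("imu_neck", trial.imu_neck)):
        out = df.copy()
        out.insert(0, "time_s", t_imu)
        out.to_csv(subject_dir / f"{name}.csv", index=False)
    pd.DataFrame(trial.borg_events, columns=["time_s", "rating"]).to_csv(
        subject_dir / "borg.csv", index=False)
    cal = asdict(trial.calibration)
    cal["load_kg"] = trial.load_kg
    cal["fs"] = {"ofs": trial.fs_ofs, "emg": trial.fs_emg,
                 "imu": trial.fs_imu}
    cal["duration_s"] = trial.duration
    with open(subject_dir / "calibration.json", "w") as fh:
        json.dump(cal, fh, indent=2)


def read_trial(subject_dir: Path) -> SensorTrial:
    subject_dir = Path(subject_dir)
    with open(subject_dir / "calibration.json") as fh:
        cal = json.load(fh)
    fs = cal.pop("fs")
    duration = cal.pop("duration_s")
    load_kg = cal.pop("load_kg")
    calibration = CalibrationRecord(**cal)
    ofs = pd.read_csv(subject_dir / "ofs.csv")["voltage_v"].to_numpy()
    emg = pd.read_csv(subject_dir / "emg.csv")["emg_mv"].to_numpy()
    wrist = pd.read_csv(subject_dir / "imu_wrist.csv")[list(IMU_CHANNELS)]
    neck = pd.read_csv(subject_dir / "imu_neck.csv")[list(IMU_CHANNELS)]
    borg = pd.read_csv(subject_dir / "borg.csv")
    events = [(float(t), float(r))
              for t, r in zip(borg["time_s"], borg["rating"])]
    return SensorTrial(
        subject_id=subject_dir.name, duration=float(duration),
        fs_ofs=float(fs["ofs"]), fs_emg=float(fs["emg"]),
        fs_imu=float(fs["imu"]), ofs_voltage=ofs, emg=emg,
        imu_wrist=wrist, imu_neck=neck, borg_events=events,
        calibration=calibration, load_kg=float(load_kg))


def write_cohort(trials, manifest: dict, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for trial in trials:
        write_trial(trial, out_dir / trial.subject_id)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_cohort(in_dir: Path) -> tuple[list[SensorTrial], dict]:
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    trials = [read_trial(in_dir / t["subject_id"])
              for t in manifest["trials"]]
    return trials, manifest
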