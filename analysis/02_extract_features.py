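"""Condition, segment and featurize the cohort.

Reads the raw cohort written by 01_simulate_cohort.py, applies the
per-sensor conditioning chain (angle calibration + 0.5 Hz low-pass;
EMG 15-450 Hz band-pass, MVC normalization and 200 ms envelope; IMU
30 ms smoothing and baseline subtraction), detects repetition cycles on
the elbow angle, labels each cycle from the interpolated Borg ratings,
and writes the normalized per-cycle 63-feature table plus per-subject
fatigue-trend slopes to results/.

Run from the repository root:  python analysis/02_extract_features.py
"""

import argparse
from pathlib import Path

from armfatigue.io import read_cohort
from armfatigue.pipeline import cohort_feature_table, subject_trends


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", type=Path,
                    default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    trials, _ = read_cohort(args.in_dir)
    table = cohort_feature_table(trials)
    args.results.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.results / "features.csv", index=False)

    trends = subject_trends(table)
    trends.to_csv(args.results / "subject_trends.csv", index=False)

    states = table["state"].value_counts(normalize=True)
    print(f"{len(table)} repetition cycles from {len(trials)} subjects "
          f"({len(table) / len(trials):.1f} per subject)")
    print("state proportions: "
          + ", ".join(f"{s} {100 * states[s]:.1f}%"
                      for s in ("LF", "MOF", "HF")))
    frac = lambda col, sign: (sign * trends[col] > 0).mean()
    print("fatigue fingerprints (fraction of subjects with the expected "
          "trend sign):")
    print(f"  EMG envelope mean rises:      {frac('EMG_mean_slope', 1):.0%}")
    print(f"  EMG inst. mean freq falls:    {frac('EMG_IMNF_slope', -1):.0%}")
    print(f"  cycle duration lengthens:     {frac('FIB_tnorm_slope', 1):.0%}")
    print(f"  range of motion shrinks:      {frac('FIB_ROM_slope', -1):.0%}")
    print(f"feature table -> {args.results / 'features.csv'}")


if __name__ == "__main__":
    main()
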