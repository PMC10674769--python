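"""Train and compare the five tree-based classifier families.

Subject-wise 70:30 split, then leave-one-subject-out cross-validated
grid search per family on the training subjects, final refit and
held-out evaluation.  Writes the split, the per-candidate CV table, a
per-family test report and a comparison table to results/.

The gradient-boosted model (LightGBM) searches a small grid; the other
families use their single reference configuration, so the whole
comparison stays desk-scale.

Run from the repository root:  python analysis/03_train_models.py
(use --families lgbm for a quick run; rf's 1400 trees dominate the
full comparison's runtime)
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from armfatigue import modeling
from armfatigue.evaluation import build_report
from armfatigue.features import canonical_feature_names
from armfatigue.modeling import ModelSpec
from armfatigue.pipeline import _assert_no_leakage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path,
                    default=Path("results/features.csv"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--families", nargs="+",
                    default=["lgbm", "rf", "bc", "et", "dt"])
    args = ap.parse_args()

    table = pd.read_csv(args.features)
    cols = [c for c in canonical_feature_names() if c in table.columns]
    plan = modeling.split_dataset(table["subject_id"], ratio=0.70,
                                  seed=args.seed)
    _assert_no_leakage(table, plan)
    args.results.mkdir(parents=True, exist_ok=True)
    with open(args.results / "split.json", "w") as fh:
        json.dump(asdict(plan), fh, indent=2)
    print(f"{len(plan.train_subjects)} training subjects "
          f"({plan.train_subjects}) -> {len(plan.train_subjects)} LOOCV "
          f"folds; {len(plan.test_subjects)} held out for testing")

    train_tab = table[table["subject_id"].isin(plan.train_subjects)]
    test_tab = table[table["subject_id"].isin(plan.test_subjects)]
    comparison = []
    cv_tables = []
    for family in args.families:
        spec = ModelSpec(family=family)
        search = modeling.loocv_grid_search(table, cols, plan, spec,
                                            seed=args.seed)
        model = modeling.make_estimator(family, search.best_params,
                                        seed=args.seed)
        model.fit(train_tab[cols], train_tab["state"])
        report = build_report(model, test_tab, cols,
                              metadata={"family": family,
                                        "sensor_combo": "all",
                                        "hyperparameters": search.best_params,
                                        "seed": args.seed})
        with open(args.results / f"report_{family}.json", "w") as fh:
            json.dump(report, fh, indent=2)
        cv = search.cv_table.assign(family=family)
        cv_tables.append(cv)
        best_cv = cv["mean_accuracy"].max()
        mw = report["metrics_weighted"]
        comparison.append({
            "family": family,
            "cv_accuracy_pct": round(100 * best_cv, 1),
            "test_accuracy_pct": round(100 * mw["accuracy"], 1),
            "test_precision_pct": round(100 * mw["precision"], 1),
            "test_recall_pct": round(100 * mw["recall"], 1),
            "test_f1_pct": round(100 * mw["f1"], 1),
            "best_params": json.dumps(search.best_params),
        })
        print(f"{family}: CV {100 * best_cv:.1f}%, "
              f"test {100 * mw['accuracy']:.1f}% "
              f"with {search.best_params}")

    pd.concat(cv_tables, ignore_index=True).to_csv(
        args.results / "cv_results.csv", index=False)
    comp = pd.DataFrame(comparison)
    comp.to_csv(args.results / "model_comparison.csv", index=False)
    print("\n" + comp.drop(columns="best_params").to_string(index=False))
    print(f"\nreports and tables -> {args.results}/")


if __name__ == "__main__":
    main()
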