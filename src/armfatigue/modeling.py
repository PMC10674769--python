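"""Subject-wise splitting, LOOCV grid search, importance and ablation.

The unit of partitioning is the subject, never the cycle: a random
70:30 subject split feeds training and testing, and model selection
runs leave-one-subject-out cross-validation (one fold per training
subject) so no subject's cycles ever inform a model evaluated on them.

Five tree-based families are supported (gradient-boosted trees via
LightGBM, random forest, bagged trees, extremely randomized trees and a
single decision tree); the default hyperparameter grids are small
neighborhoods of well-performing settings so a full search stays
desk-scale.  Feature importance for the gradient-boosted model is split
importance: the number of times a feature is used to split across the
ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import (BaggingClassifier, ExtraTreesClassifier,
                              RandomForestClassifier)
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import ParameterGrid
from sklearn.tree import DecisionTreeClassifier

from .features import canonical_feature_names

__all__ = [
    "SENSOR_COMBOS",
    "DEFAULT_TOP_K",
    "SplitPlan",
    "ModelSpec",
    "train_test_counts",
    "split_dataset",
    "make_estimator",
    "loocv_grid_search",
    "rank_importance",
    "select_top_features",
    "ablate_sensors",
]

#: Sensor-subset protocol: each row of the ablation study.
SENSOR_COMBOS: dict[str, tuple[str, ...]] = {
    "emg": ("emg",),
    "ofs": ("ofs",),
    "imu1": ("imu1",),
    "imu2": ("imu2",),
    "imus": ("imu1", "imu2"),
    "imus+ofs": ("imu1", "imu2", "ofs"),
    "all": ("imu1", "imu2", "ofs", "emg"),
}

#: Default reduced feature count per combo (the ablation protocol rows).
DEFAULT_TOP_K: dict[str, int] = {
    "emg": 7, "ofs": 8, "imu1": 5, "imu2": 4,
    "imus": 10, "imus+ofs": 13, "all": 33,
}


@dataclass
class SplitPlan:
    """Subject-level train/test partition."""

    train_subjects: list[str]
    test_subjects: list[str]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(f"subjects in both partitions: {overlap}")


@dataclass
class ModelSpec:
    """A model family plus its hyperparameter grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {sorted(DEFAULT_GRIDS)}")
        if not self.grid:
            self.grid = {k: list(v)
                         for k, v in DEFAULT_GRIDS[self.family].items()}


DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "lgbm": {"num_leaves": [31, 181], "min_child_samples": [8, 20],
             "n_estimators": [100]},
    "rf": {"n_estimators": [1400], "max_depth": [40], "bootstrap": [False]},
    "bc": {"n_estimators": [10], "max_features": [0.7],
           "base_estimator_max_depth": [20]},
    "et": {"criterion": ["log_loss"], "n_estimators": [200]},
    "dt": {"criterion": ["gini"], "min_samples_leaf": [1],
           "min_samples_split": [8]},
}


def train_test_counts(n: int, ratio: float = 0.70) -> tuple[int, int]:
    """(train, test) sizes for an n-item pool at the given train ratio."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n_train = int(round(ratio * n))
    return n_train, n - n_train


def split_dataset(subject_ids, ratio: float = 0.70,
                  seed: int = 0) -> SplitPlan:
    """Seeded random subject-level 70:30 partition.

    All of a subject's cycles stay on one side of the split; 30 subjects
    at ratio 0.70 give 21 training and 9 test subjects.
    """
    ids = sorted(set(subject_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects to split")
    n_train, _ = train_test_counts(len(ids), ratio)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return SplitPlan(train_subjects=train, test_subjects=test,
                     ratio=ratio, seed=seed)


def make_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate one candidate estimator for a family."""
    params = dict(params)
    if family == "lgbm":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                              **params)
    if family == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "bc":
        depth = params.pop("base_estimator_max_depth", None)
        base = DecisionTreeClassifier(max_depth=depth, random_state=seed)
        return BaggingClassifier(estimator=base, random_state=seed,
                                 n_jobs=1, **params)
    if family == "et":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if family == "dt":
        return DecisionTreeClassifier(random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}")


@dataclass
class GridSearchResult:
    best_params: dict
    cv_table: pd.DataFrame  # one row per candidate
    n_folds: int


def loocv_grid_search(table: pd.DataFrame, feature_cols: list[str],
                      plan: SplitPlan, spec: ModelSpec,
                      seed: int = 0) -> GridSearchResult:
    """Grid search scored by leave-one-subject-out CV on the training side.

    Every candidate sees the same folds: each training subject in turn
    is held out, the model fits on the remaining subjects' cycles, and
    candidate quality is the mean held-out accuracy across folds (ties
    broken by mean weighted F1, then by grid order).  Folds whose
    training rows collapse to a single class are skipped with a warning.
    """
    train_tab = table[table["subject_id"].isin(plan.train_subjects)]
    if train_tab["subject_id"].nunique() < 2:
        raise ValueError("LOOCV needs at least 2 training subjects")
    candidates = list(ParameterGrid(spec.grid))
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    folds = sorted(train_tab["subject_id"].unique())
    rows = []
    for cand_idx, params in enumerate(candidates):
        accs, f1s = [], []
        for held_out in folds:
            fit_tab = train_tab[train_tab["subject_id"] != held_out]
            val_tab = train_tab[train_tab["subject_id"] == held_out]
            if fit_tab["state"].nunique() < 2:
                warnings.warn(
                    f"fold {held_out}: single-class training data; skipped")
                continue
            model = make_estimator(spec.family, params, seed=seed)
            model.fit(fit_tab[feature_cols], fit_tab["state"])
            pred = model.predict(val_tab[feature_cols])
            accs.append(accuracy_score(val_tab["state"], pred))
            f1s.append(f1_score(val_tab["state"], pred, average="weighted"))
        rows.append({"candidate": cand_idx, **params,
                     "mean_accuracy": float(np.mean(accs)),
                     "mean_f1_weighted": float(np.mean(f1s)),
                     "n_folds": len(accs)})
    cv_table = pd.DataFrame(rows)
    order = cv_table.sort_values(
        by=["mean_accuracy", "mean_f1_weighted", "candidate"],
        ascending=[False, False, True], kind="stable")
    best = dict(candidates[int(order.iloc[0]["candidate"])])
    return GridSearchResult(best_params=best, cv_table=cv_table,
                            n_folds=len(folds))


def rank_importance(model, feature_names: list[str]
                    ) -> list[tuple[str, int]]:
    """Split-importance ranking of a fitted gradient-boosted model.

    Counts how many times each feature is used to split across all trees
    of the LightGBM ensemble, sorted by descending count with ties in
    canonical feature order.
    """
    if not isinstance(model, LGBMClassifier):
        raise TypeError("split importance requires a fitted LGBMClassifier")
    counts = model.booster_.feature_importance(importance_type="split")
    if len(counts) != len(feature_names):
        raise ValueError("feature_names length does not match the model")
    order = sorted(range(len(feature_names)),
                   key=lambda i: (-int(counts[i]), i))
    return [(feature_names[i], int(counts[i])) for i in order]


def select_top_features(ranking: list[tuple[str, int]], k: int) -> list[str]:
    """First k feature names of an importance ranking (nested prefixes)."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} outside [1, {len(ranking)}]")
    return [name for name, _ in ranking[:k]]


def ablate_sensors(table: pd.DataFrame, plan: SplitPlan,
                   best_params: dict, combos=None,
                   top_k: dict[str, int] | None = None,
                   seed: int = 0) -> dict[str, dict]:
    """Retrain and evaluate the gradient-boosted model per sensor subset.

    For each combo the feature columns are restricted to that subset's
    sensors, importance is re-ranked on the training subjects, the top-k
    features are kept, the model is retrained and evaluated on the test
    subjects.  Returns one report dict per combo (see
    ``evaluation.build_report``).
    """
    from .evaluation import build_report  # local import to avoid a cycle

    combos = list(SENSOR_COMBOS) if combos is None else list(combos)
    top_k = dict(DEFAULT_TOP_K if top_k is None else top_k)
    train_tab = table[table["subject_id"].isin(plan.train_subjects)]
    test_tab = table[table["subject_id"].isin(plan.test_subjects)]
    reports: dict[str, dict] = {}
    for combo in combos:
        sensors = SENSOR_COMBOS[combo]
        cols = [c for c in canonical_feature_names(sensors)
                if c in table.columns]
        k = top_k.get(combo, len(cols))
        if k > len(cols):
            raise ValueError(
                f"combo {combo!r}: k={k} exceeds {len(cols)} features")
        ranker = make_estimator("lgbm", best_params, seed=seed)
        ranker.fit(train_tab[cols], train_tab["state"])
        ranking = rank_importance(ranker, cols)
        selected = select_top_features(ranking, k)
        model = make_estimator("lgbm", best_params, seed=seed)
        model.fit(train_tab[selected], train_tab["state"])
        reports[combo] = build_report(
            model, test_tab, selected,
            metadata={"sensor_combo": combo, "n_features": k,
                      "family": "lgbm", "hyperparameters": best_params,
                      "seed": seed})
    return reports
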