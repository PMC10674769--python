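"""Confusion matrices and classification metrics for the three states.

The confusion matrix is 3x3 with rows = true state and columns =
predicted state in the fixed order LF, MOF, HF.  Metrics follow the
usual multiclass definitions: accuracy is the diagonal fraction;
precision, recall and F1 are aggregated either micro (pool all
decisions — for single-label multiclass this makes precision = recall
= accuracy) or weighted by true-class support, which is what tabulated
results that show precision differing from accuracy imply.  Both modes
are reported side by side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .segmentation import STATES

__all__ = [
    "Metrics",
    "ModelReport",
    "confusion",
    "metrics",
    "build_report",
]


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        """Metrics on the 0-100 scale, rounded for tabulation."""
        return {k: round(100 * v, decimals)
                for k, v in (("accuracy", self.accuracy),
                             ("precision", self.precision),
                             ("recall", self.recall), ("f1", self.f1))}


def confusion(y_true, y_pred, labels=STATES) -> np.ndarray:
    """Count (true, predicted) pairs into a labels x labels matrix."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    index = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        cm[index[t], index[p]] += 1
    return cm


def metrics(cm: np.ndarray, averaging: str = "weighted") -> Metrics:
    """Accuracy / precision / recall / F1 from a confusion matrix.

    ``averaging`` is "micro" (pooled decisions) or "weighted"
    (support-weighted mean of per-class scores).  Classes absent from
    both truth and prediction contribute zero to weighted averages with
    a warning.
    """
    cm = np.asarray(cm)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)  # true-class support
    col = cm.sum(axis=0).astype(float)  # predicted-class totals
    accuracy = float(tp.sum() / n)
    if averaging == "micro":
        precision = recall = accuracy
    elif averaging == "weighted":
        absent = (row == 0) & (col == 0)
        if absent.any():
            warnings.warn("class absent from truth and prediction; "
                          "contributes zero to weighted metrics")
        with np.errstate(invalid="ignore", divide="ignore"):
            prec_c = np.where(col > 0, tp / np.maximum(col, 1e-300), 0.0)
            rec_c = np.where(row > 0, tp / np.maximum(row, 1e-300), 0.0)
        weights = row / n
        precision = float(np.sum(weights * prec_c))
        recall = float(np.sum(weights * rec_c))
    else:
        raise ValueError("averaging must be 'micro' or 'weighted'")
    if averaging == "weighted":
        with np.errstate(invalid="ignore", divide="ignore"):
            f1_c = np.where(prec_c + rec_c > 0,
                            2 * prec_c * rec_c
                            / np.maximum(prec_c + rec_c, 1e-300), 0.0)
        f1 = float(np.sum((row / n) * f1_c))
    else:
        f1 = (0.0 if precision + recall == 0
              else 2 * precision * recall / (precision + recall))
    return Metrics(accuracy=accuracy, precision=precision, recall=recall,
                   f1=f1, averaging=averaging)


@dataclass
class ModelReport:
    """Machine-readable evaluation of one trained model on test cycles."""

    family: str
    hyperparameters: dict
    sensor_combo: str
    features: list[str]
    confusion_matrix: list[list[int]]
    labels: tuple[str, ...]
    metrics_weighted: dict
    metrics_micro: dict
    n_test_cycles: int
    metadata: dict

    def to_json(self, path=None, **kwargs) -> str:
        payload = json.dumps(asdict(self), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def build_report(model, test_table: pd.DataFrame, feature_cols: list[str],
                 metadata: dict | None = None) -> dict:
    """Predict on the test cycles and assemble a full report dict.

    The report stores the confusion matrix plus both averaging modes of
    the metrics, all recomputable from the stored matrix, along with the
    hyperparameters and feature list used.
    """
    if len(test_table) == 0:
        raise ValueError("empty test set")
    missing = [c for c in feature_cols if c not in test_table.columns]
    if missing:
        raise ValueError(f"test table lacks model features: {missing}")
    metadata = dict(metadata or {})
    pred = model.predict(test_table[feature_cols])
    cm = confusion(test_table["state"], pred)
    report = ModelReport(
        family=metadata.pop("family", type(model).__name__),
        hyperparameters=metadata.pop("hyperparameters",
                                     getattr(model, "get_params", dict)()),
        sensor_combo=metadata.pop("sensor_combo", "all"),
        features=list(feature_cols),
        confusion_matrix=cm.tolist(),
        labels=STATES,
        metrics_weighted=asdict(metrics(cm, "weighted")),
        metrics_micro=asdict(metrics(cm, "micro")),
        n_test_cycles=int(cm.sum()),
        metadata=metadata,
    )
    return asdict(report)
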