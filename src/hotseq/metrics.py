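"""Confusion-matrix construction and binary evaluation metrics.

All metrics treat hot spots (HS) as the positive class. Degenerate 0/0 cells
yield an explicit undefined marker (NaN) rather than a silent 0 or 1, so a
predictor that never emits a class is loudly visible in reports.

AUROC is computed by the rank statistic — the probability that a random hot
spot receives a higher score than a random null spot, ties counted one half —
which equals trapezoidal integration of the ROC curve over all thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from hotseq.splitting import HS, NS

#: Explicit marker for metrics whose defining ratio is 0/0.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    """The four binary confusion cells (positive class = HS)."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


def _as_binary(values: Sequence) -> np.ndarray:
    array = np.asarray(values)
    if array.dtype.kind in "biu":
        return array.astype(int)
    return (array == HS).astype(int)


def confusion(predicted: Sequence, actual: Sequence) -> ConfusionCounts:
    """Count TP/TN/FP/FN between predicted and actual binary classes.

    Accepts "HS"/"NS" strings or 0/1 integers (1 = HS).
    """
    pred = _as_binary(predicted)
    act = _as_binary(actual)
    if pred.shape != act.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {act.shape}")
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (act == 1))),
        TN=int(np.sum((pred == 0) & (act == 0))),
        FP=int(np.sum((pred == 1) & (act == 0))),
        FN=int(np.sum((pred == 0) & (act == 1))),
    )


def _ratio(numerator: float, denominator: float) -> float:
    return numerator / denominator if denominator > 0 else UNDEFINED


def scalar_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall (TPR), FPR and F1 from confusion counts.

    accuracy  = (TP+TN) / (TP+TN+FP+FN)
    precision = TP / (TP+FP)
    recall    = TP / (TP+FN)
    FPR       = FP / (FP+TN)
    F1        = 2*precision*recall / (precision+recall)

    Cells with a zero denominator are reported as NaN (undefined), never
    coerced to 0.
    """
    if counts.total == 0:
        raise ValueError("no evaluated residues")
    precision = _ratio(counts.TP, counts.TP + counts.FP)
    recall = _ratio(counts.TP, counts.TP + counts.FN)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = UNDEFINED
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": _ratio(counts.TP + counts.TN, counts.total),
        "precision": precision,
        "recall": recall,
        "fpr": _ratio(counts.FP, counts.FP + counts.TN),
        "f1": f1,
    }


def auroc(hs_probabilities: Sequence[float], actual: Sequence) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Equals the probability that a uniformly random HS outranks a uniformly
    random NS, ties counted 1/2. Returns NaN when only one class is present.
    """
    scores = np.asarray(hs_probabilities, dtype=float)
    act = _as_binary(actual)
    n_pos = int(act.sum())
    n_neg = int(act.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return UNDEFINED
    ranks = rankdata(scores)
    rank_sum_pos = ranks[act == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metrics_report(
    predicted: Sequence,
    actual: Sequence,
    hs_probabilities: Sequence[float] | None = None,
) -> dict[str, float]:
    """Scalar metrics plus AUROC (when probabilities are given) in one dict."""
    counts = confusion(predicted, actual)
    report = scalar_metrics(counts)
    report["auroc"] = auroc(hs_probabilities, actual) if hs_probabilities is not None else UNDEFINED
    report.update({"TP": counts.TP, "TN": counts.TN, "FP": counts.FP, "FN": counts.FN})
    return report


def weighted_metrics(predicted: Sequence, actual: Sequence) -> dict[str, float]:
    """Class-frequency-weighted averages of per-class precision/recall/F1.

    The alternative aggregation convention some benchmark tables use: each
    class's one-vs-rest metric weighted by its support, alongside plain
    accuracy. Emitted for comparison only; the HS-centric binary metrics of
    :func:`scalar_metrics` are the primary convention.
    """
    pred = _as_binary(predicted)
    act = _as_binary(actual)
    out = {"accuracy": float(np.mean(pred == act))}
    for name in ("precision", "recall", "f1"):
        weighted = 0.0
        for cls in (0, 1):
            support = int(np.sum(act == cls))
            if support == 0:
                continue
            counts = confusion((pred == cls).astype(int), (act == cls).astype(int))
            value = scalar_metrics(counts)[name]
            weighted += (0.0 if np.isnan(value) else value) * support / act.size
        out[f"weighted_{name}"] = weighted
    return out


def per_amino_acid_report(predictions: pd.DataFrame, actual: Sequence[str]) -> pd.DataFrame:
    """Per-amino-acid metric rows, before and after probability correction.

    ``predictions`` needs columns amino_acid, raw_hs_probability,
    predicted_class_raw and predicted_class (see
    :func:`hotseq.calibration.apply_correction`). Returns one row per
    (amino_acid, stage) with stage "original" or "corrected", plus pooled
    "ALL" rows whose counts equal the sums of the per-amino-acid counts.
    """
    if len(predictions) == 0:
        raise ValueError("empty predictions")
    frame = predictions.copy()
    frame["actual"] = list(actual)

    rows = []
    groups = [("ALL", frame)] + [(aa, grp) for aa, grp in frame.groupby("amino_acid")]
    for aa, group in groups:
        for stage, column in (("original", "predicted_class_raw"), ("corrected", "predicted_class")):
            counts = confusion(group[column], group["actual"])
            row = {"amino_acid": aa, "stage": stage,
                   "TP": counts.TP, "TN": counts.TN, "FP": counts.FP, "FN": counts.FN}
            row.update(scalar_metrics(counts))
            row["auroc"] = auroc(group["raw_hs_probability"], group["actual"])
            rows.append(row)
    return pd.DataFrame(rows)
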