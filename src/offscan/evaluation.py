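"""Tie-aware ROC and precision-recall evaluation, from first principles.

Off-target benchmarks are extremely imbalanced (positives are a fraction of a
percent of candidates), so both curves are computed: ROC-AUC summarizes
ranking quality overall, PR-AUC is the imbalance-sensitive complement.

Conventions: scores are "larger = more cleavage-prone"; tied scores share a
single threshold (one operating point per distinct value), so ROC-AUC equals
the Mann-Whitney U statistic over (positive, negative) pairs with ties
counted one half, and PR-AUC uses the average-precision step sum
sum_k (R_k - R_{k-1}) * P_k rather than trapezoidal interpolation, which is
known to overestimate area in PR space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import feature_columns

__all__ = [
    "UndefinedMetricError",
    "CurvePoints",
    "roc_auc",
    "pr_auc",
    "benchmark_tools",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given labels (e.g. one class only)."""


@dataclass
class CurvePoints:
    """One evaluated curve: thresholds (descending), coordinates, and area.

    For ROC, (x, y) = (FPR, TPR) including the (0,0) and (1,1) endpoints;
    for PR, (x, y) = (recall, precision) including the recall-0 anchor.
    """

    thresholds: np.ndarray
    x: np.ndarray
    y: np.ndarray
    auc: float


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary {0,1}")
    return scores, labels.astype(int)


def _tie_grouped_counts(scores, labels):
    """Cumulative TP/FP at each distinct score threshold, descending."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of each tie group
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    return s[distinct], tp, fp


def roc_auc(scores, labels) -> CurvePoints:
    """ROC curve and trapezoidal AUC with tie-grouped thresholds.

    Equals the normalized Mann-Whitney U statistic (ties counted 1/2).
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC undefined: both classes required")
    thr, tp, fp = _tie_grouped_counts(scores, labels)
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return CurvePoints(thresholds=thr, x=fpr, y=tpr, auc=auc)


def pr_auc(scores, labels) -> CurvePoints:
    """Precision-recall curve with average-precision area.

    AP = sum_k (R_k - R_{k-1}) P_k over tie-grouped descending thresholds;
    an uninformative (constant) score yields the positive prevalence.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("PR-AUC undefined: at least one positive required")
    thr, tp, fp = _tie_grouped_counts(scores, labels)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    ap = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return CurvePoints(
        thresholds=thr,
        x=np.r_[0.0, recall],
        y=np.r_[precision[0] if len(precision) else 1.0, precision],
        auc=ap,
    )


def benchmark_tools(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    by_group: bool = True,
) -> pd.DataFrame:
    """ROC-AUC and PR-AUC per score column, pooled and per cell-type group.

    A column whose metric is undefined in some slice (single-class group)
    gets NaN there with the reason recorded in the ``note`` column; the other
    columns are unaffected.  Report rows are deterministically ordered by
    (group, column).
    """
    if columns is None:
        columns = feature_columns(table)
    labels = table["label"].to_numpy()
    slices: list[tuple[str, pd.DataFrame]] = [("pooled", table)]
    if by_group and "cell_type" in table.columns and table["cell_type"].notna().any():
        for cell, sub in sorted(table.groupby("cell_type", dropna=True)):
            slices.append((str(cell), sub))
    rows = []
    for group_name, sub in slices:
        y = sub["label"].to_numpy()
        for col in columns:
            row = {"group": group_name, "column": col, "n": len(sub),
                   "n_pos": int(y.sum()), "roc_auc": np.nan, "pr_auc": np.nan,
                   "note": ""}
            try:
                row["roc_auc"] = roc_auc(sub[col].to_numpy(), y).auc
                row["pr_auc"] = pr_auc(sub[col].to_numpy(), y).auc
            except UndefinedMetricError as exc:
                row["note"] = str(exc)
            rows.append(row)
    report = pd.DataFrame(rows)
    return report.sort_values(["group", "column"], kind="stable").reset_index(drop=True)
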