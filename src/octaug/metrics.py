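"""Evaluation metrics for binary cavity segmentation.

Six headline metrics — accuracy, Dice coefficient, precision, recall
(sensitivity), specificity and Jaccard index — are computed from the pixel
confusion counts with the cavity class as foreground.  Accuracy is reported
in two variants: overall pixel accuracy ``(TP+TN)/N`` (the headline value)
and the class-averaged form ``(1/k)·Σ_j p_jj/g_j``; both appear in every
record.  Degenerate denominators follow a fixed convention: a metric whose
denominator is empty scores 1.0 when there are no errors of either kind and
0.0 otherwise, and the affected metric names are flagged on the record.

Fold-level aggregation and the Welch two-sample t-test used to compare an
augmented run against a baseline run live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricsRecord", "compute_metrics", "aggregate_folds",
           "compare_runs", "METRIC_NAMES"]

METRIC_NAMES = ["accuracy", "dice", "precision", "recall", "specificity", "jaccard"]


@dataclass(frozen=True)
class MetricsRecord:
    accuracy: float          # overall pixel accuracy (headline)
    dice: float
    precision: float
    recall: float
    specificity: float
    jaccard: float
    accuracy_class_avg: float
    tp: int
    fp: int
    fn: int
    tn: int
    degenerate: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                METRIC_NAMES + ["accuracy_class_avg", "tp", "fp", "fn", "tn"]}


def _ratio(num: float, den: float, fp: int, fn: int, name: str,
           flags: list[str]) -> float:
    if den > 0:
        return num / den
    flags.append(name)
    return 1.0 if (fp == 0 and fn == 0) else 0.0


def compute_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray) -> MetricsRecord:
    """Confusion-count metrics between a predicted and a reference mask."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for arr, label in ((pred, "pred_mask"), (gt, "gt_mask")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{label} must be binary")

    pred = pred.astype(bool)
    gt = gt.astype(bool)
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())
    n = tp + fp + fn + tn

    flags: list[str] = []
    record = MetricsRecord(
        accuracy=(tp + tn) / n,
        dice=_ratio(2 * tp, 2 * tp + fp + fn, fp, fn, "dice", flags),
        precision=_ratio(tp, tp + fp, fp, fn, "precision", flags),
        recall=_ratio(tp, tp + fn, fp, fn, "recall", flags),
        specificity=_ratio(tn, tn + fp, fp, fn, "specificity", flags),
        jaccard=_ratio(tp, tp + fp + fn, fp, fn, "jaccard", flags),
        accuracy_class_avg=0.5 * (_ratio(tn, tn + fp, fp, fn, "accuracy_class_avg", flags)
                                  + _ratio(tp, tp + fn, fp, fn, "accuracy_class_avg", flags)),
        tp=tp, fp=fp, fn=fn, tn=tn,
        degenerate=tuple(dict.fromkeys(flags)),
    )
    return record


def aggregate_folds(records: list[MetricsRecord]) -> pd.DataFrame:
    """Per-metric sample mean and standard deviation (n−1) across folds."""
    if len(records) < 2:
        raise ValueError("need at least two fold records to aggregate")
    frame = pd.DataFrame([r.as_dict() for r in records])[METRIC_NAMES]
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})


def compare_runs(a: list[MetricsRecord], b: list[MetricsRecord]) -> pd.DataFrame:
    """Welch two-sided t-test and mean delta (a − b) per metric.

    ``a`` is conventionally the augmented run and ``b`` the baseline, so a
    positive delta is an improvement.  With zero variance on both sides the
    t statistic is undefined; such rows get p = 1.0 for equal means, 0.0
    otherwise, and are flagged.
    """
    if len(a) != len(b):
        raise ValueError("fold counts differ")
    if len(a) < 2:
        raise ValueError("need at least two folds per run")
    fa = pd.DataFrame([r.as_dict() for r in a])[METRIC_NAMES]
    fb = pd.DataFrame([r.as_dict() for r in b])[METRIC_NAMES]
    rows = {}
    for m in METRIC_NAMES:
        xa, xb = fa[m].to_numpy(), fb[m].to_numpy()
        delta = xa.mean() - xb.mean()
        undefined = xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0
        if undefined:
            p = 1.0 if np.isclose(delta, 0.0) else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        rows[m] = {"delta": float(delta), "p_value": p, "undefined_variance": undefined}
    return pd.DataFrame(rows).T
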