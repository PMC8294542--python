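"""Performance metrics computed from predictions.

Classification metrics are derived from confusion counts with explicit
closed forms; regression metrics use their standard definitions.  Every
metric carries direction metadata (greater- vs lesser-is-better) so that
configuration ranking is always direction-aware.

Convention for degenerate ratios (zero denominator): the score is 0 and a
degeneracy flag is raised alongside — never NaN — so that ranking over
configurations remains a total order.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricValue",
    "Direction",
    "CLASSIFICATION_METRICS",
    "REGRESSION_METRICS",
    "METRIC_NAMES",
    "confusion",
    "score",
    "score_detailed",
    "direction",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with respect to a chosen positive label."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricValue:
    """One metric evaluation, tagged with the data split and fold it
    belongs to (``split`` is one of train/validation/test)."""

    metric_name: str
    value: float
    split: str
    fold_id: int


class Direction(Enum):
    GREATER_IS_BETTER = "greater_is_better"
    LESSER_IS_BETTER = "lesser_is_better"


CLASSIFICATION_METRICS = (
    "accuracy",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "recall",
    "f1_score",
    "matthews_corrcoef",
)
REGRESSION_METRICS = ("mean_absolute_error", "mean_squared_error", "r2")
METRIC_NAMES = CLASSIFICATION_METRICS + REGRESSION_METRICS

_LESSER = {"mean_absolute_error", "mean_squared_error"}


def direction(metric_name: str) -> Direction:
    """Ranking direction of a metric: error-type metrics are minimized,
    everything else is maximized."""
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}")
    return Direction.LESSER_IS_BETTER if metric_name in _LESSER else Direction.GREATER_IS_BETTER


def confusion(y_true, y_pred, positive_label=1) -> ConfusionCounts:
    """Standard binary confusion counts with respect to *positive_label*."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    pos_t = yt == positive_label
    pos_p = yp == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def _binary_scores(c: ConfusionCounts, name: str) -> tuple[float, bool]:
    if name == "accuracy":
        return _ratio(c.tp + c.tn, c.n)
    if name == "sensitivity" or name == "recall":
        return _ratio(c.tp, c.tp + c.fn)
    if name == "specificity":
        return _ratio(c.tn, c.tn + c.fp)
    if name == "precision":
        return _ratio(c.tp, c.tp + c.fp)
    if name == "balanced_accuracy":
        sens, d1 = _ratio(c.tp, c.tp + c.fn)
        spec, d2 = _ratio(c.tn, c.tn + c.fp)
        return (sens + spec) / 2.0, d1 or d2
    if name == "f1_score":
        return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    if name == "matthews_corrcoef":
        den2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
        if den2 == 0:
            return 0.0, True
        return (c.tp * c.tn - c.fp * c.fn) / float(np.sqrt(den2)), False
    raise ValueError(f"unknown classification metric {name!r}")


def _multiclass_mcc(yt: np.ndarray, yp: np.ndarray) -> tuple[float, bool]:
    # generalized (R_K) correlation from the full confusion matrix
    classes = np.unique(np.concatenate([yt, yp]))
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=float)
    for t, p in zip(yt, yp):
        cm[idx[t], idx[p]] += 1
    t_sum = cm.sum(axis=1)
    p_sum = cm.sum(axis=0)
    n = cm.sum()
    cov_tp = n * np.trace(cm) - t_sum @ p_sum
    cov_tt = n * n - t_sum @ t_sum
    cov_pp = n * n - p_sum @ p_sum
    if cov_tt == 0 or cov_pp == 0:
        return 0.0, True
    return float(cov_tp / np.sqrt(cov_tt * cov_pp)), False


def score_detailed(metric_name: str, y_true, y_pred) -> tuple[float, bool]:
    """Compute a metric; returns ``(value, degenerate)`` where *degenerate*
    flags a zero-denominator case scored as 0."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape[0] != yp.shape[0]:
        raise ValueError("y_true and y_pred length mismatch")

    if metric_name in REGRESSION_METRICS:
        yt = yt.astype(float)
        yp = yp.astype(float)
        if metric_name == "mean_absolute_error":
            return float(np.mean(np.abs(yt - yp))), False
        if metric_name == "mean_squared_error":
            return float(np.mean((yt - yp) ** 2)), False
        ss_tot = float(np.sum((yt - yt.mean()) ** 2))
        if ss_tot == 0:
            return 0.0, True
        return 1.0 - float(np.sum((yt - yp) ** 2)) / ss_tot, False

    if metric_name not in CLASSIFICATION_METRICS:
        raise ValueError(f"unknown metric {metric_name!r}")

    classes = np.unique(np.concatenate([yt, yp]))
    if len(classes) <= 2:
        # binary: the larger label is the positive class; 0/1-coded labels
        # always treat 1 as positive, even if only 0 is observed
        try:
            zero_one = set(classes.tolist()) <= {0, 1}
        except TypeError:
            zero_one = False
        pos = 1 if zero_one else classes[-1]
        return _binary_scores(confusion(yt, yp, positive_label=pos), metric_name)

    # multiclass: macro-average one-vs-rest (MCC uses the generalized form)
    if metric_name == "accuracy":
        return float(np.mean(yt == yp)), False
    if metric_name == "matthews_corrcoef":
        return _multiclass_mcc(yt, yp)
    vals, degen = [], False
    for c in classes:
        v, d = _binary_scores(confusion(yt, yp, positive_label=c), metric_name)
        vals.append(v)
        degen = degen or d
    return float(np.mean(vals)), degen


def score(metric_name: str, y_true, y_pred) -> float:
    """Compute a metric value (degenerate ratios score 0)."""
    return score_detailed(metric_name, y_true, y_pred)[0]
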