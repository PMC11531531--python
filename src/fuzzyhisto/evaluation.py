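"""Confusion matrix and the classification metric suite.

Metrics follow the standard definitions: precision = TP/(TP+FP),
recall (sensitivity, TPR) = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN),
accuracy = (TP+TN)/n and specificity (TNR) = TN/(TN+FP).  Per-class values
treat each class as positive in turn; the "average" column is the unweighted
(macro) arithmetic mean of the per-class values.  A ratio with a zero
denominator is reported as NaN together with an ``undefined`` flag rather
than silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with class 1 as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swap_positive(self) -> "ConfusionMatrix":
        """Counts with class 0 treated as positive."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)

    def as_array(self) -> np.ndarray:
        """Rows = true class (0, 1), columns = predicted class (0, 1)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Exact binary confusion counts; labels must be 0/1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    if len(y_true) and not (
        np.isin(y_true, [0, 1]).all() and np.isin(y_pred, [0, 1]).all()
    ):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num: int, den: int, undefined: set[str], name: str) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


@dataclass
class MetricReport:
    """Per-class and macro-averaged metrics, with undefined-ratio flags."""

    per_class: dict[int, dict[str, float]]
    average: dict[str, float]
    undefined: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "average": self.average,
            "undefined": sorted(self.undefined),
        }


_METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "specificity")


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Compute the metric suite from confusion counts.

    Swapping the positive class exchanges the roles of (TP, FN) with
    (TN, FP), so class-0 precision equals TN/(TN+FN) etc., matching a
    per-class report whose columns are the two classes.
    """
    undefined: set[str] = set()
    per_class: dict[int, dict[str, float]] = {}
    for cls, c in ((1, cm), (0, cm.swap_positive())):
        per_class[cls] = {
            "accuracy": _ratio(c.tp + c.tn, c.n, undefined, f"accuracy[{cls}]"),
            "precision": _ratio(c.tp, c.tp + c.fp, undefined,
                                f"precision[{cls}]"),
            "recall": _ratio(c.tp, c.tp + c.fn, undefined, f"recall[{cls}]"),
            "f1": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, undefined,
                         f"f1[{cls}]"),
            "specificity": _ratio(c.tn, c.tn + c.fp, undefined,
                                  f"specificity[{cls}]"),
        }
    average = {
        name: float(np.mean([per_class[0][name], per_class[1][name]]))
        for name in _METRIC_NAMES
    }
    return MetricReport(per_class=per_class, average=average,
                        undefined=undefined)


def evaluate(y_true, y_pred) -> MetricReport:
    """Convenience: confusion counts then the metric suite."""
    return metrics(confusion(y_true, y_pred))
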