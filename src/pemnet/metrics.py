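"""Pixel-level segmentation metrics and mean +/- std aggregation.

For one truth/prediction mask pair with pixel tallies TP, FP, FN, TN:

    Jaccard     = TP / (TP + FP + FN)            (= IoU of the target class)
    DSC         = 2 TP / (2 TP + FP + FN)
    GPA         = (TP + TN) / total
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)

The set-based intersection-over-union and the Jaccard coefficient are the
same quantity for a single class; reported "IoU" here follows the common
evaluator convention of averaging the per-class IoU over the two semantic
classes (target and background), which is why reported IoU exceeds the
target-class Jaccard on imbalanced masks.

Degenerate denominators (e.g. an empty truth class) score 1 when both
masks are empty for that class and 0 otherwise, and the metric name is
recorded in the ``undefined`` set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaskPair", "ConfusionCounts", "MetricSet", "confusion",
           "per_class_metrics", "evaluate_pair", "aggregate", "AggregateReport"]

METRIC_NAMES = ("iou_mean_class", "gpa", "dsc", "jaccard",
                "sensitivity", "specificity")


@dataclass(frozen=True)
class MaskPair:
    """Ground-truth and predicted binary masks of equal shape."""

    truth: np.ndarray
    pred: np.ndarray

    def __post_init__(self):
        t, p = np.asarray(self.truth), np.asarray(self.pred)
        if t.shape != p.shape:
            raise ValueError(f"mask shapes differ: {t.shape} vs {p.shape}")
        object.__setattr__(self, "truth", t.astype(bool))
        object.__setattr__(self, "pred", p.astype(bool))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    iou_mean_class: float
    gpa: float
    dsc: float
    jaccard: float
    sensitivity: float
    specificity: float
    undefined: frozenset = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(pair: MaskPair) -> ConfusionCounts:
    """Exact pixel tallies of the truth/prediction contingency table."""
    t, p = pair.truth, pair.pred
    tp = int(np.count_nonzero(t & p))
    fp = int(np.count_nonzero(~t & p))
    fn = int(np.count_nonzero(t & ~p))
    tn = int(np.count_nonzero(~t & ~p))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, both_empty: bool, undefined: set, name: str) -> float:
    if den == 0:
        undefined.add(name)
        return 1.0 if both_empty else 0.0
    return num / den


def per_class_metrics(c: ConfusionCounts) -> MetricSet:
    """The six metrics derived from one confusion table.

    The background-class Jaccard (TN / (TN + FP + FN)) enters only the
    class-averaged IoU.
    """
    und: set = set()
    fg_empty = (c.tp + c.fn == 0) and (c.tp + c.fp == 0)
    bg_empty = (c.tn + c.fp == 0) and (c.tn + c.fn == 0)
    jac = _ratio(c.tp, c.tp + c.fp + c.fn, fg_empty, und, "jaccard")
    dsc = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, fg_empty, und, "dsc")
    jac_bg = _ratio(c.tn, c.tn + c.fp + c.fn, bg_empty, und, "iou_mean_class")
    gpa = _ratio(c.tp + c.tn, c.total, False, und, "gpa")
    sens = _ratio(c.tp, c.tp + c.fn, c.tp + c.fp == 0, und, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, c.tn + c.fn == 0, und, "specificity")
    return MetricSet(iou_mean_class=(jac + jac_bg) / 2.0, gpa=gpa, dsc=dsc,
                     jaccard=jac, sensitivity=sens, specificity=spec,
                     undefined=frozenset(und))


def evaluate_pair(truth, pred) -> MetricSet:
    """Convenience: metrics straight from two binary masks."""
    return per_class_metrics(confusion(MaskPair(truth, pred)))


@dataclass(frozen=True)
class AggregateReport:
    mean: dict
    std: dict
    n_images: int
    n_runs: int

    def as_dict(self) -> dict:
        return {"mean": dict(self.mean), "std": dict(self.std),
                "n_images": self.n_images, "n_runs": self.n_runs}


def _mean_over(sets) -> dict:
    return {name: float(np.mean([getattr(s, name) for s in sets]))
            for name in METRIC_NAMES}


def aggregate(per_image, per_run=None) -> AggregateReport:
    """Unweighted per-image mean; across runs, mean and sample std of run means.

    ``per_image``: MetricSets of one run (ignored when ``per_run`` is given).
    ``per_run``: optional list of runs, each a list of per-image MetricSets;
    the +/- column is then the sample standard deviation (ddof=1) of the run
    means, matching a mean +/- std presentation over repeated trainings.
    A single run reports std 0.
    """
    if per_run is not None:
        if not per_run or any(not run for run in per_run):
            raise ValueError("per_run must be a non-empty list of non-empty runs")
        run_means = [_mean_over(run) for run in per_run]
        mean = {name: float(np.mean([rm[name] for rm in run_means]))
                for name in METRIC_NAMES}
        if len(run_means) > 1:
            std = {name: float(np.std([rm[name] for rm in run_means], ddof=1))
                   for name in METRIC_NAMES}
        else:
            std = {name: 0.0 for name in METRIC_NAMES}
        return AggregateReport(mean=mean, std=std, n_runs=len(per_run),
                               n_images=sum(len(r) for r in per_run))
    if not per_image:
        raise ValueError("per_image must be non-empty")
    mean = _mean_over(per_image)
    if len(per_image) > 1:
        std = {name: float(np.std([getattr(s, name) for s in per_image], ddof=1))
               for name in METRIC_NAMES}
    else:
        std = {name: 0.0 for name in METRIC_NAMES}
    return AggregateReport(mean=mean, std=std, n_runs=1, n_images=len(per_image))


def pooled_gpa(pairs) -> float:
    """GPA pooled over all pixels of all images (variant behind a flag)."""
    tp = tn = total = 0
    for pair in pairs:
        c = confusion(pair if isinstance(pair, MaskPair) else MaskPair(*pair))
        tp += c.tp
        tn += c.tn
        total += c.total
    if total == 0:
        raise ValueError("no pixels to pool")
    return (tp + tn) / total


def report_frame(per_image):
    """One row per image: confusion counts plus all six metrics."""
    import pandas as pd

    rows = []
    for i, item in enumerate(per_image):
        if isinstance(item, tuple):
            ms, c = item
        else:
            ms, c = item, None
        row = {"image": i, **ms.as_dict(),
               "undefined": ";".join(sorted(ms.undefined))}
        if c is not None:
            row.update(tp=c.tp, fp=c.fp, fn=c.fn, tn=c.tn)
        rows.append(row)
    return pd.DataFrame(rows)
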