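"""Segmentation evaluation: confusion counts, per-class IoU and fold reports.

IoU = TP / (TP + FP + FN) per class.  Cross-validation reports follow the
convention of averaging the three foreground classes (bone, degradation
layer, residual material) for the overall column; the background class is
excluded by default but can be included.  Fold aggregation reports the mean
and the standard error (sample standard deviation / sqrt(n_folds)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import CLASS_NAMES, LabelVolume

logger = logging.getLogger("segscale")

FOREGROUND_CLASSES = (1, 2, 3)


@dataclass
class ConfusionCounts:
    tp: np.ndarray  # (k,)
    fp: np.ndarray
    fn: np.ndarray
    n_voxels: int

    @property
    def n_classes(self) -> int:
        return len(self.tp)


def confusion_counts(
    pred: LabelVolume | np.ndarray, ref: LabelVolume | np.ndarray, n_classes: int = 4
) -> ConfusionCounts:
    """Exact per-class TP/FP/FN tallies over all voxels."""
    p = pred.data if isinstance(pred, LabelVolume) else np.asarray(pred)
    r = ref.data if isinstance(ref, LabelVolume) else np.asarray(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    p = p.ravel().astype(np.int64)
    r = r.ravel().astype(np.int64)
    cm = np.bincount(r * n_classes + p, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )  # rows: reference, cols: prediction
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, n_voxels=p.size)


def iou(counts: ConfusionCounts, class_id: int) -> float:
    """TP / (TP + FP + FN); NaN if the class is absent from both volumes."""
    tp = counts.tp[class_id]
    denom = tp + counts.fp[class_id] + counts.fn[class_id]
    if denom == 0:
        logger.warning("class %d absent from both volumes; IoU undefined", class_id)
        return float("nan")
    return float(tp / denom)


def iou_per_class(
    pred: LabelVolume | np.ndarray, ref: LabelVolume | np.ndarray, n_classes: int = 4
) -> np.ndarray:
    counts = confusion_counts(pred, ref, n_classes)
    return np.array([iou(counts, c) for c in range(n_classes)])


def mean_iou(
    pred: LabelVolume | np.ndarray,
    ref: LabelVolume | np.ndarray,
    n_classes: int = 4,
    include_background: bool = False,
) -> float:
    """Mean over defined class IoUs; background excluded by default."""
    vals = iou_per_class(pred, ref, n_classes)
    classes = range(n_classes) if include_background else FOREGROUND_CLASSES
    sel = [vals[c] for c in classes if not np.isnan(vals[c])]
    if not sel:
        return float("nan")
    return float(np.mean(sel))


@dataclass
class IoUReport:
    class_ids: list[int]
    class_means: dict[int, float]
    class_se: dict[int, float | None]
    overall_mean: float
    overall_se: float | None
    per_fold: np.ndarray = field(repr=False)  # (n_folds, k)

    def to_frame(self) -> pd.DataFrame:
        """Report table: one row per fold-aggregate, values scaled x100."""
        cols = {}
        for c in self.class_ids:
            se = self.class_se[c]
            cols[CLASS_NAMES.get(c, str(c))] = [
                f"{100 * self.class_means[c]:.2f}"
                + (f" ± {100 * se:.2f}" if se is not None else "")
            ]
        se = self.overall_se
        cols["Avr"] = [
            f"{100 * self.overall_mean:.2f}"
            + (f" ± {100 * se:.2f}" if se is not None else "")
        ]
        return pd.DataFrame(cols)


def aggregate_folds(
    per_fold_per_class: np.ndarray, class_ids=FOREGROUND_CLASSES
) -> IoUReport:
    """Fold-level aggregation of per-class IoUs.

    ``per_fold_per_class``: (n_folds, k) array, columns indexed by class id
    (absolute — pass the full k=4 matrix).  Classes undefined in a fold
    (NaN) are excluded from that class's aggregate; the overall column is
    the mean of the selected class means.
    """
    arr = np.asarray(per_fold_per_class, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a (n_folds, n_classes) matrix")
    n_folds = arr.shape[0]
    class_ids = list(class_ids)
    means: dict[int, float] = {}
    ses: dict[int, float | None] = {}
    for c in class_ids:
        vals = arr[:, c]
        vals = vals[~np.isnan(vals)]
        means[c] = float(vals.mean()) if vals.size else float("nan")
        if n_folds >= 2 and vals.size >= 2:
            ses[c] = float(vals.std(ddof=1) / np.sqrt(vals.size))
        else:
            ses[c] = None
    per_fold_avr = np.nanmean(arr[:, class_ids], axis=1)
    overall_mean = float(np.nanmean(per_fold_avr))
    if n_folds >= 2:
        overall_se = float(np.nanstd(per_fold_avr, ddof=1) / np.sqrt(n_folds))
    else:
        overall_se = None
    return IoUReport(
        class_ids=class_ids,
        class_means=means,
        class_se=ses,
        overall_mean=overall_mean,
        overall_se=overall_se,
        per_fold=arr,
    )
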