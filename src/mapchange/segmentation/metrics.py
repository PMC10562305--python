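"""Per-class and macro segmentation metrics.

Precision, recall, F1 (Dice) and IoU (Jaccard) are computed per class from
pixel counts, excluding the background class, then averaged unweighted over
the five map classes (macro average). F1 and IoU are linked by the exact
pixel-set identity ``f1 = 2*iou / (1 + iou)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..postprocess import CLASS_NAMES

__all__ = ["SegmentationMetrics", "evaluate_segmentation"]


@dataclass(frozen=True)
class SegmentationMetrics:
    """Per-class precision/recall/F1/IoU plus macro averages.

    A class absent from both prediction and target scores 1.0 on every
    metric: a sheet that truly lacks, say, water bodies should not zero the
    macro average. This convention is deliberate and affects synthetic
    sheets more than real ones.
    """

    per_class: pd.DataFrame  # index: class names; columns: precision, recall, f1, iou

    @property
    def macro_precision(self) -> float:
        return float(self.per_class["precision"].mean())

    @property
    def macro_recall(self) -> float:
        return float(self.per_class["recall"].mean())

    @property
    def macro_f1(self) -> float:
        return float(self.per_class["f1"].mean())

    @property
    def macro_iou(self) -> float:
        return float(self.per_class["iou"].mean())


def evaluate_segmentation(
    pred: np.ndarray, target: np.ndarray, class_names: tuple[str, ...] = CLASS_NAMES
) -> SegmentationMetrics:
    """Pixel-count metrics for labels 1..len(class_names); 0 is background."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError("prediction and target shapes differ")
    rows = {}
    for code, name in enumerate(class_names, start=1):
        p = pred == code
        t = target == code
        tp = int(np.count_nonzero(p & t))
        fp = int(np.count_nonzero(p & ~t))
        fn = int(np.count_nonzero(~p & t))
        if tp + fp + fn == 0:
            rows[name] = dict(precision=1.0, recall=1.0, f1=1.0, iou=1.0)
            continue
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn)
        iou = tp / (tp + fp + fn)
        rows[name] = dict(precision=precision, recall=recall, f1=f1, iou=iou)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return SegmentationMetrics(table.loc[list(class_names)])
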