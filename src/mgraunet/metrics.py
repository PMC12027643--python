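"""Pixel-level evaluation metrics for binary segmentation.

Five standard ratios over the pixel confusion table:

    Acc = (TP + TN) / (TP + FP + FN + TN)
    DSC = 2 TP / (2 TP + FP + FN)
    Pre = TP / (TP + FP)
    Rec = TP / (TP + FN)
    IoU = TP / (TP + FP + FN)

DSC and IoU are algebraically linked (DSC = 2 IoU / (1 + IoU)).
Zero-denominator conventions: a ratio is 1 when both masks are empty and
0 when exactly one of them is; every such degenerate case is logged so
dataset-level means stay auditable.  Dataset reporting computes metrics
per image and averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    acc: float
    dsc: float
    pre: float
    rec: float
    iou: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "dsc": self.dsc, "pre": self.pre, "rec": self.rec, "iou": self.iou}


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts of two binary masks of identical shape."""
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch: pred {pred_mask.shape} vs gt {gt_mask.shape}")
    for name, m in (("pred", pred_mask), ("gt", gt_mask)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary; threshold probabilities first")
    p = pred_mask.astype(bool)
    g = gt_mask.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def _ratio(num: int, den: int, both_empty: bool, context: str) -> float:
    if den == 0:
        logger.info("degenerate %s (zero denominator): convention value %d", context, int(both_empty))
        return 1.0 if both_empty else 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """The five evaluation ratios with the logged degenerate-case conventions."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total <= 0:
        raise ValueError("confusion table is empty")
    pred_empty = tp + fp == 0
    gt_empty = tp + fn == 0
    both_empty = pred_empty and gt_empty
    return MetricsReport(
        acc=(tp + tn) / counts.total,
        dsc=_ratio(2 * tp, 2 * tp + fp + fn, both_empty, "DSC"),
        pre=_ratio(tp, tp + fp, both_empty, "precision"),
        rec=_ratio(tp, tp + fn, both_empty, "recall"),
        iou=_ratio(tp, tp + fp + fn, both_empty, "IoU"),
    )


def evaluate_masks(
    pred_masks: "list[np.ndarray]", gt_masks: "list[np.ndarray]"
) -> tuple[list[MetricsReport], MetricsReport]:
    """Per-image metrics plus their unweighted mean."""
    if len(pred_masks) != len(gt_masks) or not pred_masks:
        raise ValueError("need equally many (and at least one) predicted and true masks")
    reports = [metrics(confusion(p, g)) for p, g in zip(pred_masks, gt_masks)]
    mean = MetricsReport(
        **{
            k: float(np.mean([r.as_dict()[k] for r in reports]))
            for k in ("acc", "dsc", "pre", "rec", "iou")
        }
    )
    return reports, mean
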