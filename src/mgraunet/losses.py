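"""Compound BCE + Dice objective for binary segmentation.

    BceDice = alpha * BCE + beta * Dice
    BCE  = -(1/N) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
    Dice = 1 - (2 sum_i p_i y_i + eps) / (sum_i p_i + sum_i y_i + eps)

Pixel-wise cross-entropy drives per-pixel accuracy; the Dice term
counters foreground/background imbalance so small lesions still carry
gradient.  Both weights default to 1.  ``eps`` keeps empty-mask batches
finite; predictions are clipped away from {0, 1} before the logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor import Tensor

_CLIP = 1e-7


@dataclass
class LossConfig:
    alpha: float = 1.0
    beta: float = 1.0
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("loss weights must be nonnegative with alpha + beta > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def bce_dice_tensor(pred_probs: Tensor, gt: Tensor, cfg: LossConfig | None = None) -> Tensor:
    """Autograd BceDice on predicted probabilities (any shape, same for both)."""
    cfg = cfg or LossConfig()
    p = pred_probs.clip(_CLIP, 1.0 - _CLIP)
    bce = -(gt * p.log() + (1.0 - gt) * (1.0 - p).log()).mean()
    inter = (p * gt).sum()
    dice = 1.0 - (2.0 * inter + cfg.epsilon) / (p.sum() + gt.sum() + cfg.epsilon)
    return cfg.alpha * bce + cfg.beta * dice


def bce_dice_loss(pred_probs: np.ndarray, gt: np.ndarray, cfg: LossConfig | None = None) -> float:
    """BceDice on arrays; validates shapes and binary ground truth."""
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred_probs.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred_probs.shape} vs gt {gt.shape}")
    if not np.isin(gt, (0.0, 1.0)).all():
        raise ValueError("ground truth must be binary (values in {0, 1})")
    return float(bce_dice_tensor(Tensor(pred_probs), Tensor(gt), cfg).item())
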