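"""The evaluation metrics and the compound loss on hand-checkable inputs.

Evaluates the five segmentation metrics on a known confusion table and
the BCE+Dice loss on tiny prediction vectors, printing values that can
be verified with a pocket calculator.
"""

import numpy as np

from mgraunet import ConfusionCounts, LossConfig, bce_dice_loss, metrics

r = metrics(ConfusionCounts(tp=6, fp=2, tn=90, fn=2))
print("confusion TP=6 FP=2 TN=90 FN=2 ->")
print(f"  Acc={r.acc}  DSC={r.dsc}  Pre={r.pre}  Rec={r.rec}  IoU={r.iou}")
print(f"  DSC equals 2*IoU/(1+IoU) = {2 * r.iou / (1 + r.iou)}")

gt = np.array([1.0, 1.0, 0.0, 0.0])
print(f"uniform 0.5 prediction, BCE term only: {bce_dice_loss(np.full(4, 0.5), gt, LossConfig(alpha=1, beta=0)):.6f}"
      f"  (ln 2 = {np.log(2):.6f})")
print(f"perfect prediction, full BceDice: {bce_dice_loss(gt.copy(), gt):.2e} (~0)")
print(f"y=(1,1,0,0), p=(0.9,0.6,0.2,0.1): BceDice = {bce_dice_loss(np.array([0.9,0.6,0.2,0.1]), gt):.6f}")
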