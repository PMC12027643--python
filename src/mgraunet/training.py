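"""Training, evaluation and prediction loops.

The published protocol: AdamW (initial learning rate 1e-3, batch size 8),
cosine-annealing schedule over the epoch horizon, BceDice loss with both
weights 1, random rotation/flip augmentation, best checkpoint selected by
validation DSC.  The loop is fully seeded; two runs with the same seed
produce identical losses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.special import expit

from .data import AugmentConfig, SegmentationSample, augment, to_arrays
from .losses import LossConfig, bce_dice_tensor
from .metrics import MetricsReport, evaluate_masks
from .network import NetworkConfig, SMGRAUNet, build_network
from .nn import AdamW, CosineAnnealingLR
from .tensor import Tensor, no_grad

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig | None = None  # None = no augmentation
    stop_at_val_dsc: float | None = None  # optional early exit once reached


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dsc: float = -1.0


def _forward_loss(model, x: np.ndarray, y: np.ndarray, loss_cfg: LossConfig) -> Tensor:
    logits = model(Tensor(x))
    return bce_dice_tensor(logits.sigmoid(), Tensor(y), loss_cfg)


def fit(
    model: SMGRAUNet,
    train_samples: "list[SegmentationSample]",
    val_samples: "list[SegmentationSample]",
    cfg: TrainConfig,
) -> tuple[History, dict]:
    """Train ``model`` in place; returns history and the best state dict."""
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(
        model.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    sched = CosineAnnealingLR(opt, t_max=cfg.epochs)
    hist = History()
    best_state = model.state_dict()
    n = len(train_samples)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = [train_samples[i] for i in order[start : start + cfg.batch_size]]
            if cfg.augment is not None:
                batch = [augment(s, rng, cfg.augment) for s in batch]
            x, y = to_arrays(batch)
            loss = _forward_loss(model, x, y, cfg.loss)
            if not np.isfinite(loss.item()):
                model.load_state_dict(best_state)
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}; restored best checkpoint "
                    f"(epoch {hist.best_epoch + 1})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        sched.step()
        hist.train_loss.append(float(np.mean(losses)))

        vloss, vdsc = _validate(model, val_samples, cfg)
        hist.val_loss.append(vloss)
        hist.val_dsc.append(vdsc)
        logger.info(
            "epoch %d/%d train_loss=%.4f val_loss=%.4f val_dsc=%.4f",
            epoch + 1, cfg.epochs, hist.train_loss[-1], vloss, vdsc,
        )
        if vdsc > hist.best_val_dsc:
            hist.best_val_dsc = vdsc
            hist.best_epoch = epoch
            best_state = model.state_dict()
        if cfg.stop_at_val_dsc is not None and vdsc >= cfg.stop_at_val_dsc:
            logger.info("validation DSC target %.3f reached; stopping", cfg.stop_at_val_dsc)
            break
    model.load_state_dict(best_state)
    return hist, best_state


def _validate(model, samples, cfg: TrainConfig) -> tuple[float, float]:
    model.eval()
    losses, preds, gts = [], [], []
    with no_grad():
        for start in range(0, len(samples), cfg.batch_size):
            x, y = to_arrays(samples[start : start + cfg.batch_size])
            logits = model(Tensor(x))
            losses.append(bce_dice_tensor(logits.sigmoid(), Tensor(y), cfg.loss).item())
            probs = expit(logits.data)
            preds.extend((probs[:, 0] >= 0.5).astype(np.uint8))
            gts.extend(y[:, 0].astype(np.uint8))
    _, mean = evaluate_masks(preds, gts)
    return float(np.mean(losses)), mean.dsc


def evaluate(
    model: SMGRAUNet, samples: "list[SegmentationSample]", batch_size: int = 8
) -> tuple[list[MetricsReport], MetricsReport]:
    """Threshold probabilities at 0.5 and report per-image + mean metrics."""
    model.eval()
    preds, gts = [], []
    with no_grad():
        for start in range(0, len(samples), batch_size):
            x, y = to_arrays(samples[start : start + batch_size])
            out = model.segment(x)
            preds.extend((out.probabilities[:, 0] >= 0.5).astype(np.uint8))
            gts.extend(y[:, 0].astype(np.uint8))
    return evaluate_masks(preds, gts)


def predict_mask(model: SMGRAUNet, image: np.ndarray, proto_size: int = 256) -> np.ndarray:
    """Segment one (H, W, 3) uint8 image; returns a 0/255 mask of the same size."""
    h, w = image.shape[:2]
    img = Image.fromarray(image).resize((proto_size, proto_size), Image.BILINEAR)
    x = np.asarray(img, dtype=np.float32)[None].transpose(0, 3, 1, 2) / 255.0
    out = model.segment(x)
    mask = (out.probabilities[0, 0] >= 0.5).astype(np.uint8) * 255
    return np.asarray(Image.fromarray(mask).resize((w, h), Image.NEAREST), dtype=np.uint8)


# -- checkpointing -----------------------------------------------------


def save_checkpoint(path, model: SMGRAUNet, extra: dict | None = None):
    """NPZ checkpoint with the network config embedded."""
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[SMGRAUNet, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    cfg = NetworkConfig.from_dict(meta["config"])
    model = build_network(cfg, seed=0)
    model.load_state_dict(state)
    return model, meta


def write_metrics_table(path, reports: "list[MetricsReport]", mean: MetricsReport, ids: "list[str]"):
    """Delimited per-image metrics table with a trailing mean row."""
    path = Path(path)
    with path.open("w") as f:
        f.write("id\tacc\tdsc\tpre\trec\tiou\n")
        for i, r in zip(ids, reports):
            f.write(f"{i}\t{r.acc:.4f}\t{r.dsc:.4f}\t{r.pre:.4f}\t{r.rec:.4f}\t{r.iou:.4f}\n")
        f.write(
            f"mean\t{mean.acc:.4f}\t{mean.dsc:.4f}\t{mean.pre:.4f}\t{mean.rec:.4f}\t{mean.iou:.4f}\n"
        )
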