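"""Segmentation and classification losses for the joint model.

The segmentation loss combines a two-sided dice loss (foreground and
background overlap ratios, so neither class dominates when nuclei cover only
a small fraction of the image) with a focal loss that down-weights easy
pixels by ``(1 - y~)**2``.  Classification uses summed cross-entropy, binary
or multi-class, and the total loss is the convex combination
``(1 - lambda_c) * L_seg + lambda_c * L_c``.

All functions are differentiable through the package's autodiff backend:
predictions may be :class:`~diunet.nn.Tensor` (gradients flow) or plain
arrays (a detached tensor is created).  Losses are batch *sums* by default;
set ``reduction="mean"`` to average instead — the calibration of ``lambda_s``
and ``lambda_c`` depends on this choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .nn import Tensor, as_tensor

ArrayOrTensor = Union[np.ndarray, "Tensor", list, tuple]


@dataclass
class LossConfig:
    """Loss hyper-parameters.

    eps : dice stabiliser against division by zero (added once, outside the
        per-pixel sums).
    lambda_s : weight of the focal term inside the segmentation loss.
    lambda_c : weight of the classification loss in the total loss; in [0, 1].
    clamp_delta : probability floor applied before any logarithm.
    reduction : "sum" (default) or "mean" over the batch for the focal and
        cross-entropy losses.
    """

    eps: float = 1e-6
    lambda_s: float = 1.0
    lambda_c: float = 0.99
    clamp_delta: float = 1e-7
    reduction: str = "sum"

    def __post_init__(self):
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if not 0 < self.clamp_delta < 0.5:
            raise ValueError("clamp_delta must be in (0, 0.5)")
        if not 0 <= self.lambda_c <= 1:
            raise ValueError("lambda_c must be in [0, 1]")
        if self.lambda_s < 0:
            raise ValueError("lambda_s must be non-negative")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")


def _flatten_pred(pred: ArrayOrTensor) -> Tensor:
    t = as_tensor(pred)
    t = t.reshape(-1) if t.ndim != 1 else t
    if t.size == 0:
        raise ValueError("empty prediction batch")
    if np.any(t.data < 0) or np.any(t.data > 1):
        raise ValueError("predictions must lie in [0, 1]")
    return t


def _flatten_truth(truth: ArrayOrTensor, n: int) -> np.ndarray:
    y = truth.data if isinstance(truth, Tensor) else np.asarray(truth, dtype=np.float32)
    y = y.reshape(-1).astype(np.float32)
    if y.size != n:
        raise ValueError(f"prediction/truth length mismatch: {n} vs {y.size}")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("ground-truth labels must be exactly 0 or 1")
    return y


def _reduce(loss: Tensor, n: int, reduction: str) -> Tensor:
    return loss * (1.0 / n) if reduction == "mean" else loss


def dice_loss(pred: ArrayOrTensor, truth: ArrayOrTensor,
              cfg: LossConfig = LossConfig()) -> Tensor:
    """Two-sided dice loss.

    ``1 - (sum(y*yhat)+eps)/(sum(y+yhat)+eps)
         - (sum((1-y)(1-yhat))+eps)/(sum(2-y-yhat)+eps)``

    Zero (up to eps) for a perfect prediction, 1 for complete disagreement.
    The background term makes the loss symmetric under foreground/background
    exchange, which matters when nuclei are a small area fraction.

    For a degenerate batch whose truth is entirely one class, a perfect
    prediction makes the empty-class ratio evaluate to eps/eps = 1 and the
    loss approaches -1/2 rather than 0; the (0, 1) band holds whenever the
    truth contains both classes.
    """
    p = _flatten_pred(pred)
    y = _flatten_truth(truth, p.size)
    eps = cfg.eps
    fg = (p * y).sum() + eps
    fg_den = (p + y).sum() + eps
    bg = ((1.0 - p) * (1.0 - y)).sum() + eps
    bg_den = ((1.0 - p) + (1.0 - y)).sum() + eps
    return 1.0 - fg / fg_den - bg / bg_den


def focal_transform(pred: ArrayOrTensor, truth: ArrayOrTensor) -> Tensor:
    """Per-pixel probability of the *true* class: yhat where y=1, else 1-yhat."""
    p = _flatten_pred(pred)
    y = _flatten_truth(truth, p.size)
    return p * y + (1.0 - p) * (1.0 - y)


def focal_loss(pred: ArrayOrTensor, truth: ArrayOrTensor,
               cfg: LossConfig = LossConfig()) -> Tensor:
    """``-sum((1 - y~)**2 * log(y~))`` with y~ clamped to [clamp_delta, 1]."""
    yt = focal_transform(pred, truth).clip(cfg.clamp_delta, 1.0)
    loss = -((1.0 - yt) ** 2.0 * yt.log()).sum()
    return _reduce(loss, yt.size, cfg.reduction)


def segmentation_loss(pred: ArrayOrTensor, truth: ArrayOrTensor,
                      cfg: LossConfig = LossConfig()) -> Tensor:
    """``L_seg = L_dice + lambda_s * L_focal``."""
    return dice_loss(pred, truth, cfg) + cfg.lambda_s * focal_loss(pred, truth, cfg)


def binary_ce(pred: ArrayOrTensor, truth: ArrayOrTensor,
              cfg: LossConfig = LossConfig()) -> Tensor:
    """Summed binary cross-entropy over a batch of image-level predictions.

    ``pred`` holds the predicted probability of the positive (malignant)
    class per image; ``truth`` the 0/1 labels.
    """
    p = _flatten_pred(pred).clip(cfg.clamp_delta, 1.0 - cfg.clamp_delta)
    y = _flatten_truth(truth, p.size)
    loss = -(y * p.log() + (1.0 - y) * (1.0 - p).log()).sum()
    return _reduce(loss, p.size, cfg.reduction)


def multiclass_ce(target_probs: ArrayOrTensor,
                  cfg: LossConfig = LossConfig()) -> Tensor:
    """Summed multi-class cross-entropy.

    ``target_probs`` holds, for each image, the predicted probability of that
    image's true class (already gathered from the softmax vector).
    """
    p = as_tensor(target_probs)
    p = p.reshape(-1) if p.ndim != 1 else p
    if p.size == 0:
        raise ValueError("empty classification batch")
    if np.any(p.data < 0) or np.any(p.data > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    loss = -p.clip(cfg.clamp_delta, 1.0).log().sum()
    return _reduce(loss, p.size, cfg.reduction)


def classification_loss(task: str, batch, cfg: LossConfig = LossConfig()) -> Tensor:
    """Dispatch to the binary or multi-class cross-entropy.

    ``task`` is "binary" (batch = (predictions, truths)) or "multiclass"
    (batch = target-class probabilities).
    """
    if task == "binary":
        if not (isinstance(batch, (tuple, list)) and len(batch) == 2):
            raise TypeError("binary task expects a (predictions, truths) pair")
        return binary_ce(batch[0], batch[1], cfg)
    if task == "multiclass":
        if isinstance(batch, (tuple, list)) and len(batch) == 2 and not np.isscalar(batch[0]):
            raise TypeError("multiclass task expects target-class probabilities only")
        return multiclass_ce(batch, cfg)
    raise ValueError(f"unknown task {task!r}; expected 'binary' or 'multiclass'")


def total_loss(l_seg, l_c, cfg: LossConfig = LossConfig()) -> Tensor:
    """``L_total = (1 - lambda_c) * L_seg + lambda_c * L_c``."""
    lam = cfg.lambda_c
    return (1.0 - lam) * as_tensor(l_seg) + lam * as_tensor(l_c)
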