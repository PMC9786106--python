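"""Evaluation indicators: dice coefficient, accuracy, confusion matrix."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion


def dice_coefficient(pred: np.ndarray, truth: np.ndarray,
                     threshold: float = 0.5) -> float:
    """Dice overlap 2|P∩T| / (|P|+|T|) of the thresholded prediction.

    ``pred`` is a soft map in [0,1] (binarised at ``threshold``) or an
    already-binary mask; defined as 1.0 when both sets are empty.  Symmetric
    in its two arguments.
    """
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    pb = p > threshold
    tb = t > threshold
    denom = pb.sum() + tb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pb & tb).sum() / denom)


def mean_dice(preds: Sequence[np.ndarray], truths: Sequence[np.ndarray],
              threshold: float = 0.5) -> float:
    """Per-image dice averaged over a set (not pooled over pixels)."""
    if len(preds) == 0 or len(preds) != len(truths):
        raise ValueError("need equal, non-empty prediction/truth lists")
    return float(np.mean([dice_coefficient(p, t, threshold)
                          for p, t in zip(preds, truths)]))


def _to_labels(preds) -> np.ndarray:
    arr = np.asarray(preds)
    if arr.ndim == 2:           # probability vectors; ties -> lowest index
        return arr.argmax(axis=1)
    if arr.ndim == 1 and np.issubdtype(arr.dtype, np.integer):
        return arr
    if arr.ndim == 1:
        return arr.astype(int)
    raise ValueError(f"cannot interpret predictions with shape {arr.shape}")


def accuracy(preds, truths) -> float:
    """Fraction of correct argmax predictions.

    ``preds`` may be an (n, n_classes) matrix of probability vectors or a
    vector of label indices; argmax ties break to the lowest class index.
    """
    yhat = _to_labels(preds)
    y = np.asarray(truths)
    if yhat.size == 0 or yhat.shape != y.shape:
        raise ValueError("predictions and truths must be non-empty and paired")
    return float((yhat == y).mean())


def confusion_matrix(preds, truths, n_classes: int) -> np.ndarray:
    """Count matrix with entry (i, j) = truth class i predicted as class j."""
    yhat = _to_labels(preds)
    y = np.asarray(truths)
    if yhat.size == 0 or yhat.shape != y.shape:
        raise ValueError("predictions and truths must be non-empty and paired")
    for name, arr in (("prediction", yhat), ("truth", y)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    return _sk_confusion(y, yhat, labels=np.arange(n_classes))


@dataclass
class EvalReport:
    """Joint report: segmentation dice, classification accuracy, confusion."""

    dice: float
    accuracy: float
    confusion: list
    n_samples: int

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_predictions(cls, nfms, masks, class_probs, class_truths,
                         n_classes: int, threshold: float = 0.5) -> "EvalReport":
        conf = confusion_matrix(class_probs, class_truths, n_classes)
        return cls(dice=mean_dice(nfms, masks, threshold),
                   accuracy=accuracy(class_probs, class_truths),
                   confusion=conf.tolist(),
                   n_samples=int(np.asarray(class_truths).size))
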