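"""Joint segmentation-classification training.

Two training streams are interleaved.  A *segmentation step* draws an
(image, mask) batch, applies the complementary-color conversion, and updates
only the segmentation network with the dice+focal loss.  A *classification
step* draws an (image, label) batch — no masks exist for these images — runs
image -> NFM -> NFWI -> classifier, and updates *both* networks with the
total loss; with no mask available the segmentation term contributes
nothing, so the effective signal is ``lambda_c * L_c`` propagating into the
segmentation network through the NFM x image product.  The ``separated``
mode is the control: the segmentation network is trained to convergence
first, then frozen while the classifier trains on its NFWIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import losses as L
from .augmentation import C3SPolicy, apply_c3s
from .cls_network import BHCNet, BHCNetConfig, build_bhcnet
from .nn import Adam, Tensor
from .seg_network import DIUNet, DIUNetConfig, build_diunet

__all__ = ["TrainConfig", "TrainingHistory", "JointTrainer", "fuse", "train",
           "predict_proba"]


@dataclass
class TrainConfig:
    """Optimisation and scheduling parameters for joint/separated training.

    ``interleave_ratio`` is (segmentation steps : classification steps) per
    cycle in joint mode.  ``total_steps`` counts individual gradient steps of
    either kind.  The learning rate default suits the tiny desk-scale
    presets; larger networks warrant smaller rates.
    """

    optimizer: str = "adam"
    lr: float = 3e-3
    seg_batch_size: int = 4
    cls_batch_size: int = 8
    interleave_ratio: Tuple[int, int] = (1, 1)
    total_steps: int = 200
    seed: int = 0
    mode: str = "joint"
    task: str = "binary"
    loss: L.LossConfig = field(default_factory=L.LossConfig)
    c3s: Optional[C3SPolicy] = field(default_factory=C3SPolicy)
    seg: DIUNetConfig = field(default_factory=DIUNetConfig)
    cls: BHCNetConfig = field(default_factory=BHCNetConfig)

    def __post_init__(self):
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        if min(self.interleave_ratio) < 1:
            raise ValueError("interleave_ratio parts must be positive")
        if self.mode not in ("joint", "separated"):
            raise ValueError("mode must be 'joint' or 'separated'")
        if self.task not in ("binary", "multiclass"):
            raise ValueError("task must be 'binary' or 'multiclass'")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is provided")


@dataclass
class TrainingHistory:
    """Per-step loss records plus any periodic validation entries."""

    records: List[dict] = field(default_factory=list)

    def log(self, **kwargs) -> None:
        self.records.append(kwargs)

    def of_kind(self, kind: str) -> List[dict]:
        return [r for r in self.records if r["kind"] == kind]


def _stack_images(images: Sequence[np.ndarray]) -> Tensor:
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return Tensor(arr.transpose(0, 3, 1, 2))


def fuse(image: Union[Tensor, np.ndarray], nfm: Union[Tensor, np.ndarray]) -> Tensor:
    """Nucleus-focus-weighted image: per-pixel, per-channel product of the
    input image and the (soft, unthresholded) focus map.

    ``image`` is (N, 3, H, W) and ``nfm`` (N, 1, H, W) (or single HxWx3 /
    HxW arrays, which are promoted).  Gradients flow through ``nfm`` back
    into the segmentation network.
    """
    img = image if isinstance(image, Tensor) else Tensor(
        np.asarray(image, dtype=np.float32).transpose(2, 0, 1)[None])
    m = nfm if isinstance(nfm, Tensor) else Tensor(
        np.asarray(nfm, dtype=np.float32)[None, None])
    if m.shape[-2:] != img.shape[-2:]:
        raise ValueError(f"spatial mismatch: image {img.shape} vs nfm {m.shape}")
    return img * m


class JointTrainer:
    """Holds the two networks, their optimisers and the step logic."""

    def __init__(self, seg_model: DIUNet, cls_model: BHCNet, cfg: TrainConfig):
        self.seg_model = seg_model
        self.cls_model = cls_model
        self.cfg = cfg
        self.history = TrainingHistory()
        self.rng = np.random.default_rng(cfg.seed)
        self.seg_opt = Adam(seg_model.parameters(), lr=cfg.lr)
        self.joint_opt = Adam(seg_model.parameters() + cls_model.parameters(),
                              lr=cfg.lr)
        self.cls_opt = Adam(cls_model.parameters(), lr=cfg.lr)
        self._step = 0

    # ------------------------------------------------------------ seg step
    def seg_step(self, seg_batch: Sequence[Tuple[np.ndarray, np.ndarray]]) -> float:
        """One gradient update of the segmentation network only."""
        images = _stack_images([im for im, _ in seg_batch])
        masks = np.stack([m for _, m in seg_batch]).astype(np.float32)
        self.seg_model.train()
        images.requires_grad = False
        pred = self.seg_model(images)
        loss = L.segmentation_loss(pred.reshape(-1), masks.reshape(-1), self.cfg.loss)
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite segmentation loss at step "
                                     f"{self._step}: {value}")
        self.seg_opt.zero_grad()
        loss.backward()
        self.seg_opt.step()
        self._step += 1
        self.history.log(step=self._step, kind="seg", l_seg=value)
        return value

    # ------------------------------------------------------------ cls step
    def cls_step(self, cls_batch: Sequence[Tuple[np.ndarray, int]],
                 update_seg: bool = True) -> float:
        """One update through segment -> fuse -> classify.

        ``update_seg=False`` freezes the segmentation network (separated
        mode); otherwise the total loss updates both networks.
        """
        images = _stack_images([im for im, _ in cls_batch])
        labels = np.array([y for _, y in cls_batch], dtype=np.int64)
        if update_seg:
            self.seg_model.train()
        else:
            self.seg_model.eval()
        self.cls_model.train()
        nfm = self.seg_model(images)
        probs = self.cls_model(fuse(images, nfm))
        if self.cfg.task == "binary":
            # yhat_k = predicted probability of the positive (class-1) label
            pos = _gather(probs, np.ones(labels.size, dtype=np.int64))
            l_c = L.binary_ce(pos, labels, self.cfg.loss)
        else:
            l_c = L.multiclass_ce(_gather(probs, labels), self.cfg.loss)
        # no masks exist for classification images: the segmentation term of
        # the total loss has no ground truth here and contributes zero
        loss = L.total_loss(0.0, l_c, self.cfg.loss)
        value_c, value_t = l_c.item(), loss.item()
        if not np.isfinite(value_t):
            raise FloatingPointError(f"non-finite total loss at step "
                                     f"{self._step}: {value_t}")
        opt = self.joint_opt if update_seg else self.cls_opt
        opt.zero_grad()
        loss.backward()
        opt.step()
        self._step += 1
        self.history.log(step=self._step, kind="cls", l_c=value_c, l_total=value_t)
        return value_t

    # ------------------------------------------------------------ sampling
    def _draw(self, data, size: int):
        idx = self.rng.choice(len(data), size=min(size, len(data)), replace=False)
        return [data[i] for i in idx]


def _gather(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Select probs[i, labels[i]] as a differentiable vector."""
    onehot = np.zeros(probs.shape, dtype=np.float32)
    onehot[np.arange(labels.size), labels] = 1.0
    return (probs * onehot).sum(axis=1)


def train(seg_data: Sequence[Tuple[np.ndarray, np.ndarray]],
          cls_data: Sequence[Tuple[np.ndarray, int]],
          cfg: TrainConfig,
          seg_model: Optional[DIUNet] = None,
          cls_model: Optional[BHCNet] = None
          ) -> Tuple[DIUNet, BHCNet, TrainingHistory]:
    """Train the joint model (or the separated-training control).

    In ``joint`` mode, segmentation and classification steps alternate at
    ``interleave_ratio``.  In ``separated`` mode the segmentation network is
    trained alone for the first half of the budget, then frozen while the
    classifier trains on its weighted images.  Fully reproducible from
    ``cfg.seed``.
    """
    if len(seg_data) == 0:
        raise ValueError("segmentation dataset is empty")
    if cfg.mode in ("joint", "separated") and len(cls_data) == 0:
        raise ValueError("classification dataset is empty")

    seg_model = seg_model or build_diunet(cfg.seg, seed=cfg.seed)
    cls_model = cls_model or build_bhcnet(cfg.cls, seed=cfg.seed + 1)
    trainer = JointTrainer(seg_model, cls_model, cfg)
    c3s_rng = np.random.default_rng(
        cfg.c3s.rng_seed if cfg.c3s is not None else 0)

    def seg_batch():
        batch = trainer._draw(seg_data, cfg.seg_batch_size)
        if cfg.c3s is not None:
            batch = apply_c3s(batch, cfg.c3s, rng=c3s_rng)
        return batch

    if cfg.mode == "joint":
        a, b = cfg.interleave_ratio
        kinds = ["seg"] * a + ["cls"] * b
        for i in range(cfg.total_steps):
            if kinds[i % len(kinds)] == "seg":
                trainer.seg_step(seg_batch())
            else:
                trainer.cls_step(trainer._draw(cls_data, cfg.cls_batch_size))
    else:
        n_seg = cfg.total_steps // 2
        for _ in range(n_seg):
            trainer.seg_step(seg_batch())
        for _ in range(cfg.total_steps - n_seg):
            trainer.cls_step(trainer._draw(cls_data, cfg.cls_batch_size),
                             update_seg=False)
    return seg_model, cls_model, trainer.history


def predict_proba(seg_model: DIUNet, cls_model: BHCNet,
                  images: Sequence[np.ndarray]) -> np.ndarray:
    """Inference pipeline image -> NFM -> NFWI -> class probabilities."""
    seg_model.eval()
    cls_model.eval()
    x = _stack_images(images)
    nfm = seg_model(x)
    return cls_model(fuse(x, nfm)).data
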