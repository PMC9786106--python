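"""BHCNet-style classifier built from small SE-ResNet blocks.

A small SE-ResNet block is a two-convolution residual block whose output is
recalibrated channel-wise by a squeeze-and-excitation (SE) path: global
average pooling squeezes each channel to a scalar, two fully connected
layers (C -> C/r -> C) with ReLU/sigmoid produce per-channel weights, and
the block output is scaled by them before the residual addition.

The classifier stacks three channel groups (c, 2c, 4c) of these blocks with
2x2 max-pooling between groups, then global average pooling and a softmax
head.  ``variant`` sets the total number of SE-ResNet blocks: BHCNet-3 (one
block per group) for the benign/malignant task and the deeper BHCNet-6 (two
per group) for the eight-subtype task — the two differ only in depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["BHCNetConfig", "SEBlock", "SmallSEResNetBlock", "BHCNet",
           "build_bhcnet", "classify"]


@dataclass
class BHCNetConfig:
    """``variant`` in {3, 6}; ``n_classes`` defaults to 2 for variant 3 and
    8 for variant 6 (overridable); ``base_channels`` is the stem width."""

    variant: int = 3
    n_classes: Optional[int] = None
    se_reduction: int = 16
    base_channels: int = 8
    in_channels: int = 3

    def __post_init__(self):
        if self.variant not in (3, 6):
            raise ValueError(f"unsupported variant {self.variant}; expected 3 or 6")
        if self.n_classes is None:
            self.n_classes = 2 if self.variant == 3 else 8
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @classmethod
    def preset(cls, name: str, variant: int = 3) -> "BHCNetConfig":
        if name == "paper":
            return cls(variant=variant, base_channels=32)
        if name == "tiny":
            return cls(variant=variant, base_channels=8, se_reduction=4)
        raise ValueError(f"unknown preset {name!r}")


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel recalibration (C -> C/r -> C)."""

    def __init__(self, channels: int, reduction: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = nn.global_avg_pool(x)                      # (N, C)
        s = self.fc2(self.fc1(s).relu()).sigmoid()     # (N, C)
        n, c = s.shape
        return x * s.reshape(n, c, 1, 1)


class SmallSEResNetBlock(nn.Module):
    """conv-BN-ReLU -> conv-BN -> SE scaling -> residual add -> ReLU."""

    def __init__(self, in_channels: int, out_channels: int, se_reduction: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.conv1 = nn.ConvBNReLU(in_channels, out_channels, 3, rng=rng)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.GroupNorm(out_channels)
        self.se = SEBlock(out_channels, se_reduction, rng=rng)
        self.shortcut = (nn.Conv2d(in_channels, out_channels, 1, rng=rng)
                         if in_channels != out_channels else None)

    def forward(self, x: Tensor) -> Tensor:
        y = self.se(self.bn2(self.conv2(self.conv1(x))))
        sc = self.shortcut(x) if self.shortcut is not None else x
        return (y + sc).relu()


class BHCNet(nn.Module):
    def __init__(self, cfg: BHCNetConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        c = cfg.base_channels
        per_group = cfg.variant // 3
        self.stem = nn.ConvBNReLU(cfg.in_channels, c, 3, rng=rng)
        self.blocks = nn.ModuleList()
        self.pools = nn.ModuleList()
        c_prev = c
        for g, cg in enumerate((c, 2 * c, 4 * c)):
            if g > 0:
                self.pools.append(nn.MaxPool2x2())
            for _ in range(per_group):
                self.blocks.append(SmallSEResNetBlock(
                    c_prev, cg, cfg.se_reduction, rng=rng))
                c_prev = cg
        self.per_group = per_group
        self.fc = nn.Linear(c_prev, cfg.n_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input (N, {self.cfg.in_channels}, H, W), got {x.shape}")
        x = self.stem(x)
        for g in range(3):
            if g > 0:
                x = self.pools[g - 1](x)
            for b in range(self.per_group):
                x = self.blocks[g * self.per_group + b](x)
        logits = self.fc(nn.global_avg_pool(x))
        return nn.softmax(logits, axis=-1)


def build_bhcnet(cfg: Optional[BHCNetConfig] = None, seed: int = 0) -> BHCNet:
    """Construct a BHCNet classifier from its configuration."""
    return BHCNet(cfg or BHCNetConfig(), rng=np.random.default_rng(seed))


def classify(model: BHCNet, nfwi: np.ndarray) -> np.ndarray:
    """Classify a nucleus-focus-weighted image; returns the probability vector.

    ``nfwi`` is (H, W, 3) in [0, 1] (or a batch (N, H, W, 3), in which case a
    (N, n_classes) matrix is returned).  Deterministic in inference mode.
    """
    arr = np.asarray(nfwi, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != model.cfg.in_channels:
        raise ValueError(f"cannot interpret NFWI with shape {nfwi.shape}")
    was_training = model.training
    model.eval()
    probs = model(Tensor(arr.transpose(0, 3, 1, 2))).data
    if was_training:
        model.train()
    return probs[0] if single else probs
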