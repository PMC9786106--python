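"""Dilated Inception U-Net (DIU-Net) for soft nucleus segmentation.

The network is an attention U-Net whose encoder and decoder convolution
stages are Dilated Inception (DI) blocks: four parallel branches — 1x1,
1x1->3x3, 1x1->5x5, and a dilated 3x3 followed by 1x1 — concatenated on the
channel axis.  Relative to a classic Inception module the pooling branch is
replaced by the dilated-convolution branch, so the block captures multiple
receptive-field scales without losing spatial information to pooling.
Downsampling *between* U-Net levels remains 2x2 max-pooling; upsampling is a
2x2 transposed convolution.  Additive attention gates sit on every skip
connection.  The head is a 1x1 convolution with a sigmoid, so the output is
a per-pixel nucleus focus weight in [0, 1] (the Nucleus Focus Map).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "DIBlockConfig", "DIUNetConfig", "DIBlock", "AttentionGate", "DIUNet",
    "build_di_block", "build_diunet", "segment", "contains_pooling",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class DIBlockConfig:
    """Configuration of one Dilated Inception block."""

    in_channels: int
    out_channels: int
    dilation_rate: int = 2
    # fraction of out_channels given to each of the four branches
    branch_fractions: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.dilation_rate < 2:
            raise ValueError("dilation_rate must be >= 2 (rate 1 is a plain conv)")
        chans = [round(f * self.out_channels) for f in self.branch_fractions]
        if sum(chans) != self.out_channels or any(c < 1 for c in chans):
            raise ValueError(
                f"branch_fractions {self.branch_fractions} do not split "
                f"{self.out_channels} channels into four positive integers")
        self.branch_channels = tuple(chans)


@dataclass
class DIUNetConfig:
    """Configuration of the full DIU-Net.

    ``depth`` counts resolution levels including the bottleneck; spatial
    input dims must be divisible by ``2**(depth-1)``.  The ``paper`` preset
    uses the 64->128->256->512 channel ladder; ``tiny`` (8->16->32->64 at
    depth 3) is the desk-scale default for CPU experiments.
    """

    depth: int = 3
    base_channels: int = 8
    channel_growth: int = 2
    dilation_rate: int = 2
    attention_gates: bool = True
    in_channels: int = 3

    @classmethod
    def preset(cls, name: str) -> "DIUNetConfig":
        if name == "paper":
            return cls(depth=4, base_channels=64)
        if name == "tiny":
            return cls(depth=3, base_channels=8)
        raise ValueError(f"unknown preset {name!r}")


class DIBlock(nn.Module):
    """Four-branch Dilated Inception block; concatenation preserves H x W."""

    def __init__(self, cfg: DIBlockConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        c_in = cfg.in_channels
        c1, c3, c5, cd = cfg.branch_channels
        d = cfg.dilation_rate
        self.branch1 = nn.ConvBNReLU(c_in, c1, 1, rng=rng)
        self.branch3 = nn.Sequential(
            nn.ConvBNReLU(c_in, max(c3 // 2, 1), 1, rng=rng),
            nn.ConvBNReLU(max(c3 // 2, 1), c3, 3, rng=rng))
        self.branch5 = nn.Sequential(
            nn.ConvBNReLU(c_in, max(c5 // 2, 1), 1, rng=rng),
            nn.ConvBNReLU(max(c5 // 2, 1), c5, 5, rng=rng))
        # dilated branch replaces the Inception pooling branch
        self.branch_dil = nn.Sequential(
            nn.ConvBNReLU(c_in, cd, 3, dilation=d, rng=rng),
            nn.ConvBNReLU(cd, cd, 1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        return nn.concat([self.branch1(x), self.branch3(x),
                          self.branch5(x), self.branch_dil(x)], axis=1)


class AttentionGate(nn.Module):
    """Additive attention on a skip connection.

    The decoder's (upsampled) gating signal and the encoder skip feature are
    each projected by 1x1 convolutions, summed, passed through ReLU and a
    final 1x1 convolution with sigmoid; the resulting per-pixel coefficient
    rescales the skip feature.
    """

    def __init__(self, gate_channels: int, skip_channels: int,
                 inter_channels: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.w_gate = nn.Conv2d(gate_channels, inter_channels, 1, rng=rng)
        self.w_skip = nn.Conv2d(skip_channels, inter_channels, 1, rng=rng)
        self.psi = nn.Conv2d(inter_channels, 1, 1, rng=rng)

    def forward(self, gate: Tensor, skip: Tensor) -> Tensor:
        alpha = self.psi((self.w_gate(gate) + self.w_skip(skip)).relu()).sigmoid()
        return skip * alpha


class DIUNet(nn.Module):
    """Encoder-decoder with DI blocks and attention-gated skips."""

    def __init__(self, cfg: DIUNetConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        chans = [cfg.base_channels * cfg.channel_growth ** i for i in range(cfg.depth)]

        self.encoders = nn.ModuleList()
        self.pools = nn.ModuleList()
        c_prev = cfg.in_channels
        for c in chans[:-1]:
            self.encoders.append(DIBlock(
                DIBlockConfig(c_prev, c, cfg.dilation_rate), rng=rng))
            self.pools.append(nn.MaxPool2x2())
            c_prev = c
        self.bottleneck = DIBlock(
            DIBlockConfig(c_prev, chans[-1], cfg.dilation_rate), rng=rng)

        self.upconvs = nn.ModuleList()
        self.gates = nn.ModuleList()
        self.decoders = nn.ModuleList()
        c_prev = chans[-1]
        for c in reversed(chans[:-1]):
            self.upconvs.append(nn.ConvTranspose2x2(c_prev, c, rng=rng))
            if cfg.attention_gates:
                self.gates.append(AttentionGate(c, c, max(c // 2, 1), rng=rng))
            self.decoders.append(DIBlock(
                DIBlockConfig(2 * c, c, cfg.dilation_rate), rng=rng))
            c_prev = c
        self.head = nn.Conv2d(c_prev, 1, 1, rng=rng)

    def _check_input(self, x: Tensor) -> None:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input (N, {self.cfg.in_channels}, H, W), got {x.shape}")
        div = 2 ** (self.cfg.depth - 1)
        h, w = x.shape[2], x.shape[3]
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by "
                f"2**(depth-1) = {div} for depth {self.cfg.depth}")

    def forward(self, x: Tensor) -> Tensor:
        self._check_input(x)
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc(x)
            skips.append(x)
            x = pool(x)
        x = self.bottleneck(x)
        for i, (up, dec) in enumerate(zip(self.upconvs, self.decoders)):
            x = up(x)
            skip = skips[-(i + 1)]
            if self.cfg.attention_gates:
                skip = self.gates[i](x, skip)
            x = dec(nn.concat([skip, x], axis=1))
        return self.head(x).sigmoid()


def build_di_block(cfg: DIBlockConfig,
                   rng: Optional[np.random.Generator] = None) -> DIBlock:
    """Construct a single DI block from its configuration."""
    return DIBlock(cfg, rng=rng)


def build_diunet(cfg: Union[DIUNetConfig, str, None] = None, seed: int = 0) -> DIUNet:
    """Construct a DIU-Net from a config object or preset name."""
    if cfg is None:
        cfg = DIUNetConfig()
    elif isinstance(cfg, str):
        cfg = DIUNetConfig.preset(cfg)
    return DIUNet(cfg, rng=np.random.default_rng(seed))


def contains_pooling(module: nn.Module) -> bool:
    """Structural audit: does any submodule perform pooling?"""
    return any(isinstance(m, nn.MaxPool2x2) for m in module.modules())


def _to_nchw(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim == 3:
        img = img.transpose(2, 0, 1)[None]
    elif img.ndim != 4:
        raise ValueError(f"cannot interpret image with shape {image.shape}")
    return img


def segment(model: DIUNet, image: np.ndarray) -> np.ndarray:
    """Run soft-segmentation inference: image (H, W, 3) in [0,1] -> NFM (H, W).

    The model is switched to eval mode, so the result is deterministic.
    """
    arr = _to_nchw(image)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("image must be normalised to [0, 1]")
    was_training = model.training
    model.eval()
    nfm = model(Tensor(arr)).data[0, 0]
    if was_training:
        model.train()
    return nfm


def save_checkpoint(model: nn.Module, path: Union[str, Path]) -> None:
    """Save parameters and batch-norm statistics to a single ``.npz`` file."""
    np.savez(path, __format_version__=np.int64(1), **model.state_dict())


def load_checkpoint(model: nn.Module, path: Union[str, Path]) -> None:
    with np.load(path) as data:
        state = {k: data[k] for k in data.files if k != "__format_version__"}
    model.load_state_dict(state)
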