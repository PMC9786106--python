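"""Validated run configuration (YAML-backed, schema-checked).

Every section mirrors one module's dataclass; unknown keys are rejected so
typos fail loudly.  ``RunConfig.to_*`` methods hand the validated values to
the library objects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .augmentation import C3SPolicy
from .cls_network import BHCNetConfig
from .losses import LossConfig
from .seg_network import DIUNetConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegSection(_Section):
    preset: Optional[str] = None            # "paper" | "tiny"
    depth: int = 3
    base_channels: int = 8
    dilation_rate: int = Field(2, ge=2)
    attention_gates: bool = True


class ClsSection(_Section):
    preset: Optional[str] = None
    variant: int = 3
    n_classes: Optional[int] = None
    se_reduction: int = Field(16, ge=1)
    base_channels: int = 8
    input_size: int = 64


class LossSection(_Section):
    eps: float = Field(1e-6, gt=0)
    lambda_s: float = Field(1.0, ge=0)
    lambda_c: float = Field(0.99, ge=0, le=1)
    clamp_delta: float = Field(1e-7, gt=0, lt=0.5)
    reduction: str = "sum"


class C3SSection(_Section):
    enabled: bool = True
    fraction: float = Field(0.5, ge=0, le=1)
    seed: int = 0


class TrainSection(_Section):
    optimizer: str = "adam"
    lr: float = Field(3e-3, gt=0)
    seg_batch_size: int = Field(4, ge=1)
    cls_batch_size: int = Field(8, ge=1)
    interleave_seg: int = Field(1, ge=1)
    interleave_cls: int = Field(1, ge=1)
    total_steps: int = Field(200, ge=1)
    seed: int = 0
    mode: str = "joint"
    task: str = "binary"


class EvalSection(_Section):
    threshold: float = Field(0.5, gt=0, lt=1)


class RunConfig(_Section):
    seg: SegSection = SegSection()
    cls: ClsSection = ClsSection()
    loss: LossSection = LossSection()
    c3s: C3SSection = C3SSection()
    train: TrainSection = TrainSection()
    eval: EvalSection = EvalSection()

    # ----------------------------------------------------------- converters
    def to_loss_config(self) -> LossConfig:
        return LossConfig(**self.loss.model_dump())

    def to_c3s_policy(self) -> Optional[C3SPolicy]:
        if not self.c3s.enabled:
            return None
        return C3SPolicy(fraction=self.c3s.fraction, rng_seed=self.c3s.seed)

    def to_seg_config(self) -> DIUNetConfig:
        if self.seg.preset:
            return DIUNetConfig.preset(self.seg.preset)
        return DIUNetConfig(depth=self.seg.depth,
                            base_channels=self.seg.base_channels,
                            dilation_rate=self.seg.dilation_rate,
                            attention_gates=self.seg.attention_gates)

    def to_cls_config(self) -> BHCNetConfig:
        if self.cls.preset:
            return BHCNetConfig.preset(self.cls.preset, variant=self.cls.variant)
        return BHCNetConfig(variant=self.cls.variant,
                            n_classes=self.cls.n_classes,
                            se_reduction=self.cls.se_reduction,
                            base_channels=self.cls.base_channels)

    def to_train_config(self):
        from .joint_training import TrainConfig
        t = self.train
        return TrainConfig(optimizer=t.optimizer, lr=t.lr,
                           seg_batch_size=t.seg_batch_size,
                           cls_batch_size=t.cls_batch_size,
                           interleave_ratio=(t.interleave_seg, t.interleave_cls),
                           total_steps=t.total_steps, seed=t.seed,
                           mode=t.mode, task=t.task,
                           loss=self.to_loss_config(),
                           c3s=self.to_c3s_policy(),
                           seg=self.to_seg_config(),
                           cls=self.to_cls_config())


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration; empty file -> defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        keys = ", ".join(".".join(str(p) for p in err["loc"]) for err in e.errors())
        raise ValueError(f"invalid configuration in {path}: offending keys: {keys}") from e


def dump_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Write a config back to YAML; ``load_config`` round-trips to equality."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
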