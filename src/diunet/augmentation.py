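"""Complementary Color Conversion Scheme (C3S).

Converting a random subset of training images to their complementary colors
(per-channel intensity inversion v -> 1 - v) removes color and
relative-brightness polarity as a usable cue: a network that must segment
both a nucleus-darker image and its complement is pushed toward texture and
shape features, which transfer across staining appearances.  Masks are never
touched, and the conversion is a training-time-only operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["C3SPolicy", "complement", "apply_c3s"]


@dataclass
class C3SPolicy:
    """Per-sample conversion probability and the seed driving the draws."""

    fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


def complement(image: np.ndarray) -> np.ndarray:
    """Complementary-color image: 1 - v per channel per pixel (an involution).

    Arithmetic runs in float64, where ``1 - v`` is exact for any float32
    input, so ``complement(complement(x))`` reproduces ``x`` bit-for-bit.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return 1.0 - img


def apply_c3s(batch: Sequence[Tuple[np.ndarray, np.ndarray]],
              policy: C3SPolicy,
              rng: Optional[np.random.Generator] = None
              ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Complement each (image, mask) sample independently with probability
    ``policy.fraction``; masks pass through untouched.

    With the default ``rng=None`` the generator is seeded from
    ``policy.rng_seed``, so repeated calls select the same subset.  A trainer
    that wants fresh draws every step passes its own generator.
    """
    rng = rng if rng is not None else np.random.default_rng(policy.rng_seed)
    out = []
    for image, mask in batch:
        if policy.fraction > 0 and rng.random() < policy.fraction:
            out.append((complement(image), mask))
        else:
            out.append((image, mask))
    return out
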