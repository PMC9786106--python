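"""DIU-Net architecture audits, shape contracts and training sanity."""

import numpy as np
import pytest

from diunet import nn
from diunet.nn import Tensor
from diunet.seg_network import (
    DIBlock,
    DIBlockConfig,
    DIUNetConfig,
    build_di_block,
    build_diunet,
    contains_pooling,
    load_checkpoint,
    save_checkpoint,
    segment,
)


@pytest.fixture(scope="module")
def tiny_net():
    return build_diunet("tiny", seed=0)


def test_di_block_preserves_spatial_size_and_channels():
    blk = build_di_block(DIBlockConfig(in_channels=3, out_channels=8))
    y = blk(Tensor(np.random.default_rng(0).random((1, 3, 32, 32))
                   .astype(np.float32)))
    assert y.shape == (1, 8, 32, 32)


def test_di_block_contains_no_pooling(tiny_net):
    """The dilated branch replaces Inception's pooling branch; the audit of
    every DI block must list zero pooling operators (downsampling between
    U-Net levels is separate and allowed)."""
    blk = build_di_block(DIBlockConfig(3, 8))
    assert not contains_pooling(blk)
    for m in tiny_net.modules():
        if isinstance(m, DIBlock):
            assert not contains_pooling(m)
    assert contains_pooling(tiny_net)  # between-level pooling exists


def test_di_block_has_four_branches_with_dilated_conv():
    blk = build_di_block(DIBlockConfig(4, 16, dilation_rate=3))
    dilations = [m.dilation for m in blk.modules() if isinstance(m, nn.Conv2d)]
    assert 3 in dilations
    kernels = {m.weight.shape[-1] for m in blk.modules() if isinstance(m, nn.Conv2d)}
    assert {1, 3, 5} <= kernels


def test_di_block_config_validation():
    with pytest.raises(ValueError):
        DIBlockConfig(3, 8, dilation_rate=1)       # degenerate dilation
    with pytest.raises(ValueError):
        DIBlockConfig(3, 6)                         # 6 not divisible by 4
    with pytest.raises(ValueError):
        DIBlockConfig(0, 8)


def test_diunet_output_shape_and_range(tiny_net):
    for size in (32, 64):
        x = Tensor(np.random.default_rng(1).random((1, 3, size, size))
                   .astype(np.float32))
        tiny_net.eval()
        y = tiny_net(x)
        assert y.shape == (1, 1, size, size)
        assert y.data.min() >= 0.0 and y.data.max() <= 1.0


def test_diunet_rejects_indivisible_input(tiny_net):
    x = Tensor(np.zeros((1, 3, 30, 30), dtype=np.float32))
    with pytest.raises(ValueError, match="divisible"):
        tiny_net(x)


def test_attention_gates_off_reduces_parameters():
    base = DIUNetConfig(depth=3, base_channels=8)
    with_gates = build_diunet(base, seed=0)
    without = build_diunet(DIUNetConfig(depth=3, base_channels=8,
                                        attention_gates=False), seed=0)
    assert without.n_parameters() < with_gates.n_parameters()
    x = np.random.default_rng(2).random((32, 32, 3)).astype(np.float32)
    assert segment(without, x).shape == (32, 32)


def test_parameter_count_grows_with_width():
    small = build_diunet(DIUNetConfig(depth=3, base_channels=8), seed=0)
    wide = build_diunet(DIUNetConfig(depth=3, base_channels=16), seed=0)
    assert wide.n_parameters() > small.n_parameters()


def test_segment_deterministic_and_stable(tiny_net):
    x = np.zeros((32, 32, 3), dtype=np.float32)
    a = segment(tiny_net, x)
    b = segment(tiny_net, x)
    assert np.array_equal(a, b)
    assert np.all(np.isfinite(a)) and a.min() >= 0 and a.max() <= 1
    with pytest.raises(ValueError):
        segment(tiny_net, np.full((32, 32, 3), 2.0, dtype=np.float32))


def test_every_parameter_receives_gradient():
    net = build_diunet(DIUNetConfig(depth=3, base_channels=8), seed=3)
    net.train()
    rng = np.random.default_rng(3)
    x = Tensor(rng.random((2, 3, 16, 16)).astype(np.float32))
    target = (rng.random((2, 1, 16, 16)) < 0.3).astype(np.float32)
    pred = net(x)
    from diunet.losses import LossConfig, segmentation_loss
    loss = segmentation_loss(pred.reshape(-1), target.reshape(-1), LossConfig())
    loss.backward()
    for name, p in net.named_parameters():
        assert p.grad is not None, f"no gradient for {name}"
        assert np.any(p.grad != 0), f"zero gradient for {name}"


def test_checkpoint_roundtrip(tmp_path, tiny_net):
    path = tmp_path / "seg.npz"
    save_checkpoint(tiny_net, path)
    other = build_diunet("tiny", seed=99)
    x = np.random.default_rng(5).random((32, 32, 3)).astype(np.float32)
    assert not np.allclose(segment(other, x), segment(tiny_net, x))
    load_checkpoint(other, path)
    assert np.allclose(segment(other, x), segment(tiny_net, x))


def test_preset_validation():
    with pytest.raises(ValueError):
        DIUNetConfig.preset("huge")
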