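"""Loss functions versus naive per-element loop oracles and analytic limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from diunet.losses import (
    LossConfig,
    binary_ce,
    classification_loss,
    dice_loss,
    focal_loss,
    focal_transform,
    multiclass_ce,
    segmentation_loss,
    total_loss,
)

from oracles import oracle_bce, oracle_dice, oracle_focal, oracle_mce, random_case

EPS0 = LossConfig(eps=1e-12)  # near-zero stabiliser for analytic limits


# ------------------------------------------------------------- worked examples
def test_dice_worked_example():
    """1 - 1.4/4.0 - 1.4/4.0 = 0.30 for the mixed four-pixel case."""
    val = dice_loss([0.8, 0.2, 0.6, 0.4], [1, 0, 1, 0], EPS0).item()
    assert val == pytest.approx(0.30, abs=1e-9)


def test_dice_perfect_and_worst_limits():
    truth = np.array([1, 0, 1, 1, 0], dtype=float)
    assert dice_loss(truth, truth, EPS0).item() == pytest.approx(0.0, abs=1e-8)
    assert dice_loss(1 - truth, truth, EPS0).item() == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("y,p,expected", [
    (1.0, 0.9, 0.9),   # nucleus pixel keeps its predicted probability
    (0.0, 0.9, 0.1),   # background pixel flips it
    (0.0, 0.0, 1.0),   # confident correct background
])
def test_focal_transform_piecewise(y, p, expected):
    assert focal_transform([p], [y]).numpy()[0] == pytest.approx(expected)


def test_focal_worked_example_and_additivity():
    single = focal_loss([0.5], [1.0], EPS0).item()
    assert single == pytest.approx(0.25 * math.log(2), rel=1e-9)
    many = focal_loss([0.5] * 7, [1.0] * 7, EPS0).item()
    assert many == pytest.approx(7 * single, rel=1e-9)
    assert focal_loss([1.0, 0.0], [1.0, 0.0], EPS0).item() == pytest.approx(0.0)


def test_binary_ce_worked_example_and_additivity():
    assert binary_ce([0.5, 0.5], [1, 0], EPS0).item() == pytest.approx(
        2 * math.log(2), rel=1e-9)
    one = binary_ce([0.3], [1], EPS0).item()
    assert binary_ce([0.3] * 5, [1] * 5, EPS0).item() == pytest.approx(5 * one)
    # confident correct prediction is ~0 up to the clamp floor
    assert binary_ce([1.0 - 1e-7], [1], EPS0).item() == pytest.approx(0.0, abs=1e-6)


def test_multiclass_ce_worked_examples():
    assert multiclass_ce([0.125], EPS0).item() == pytest.approx(math.log(8), rel=1e-9)
    assert multiclass_ce([0.5] * 4, EPS0).item() == pytest.approx(4 * math.log(2))
    assert multiclass_ce([1.0, 1.0], EPS0).item() == pytest.approx(0.0, abs=1e-6)


def test_segmentation_loss_composition():
    pred, truth = [0.8, 0.2, 0.6, 0.4], [1, 0, 1, 0]
    cfg = LossConfig(eps=1e-12, lambda_s=1.0)
    expected = oracle_dice(pred, truth, cfg.eps) + oracle_focal(pred, truth,
                                                                cfg.clamp_delta)
    assert segmentation_loss(pred, truth, cfg).item() == pytest.approx(expected)
    cfg0 = LossConfig(eps=1e-12, lambda_s=0.0)
    assert segmentation_loss(pred, truth, cfg0).item() == pytest.approx(
        dice_loss(pred, truth, cfg0).item())


def test_total_loss_arithmetic():
    assert total_loss(1.0, 2.0, LossConfig(lambda_c=0.99)).item() == pytest.approx(1.99)
    assert total_loss(3.0, 7.0, LossConfig(lambda_c=0.0)).item() == pytest.approx(3.0)
    assert total_loss(3.0, 7.0, LossConfig(lambda_c=1.0)).item() == pytest.approx(7.0)
    x = 1.234
    assert total_loss(x, x, LossConfig(lambda_c=0.5)).item() == pytest.approx(x)


def test_total_loss_symmetry_at_half():
    cfg = LossConfig(lambda_c=0.5)
    a, b = 0.7, 2.9
    assert (total_loss(a, b, cfg).item() + total_loss(b, a, cfg).item()
            == pytest.approx(a + b))


# --------------------------------------------------------- oracle equivalence
def test_vectorized_losses_match_loop_oracles():
    """>=100 random cases, N <= 256: every loss matches its loop oracle to
    1e-6 relative tolerance."""
    rng = np.random.default_rng(42)
    cfg = LossConfig()
    for _ in range(120):
        n = int(rng.integers(1, 257))
        pred, truth = random_case(rng, n)
        assert dice_loss(pred, truth, cfg).item() == pytest.approx(
            oracle_dice(pred, truth, cfg.eps), rel=1e-6, abs=1e-9)
        assert focal_loss(pred, truth, cfg).item() == pytest.approx(
            oracle_focal(pred, truth, cfg.clamp_delta), rel=1e-6)
        assert segmentation_loss(pred, truth, cfg).item() == pytest.approx(
            oracle_dice(pred, truth, cfg.eps)
            + cfg.lambda_s * oracle_focal(pred, truth, cfg.clamp_delta), rel=1e-6)
        m = int(rng.integers(1, 33))
        bp, bt = random_case(rng, m)
        assert binary_ce(bp, bt, cfg).item() == pytest.approx(
            oracle_bce(bp, bt, cfg.clamp_delta), rel=1e-6)
        probs = rng.uniform(1e-4, 1.0, m)
        assert multiclass_ce(probs, cfg).item() == pytest.approx(
            oracle_mce(probs, cfg.clamp_delta), rel=1e-6)
        l_seg, l_c = rng.uniform(0, 5), rng.uniform(0, 5)
        lam = float(rng.uniform(0, 1))
        assert total_loss(l_seg, l_c, LossConfig(lambda_c=lam)).item() == \
            pytest.approx((1 - lam) * l_seg + lam * l_c, rel=1e-6)


# ------------------------------------------------------------------ properties
def test_dice_monotone_toward_truth():
    """Moving every prediction toward the ground truth never increases dice loss."""
    rng = np.random.default_rng(7)
    cfg = LossConfig()
    for _ in range(30):
        pred, truth = random_case(rng, 64)
        before = dice_loss(pred, truth, cfg).item()
        better = pred + 0.3 * (truth - pred)
        assert dice_loss(better, truth, cfg).item() <= before + 1e-9


@settings(max_examples=40, derandomize=True, deadline=None)
@given(pred=arrays(np.float64, st.integers(2, 64),
                   elements=st.floats(0, 1)),
       bits=st.integers(0, 2 ** 64 - 1))
def test_loss_bounds_hold_for_arbitrary_inputs(pred, bits):
    """Focal >= 0; dice in (-c, 1+c] whenever the truth contains both
    classes; segmentation loss finite for every contract-valid pairing."""
    truth = np.array([(bits >> (i % 64)) & 1 for i in range(pred.size)],
                     dtype=float)
    cfg = LossConfig()
    assert focal_loss(pred, truth, cfg).item() >= 0.0
    d = dice_loss(pred, truth, cfg).item()
    if 0 < truth.sum() < truth.size:  # mixed truth: two-sided dice band
        assert -1e-3 < d <= 1.0 + 1e-3
    else:  # degenerate single-class truth can legitimately reach -1/2
        assert -0.5 - 1e-3 < d <= 1.0 + 1e-3
    assert np.isfinite(segmentation_loss(pred, truth, cfg).item())


@settings(max_examples=40, derandomize=True, deadline=None)
@given(ls=st.floats(0, 10), lc=st.floats(0, 10),
       lam=st.floats(0, 1))
def test_total_loss_is_convex_combination(ls, lc, lam):
    v = total_loss(ls, lc, LossConfig(lambda_c=lam)).item()
    assert min(ls, lc) - 1e-9 <= v <= max(ls, lc) + 1e-9
    assert v == pytest.approx((1 - lam) * ls + lam * lc, rel=1e-9, abs=1e-12)


def test_losses_finite_for_extreme_inputs():
    cfg = LossConfig()
    pred = np.array([0.0, 1.0, 0.0, 1.0])
    truth = np.array([1.0, 0.0, 0.0, 1.0])
    for fn in (dice_loss, focal_loss, segmentation_loss):
        assert np.isfinite(fn(pred, truth, cfg).item())
    assert np.isfinite(binary_ce(pred, truth, cfg).item())
    assert np.isfinite(multiclass_ce([0.0, 1.0], cfg).item())


def test_dice_gradient_flows_to_predictions():
    from diunet.nn import Tensor
    p = Tensor(np.array([0.8, 0.2, 0.6, 0.4]), requires_grad=True)
    loss = segmentation_loss(p, np.array([1.0, 0, 1, 0]), LossConfig())
    loss.backward()
    assert p.grad is not None and np.any(p.grad != 0)


# -------------------------------------------------------------------- contracts
def test_classification_loss_dispatch():
    cfg = LossConfig(eps=1e-12)
    assert classification_loss("binary", ([0.5, 0.5], [1, 0]), cfg).item() == \
        pytest.approx(2 * math.log(2))
    assert classification_loss("multiclass", [0.125], cfg).item() == \
        pytest.approx(math.log(8))
    with pytest.raises(TypeError):
        classification_loss("binary", np.array([0.5, 0.5, 0.5]), cfg)
    with pytest.raises(TypeError):
        classification_loss("multiclass", ([0.5, 0.5], [1, 0]), cfg)
    with pytest.raises(ValueError):
        classification_loss("regression", [0.5], cfg)


def test_contract_violations():
    cfg = LossConfig()
    with pytest.raises(ValueError):
        dice_loss([0.5, 0.5], [1.0], cfg)          # length mismatch
    with pytest.raises(ValueError):
        dice_loss([], [], cfg)                      # empty batch
    with pytest.raises(ValueError):
        dice_loss([1.5], [1.0], cfg)                # prediction out of range
    with pytest.raises(ValueError):
        dice_loss([0.5], [0.5], cfg)                # non-binary truth
    with pytest.raises(ValueError):
        binary_ce([], [], cfg)
    with pytest.raises(ValueError):
        multiclass_ce([], cfg)


@pytest.mark.parametrize("kwargs", [
    {"eps": 0.0}, {"clamp_delta": 0.7}, {"lambda_c": 1.5},
    {"lambda_s": -1.0}, {"reduction": "max"},
])
def test_loss_config_validation(kwargs):
    with pytest.raises(ValueError):
        LossConfig(**kwargs)


def test_mean_reduction_rescales_sums():
    rng = np.random.default_rng(3)
    pred, truth = random_case(rng, 50)
    s = focal_loss(pred, truth, LossConfig(reduction="sum")).item()
    m = focal_loss(pred, truth, LossConfig(reduction="mean")).item()
    assert m == pytest.approx(s / 50, rel=1e-6)
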