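"""Fusion, update scoping and reproducibility of the joint trainer."""

from dataclasses import replace

import numpy as np
import pytest

from diunet.cls_network import BHCNetConfig, build_bhcnet
from diunet.joint_training import (
    JointTrainer,
    TrainConfig,
    fuse,
    predict_proba,
    train,
)
from diunet.losses import LossConfig
from diunet.nn import Tensor
from diunet.seg_network import DIUNetConfig, build_diunet
from diunet.synthetic_data import SyntheticSpec, make_cls_dataset, make_seg_dataset

SEG_CFG = DIUNetConfig(depth=3, base_channels=8)
CLS_CFG = BHCNetConfig.preset("tiny", 3)
SPEC = SyntheticSpec(seed=0, image_size=32, n_nuclei=(2, 5), radius=(3.0, 4.5))


def tiny_cfg(**kw):
    base = dict(total_steps=4, seg_batch_size=2, cls_batch_size=2,
                seg=SEG_CFG, cls=CLS_CFG, seed=0)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def seg_data():
    return make_seg_dataset(SPEC, 6)


@pytest.fixture(scope="module")
def cls_data():
    ds = make_cls_dataset(replace(SPEC, seed=1), 3)
    return list(zip(ds.images, ds.labels))


# ------------------------------------------------------------------- fusion
def test_fuse_identity_and_annihilator():
    img = np.random.default_rng(0).random((8, 8, 3)).astype(np.float32)
    assert np.allclose(fuse(img, np.ones((8, 8))).data[0].transpose(1, 2, 0), img)
    assert np.all(fuse(img, np.zeros((8, 8))).data == 0)


def test_fuse_scalar_product_and_bounds():
    img = np.full((4, 4, 3), 0.8, dtype=np.float32)
    nfm = np.full((4, 4), 0.5, dtype=np.float32)
    out = fuse(img, nfm).data
    assert out == pytest.approx(0.4)
    rng = np.random.default_rng(1)
    img = rng.random((4, 4, 3)).astype(np.float32)
    nfm = rng.random((4, 4)).astype(np.float32)
    assert np.all(fuse(img, nfm).data <= img.transpose(2, 0, 1)[None] + 1e-7)


def test_fuse_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        fuse(np.zeros((8, 8, 3)), np.zeros((4, 4)))


def test_fuse_routes_gradient_to_nfm():
    img = Tensor(np.random.default_rng(2).random((1, 3, 4, 4)).astype(np.float32))
    nfm = Tensor(np.full((1, 1, 4, 4), 0.5, dtype=np.float32), requires_grad=True)
    fuse(img, nfm).sum().backward()
    assert nfm.grad is not None and np.any(nfm.grad != 0)


# -------------------------------------------------------------- update scope
def test_seg_step_leaves_classifier_untouched(seg_data):
    seg = build_diunet(SEG_CFG, seed=0)
    cls = build_bhcnet(CLS_CFG, seed=1)
    before = {k: v.copy() for k, v in cls.state_dict().items()}
    trainer = JointTrainer(seg, cls, tiny_cfg())
    loss = trainer.seg_step(seg_data[:2])
    assert np.isfinite(loss)
    after = cls.state_dict()
    for k in before:
        assert np.array_equal(before[k], after[k]), k
    assert trainer.history.records[-1]["kind"] == "seg"


def test_cls_step_updates_both_networks(seg_data, cls_data):
    seg = build_diunet(SEG_CFG, seed=0)
    cls = build_bhcnet(CLS_CFG, seed=1)
    seg_before = {k: v.copy() for k, v in seg.state_dict().items()}
    trainer = JointTrainer(seg, cls, tiny_cfg())
    trainer.cls_step(cls_data[:2])
    changed = [k for k, v in seg.state_dict().items()
               if not np.array_equal(seg_before[k], v)]
    assert changed, "classification gradient did not reach the segmentation net"


def test_cls_step_gradient_reaches_seg_parameters(seg_data, cls_data):
    seg = build_diunet(SEG_CFG, seed=0)
    cls = build_bhcnet(CLS_CFG, seed=1)
    trainer = JointTrainer(seg, cls, tiny_cfg())
    trainer.cls_step(cls_data[:2])
    grads = [p.grad for p in seg.parameters()]
    assert any(g is not None and np.any(g != 0) for g in grads)


def test_separated_phase_freezes_segmentation(cls_data):
    seg = build_diunet(SEG_CFG, seed=0)
    cls = build_bhcnet(CLS_CFG, seed=1)
    before = {k: v.copy() for k, v in seg.state_dict().items()}
    trainer = JointTrainer(seg, cls, tiny_cfg(mode="separated"))
    trainer.cls_step(cls_data[:2], update_seg=False)
    for k, v in seg.state_dict().items():
        assert np.array_equal(before[k], v), k


def test_lambda_c_zero_blocks_classification_learning(cls_data):
    """With lambda_c = 0 the total loss carries no classification signal on
    classification batches, so neither network moves."""
    cfg = tiny_cfg(loss=LossConfig(lambda_c=0.0))
    seg = build_diunet(SEG_CFG, seed=0)
    cls = build_bhcnet(CLS_CFG, seed=1)
    before_seg = {k: v.copy() for k, v in seg.state_dict().items()}
    before_cls = {k: v.copy() for k, v in cls.state_dict().items()}
    trainer = JointTrainer(seg, cls, cfg)
    trainer.cls_step(cls_data[:2])
    for k, v in seg.state_dict().items():
        if not k.endswith(("running_mean", "running_var")):  # BN stats move
            assert np.array_equal(before_seg[k], v), k
    for k, v in cls.state_dict().items():
        if not k.endswith(("running_mean", "running_var")):
            assert np.array_equal(before_cls[k], v), k


def test_lambda_c_one_is_pure_classification_update(cls_data):
    a = tiny_cfg(loss=LossConfig(lambda_c=1.0))
    seg1 = build_diunet(SEG_CFG, seed=0)
    cls1 = build_bhcnet(CLS_CFG, seed=1)
    t1 = JointTrainer(seg1, cls1, a)
    l1 = t1.cls_step(cls_data[:2])
    rec = t1.history.records[-1]
    assert l1 == pytest.approx(rec["l_c"])  # L_total == L_c at lambda_c = 1


# ------------------------------------------------------------------ training
def test_interleave_ratio_schedules_equal_counts(seg_data, cls_data):
    cfg = tiny_cfg(total_steps=8, mode="joint")
    _, _, hist = train(seg_data, cls_data, cfg)
    assert len(hist.of_kind("seg")) == 4
    assert len(hist.of_kind("cls")) == 4


def test_training_reproducible_from_seed(seg_data, cls_data):
    cfg = tiny_cfg(total_steps=6)
    _, _, h1 = train(seg_data, cls_data, cfg)
    _, _, h2 = train(seg_data, cls_data, cfg)
    assert h1.records == h2.records


def test_separated_mode_phases(seg_data, cls_data):
    cfg = tiny_cfg(total_steps=6, mode="separated")
    _, _, hist = train(seg_data, cls_data, cfg)
    kinds = [r["kind"] for r in hist.records]
    assert kinds == ["seg"] * 3 + ["cls"] * 3


def test_empty_datasets_rejected(seg_data, cls_data):
    with pytest.raises(ValueError):
        train([], cls_data, tiny_cfg())
    with pytest.raises(ValueError):
        train(seg_data, [], tiny_cfg())


def test_predict_proba_shapes(seg_data, cls_data):
    seg, cls, _ = train(seg_data, cls_data, tiny_cfg(total_steps=2))
    probs = predict_proba(seg, cls, [im for im, _ in cls_data[:3]])
    assert probs.shape == (3, 2)
    assert probs.sum(axis=1) == pytest.approx(np.ones(3), abs=1e-5)


def test_train_config_validation():
    with pytest.raises(ValueError):
        tiny_cfg(total_steps=0)
    with pytest.raises(ValueError):
        tiny_cfg(mode="both")
    with pytest.raises(ValueError):
        tiny_cfg(interleave_ratio=(0, 1))
    with pytest.raises(ValueError):
        tiny_cfg(optimizer="sgd")
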