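"""Desk-scale experiment recipes.

Each function runs a complete, self-contained study on synthetic data with
tiny network presets, sized for minutes on a single CPU core:

* :func:`tiny_overfit_seg` — capacity sanity check: a tiny DIU-Net must
  near-perfectly segment a handful of images it trains on.
* :func:`tiny_overfit_cls` — the classifier alone must reach 100% training
  accuracy on a small two-class morphology set.
* :func:`c3s_generalization` — the complementary-color conversion study:
  train on nucleus-darker images only, test on nucleus-lighter images,
  with and without the conversion scheme.
* :func:`joint_vs_separated` — joint training against the separated-training
  control on a two-class morphology task.

All randomness derives from the ``base_seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Sequence

import numpy as np

from .augmentation import C3SPolicy, apply_c3s
from .cls_network import BHCNetConfig, build_bhcnet
from .evaluation import accuracy, mean_dice
from .joint_training import JointTrainer, TrainConfig, predict_proba, train
from .losses import LossConfig, binary_ce
from .nn import Adam, Tensor
from .seg_network import DIUNetConfig, build_diunet, segment
from .synthetic_data import SyntheticSpec, make_cls_dataset, make_seg_dataset, \
    make_polarity_split

TINY_SEG = DIUNetConfig(depth=3, base_channels=8)
TINY_CLS = BHCNetConfig(variant=3, base_channels=8, se_reduction=4)

#: 32 px classification/C3S images use radii scaled to the smaller canvas
SMALL_SPEC = dict(image_size=32, n_nuclei=(2, 5), radius=(3.0, 4.5))


def _spec_for(seed: int, image_size: int) -> SyntheticSpec:
    """Default spec for a canvas, with radii scaled down on small canvases."""
    if image_size < 48:
        small = dict(SMALL_SPEC, image_size=image_size)
        return SyntheticSpec(seed=seed, **small)
    return SyntheticSpec(seed=seed, image_size=image_size)


def _seg_loop(model, data, steps: int, seed: int, policy=None,
              batch_size: int = 4, lr: float = 3e-3) -> None:
    cfg = TrainConfig(total_steps=steps, seed=seed, lr=lr, c3s=policy,
                      seg=TINY_SEG, cls=TINY_CLS)
    trainer = JointTrainer(model, build_bhcnet(TINY_CLS, seed=seed + 1), cfg)
    rng = np.random.default_rng(seed)
    c3s_rng = np.random.default_rng(seed + 7)
    for _ in range(steps):
        idx = rng.choice(len(data), size=min(batch_size, len(data)), replace=False)
        batch = [data[i] for i in idx]
        if policy is not None:
            batch = apply_c3s(batch, policy, rng=c3s_rng)
        trainer.seg_step(batch)


def tiny_overfit_seg(base_seed: int = 0, n_images: int = 8, steps: int = 300,
                     image_size: int = 64, threshold: float = 0.5) -> Dict:
    """Overfit a tiny DIU-Net on a few images; report the training dice."""
    data = make_seg_dataset(_spec_for(base_seed, image_size), n_images)
    model = build_diunet(TINY_SEG, seed=base_seed)
    _seg_loop(model, data, steps, base_seed)
    nfms = [segment(model, im) for im, _ in data]
    dice = mean_dice(nfms, [m for _, m in data], threshold)
    return {"train_dice": dice, "n_images": n_images, "steps": steps}


def tiny_overfit_cls(base_seed: int = 0, n_per_class: int = 8,
                     max_steps: int = 300) -> Dict:
    """Train a tiny BHCNet-3 alone on a two-class morphology set until it
    reaches 100% training accuracy (or the step budget runs out)."""
    ds = make_cls_dataset(SyntheticSpec(seed=base_seed, **SMALL_SPEC), n_per_class)
    model = build_bhcnet(TINY_CLS, seed=base_seed)
    opt = Adam(model.parameters(), lr=3e-3)
    images = np.stack(ds.images).transpose(0, 3, 1, 2)
    labels = np.asarray(ds.labels)
    rng = np.random.default_rng(base_seed)
    cfg = LossConfig()
    steps_used = max_steps
    for step in range(max_steps):
        idx = rng.choice(len(labels), size=8, replace=False)
        model.train()
        probs = model(Tensor(images[idx]))
        onehot = np.zeros(probs.shape, dtype=np.float32)
        onehot[np.arange(idx.size), np.ones(idx.size, dtype=int)] = 1.0
        loss = binary_ce((probs * onehot).sum(axis=1), labels[idx], cfg)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step % 10 == 9:
            model.eval()
            acc = accuracy(model(Tensor(images)).data, labels)
            if acc == 1.0:
                steps_used = step + 1
                break
    model.eval()
    final = accuracy(model(Tensor(images)).data, labels)
    return {"train_accuracy": final, "steps_used": steps_used,
            "n_images": int(labels.size)}


def c3s_generalization(base_seed: int = 0, seeds: int = 3, steps: int = 150,
                       n_train: int = 12, n_test: int = 8,
                       image_size: int = 64) -> Dict:
    """Cross-polarity generalization with and without color conversion.

    For each seed, a tiny DIU-Net trains on darker-type images only and is
    evaluated on lighter-type images; the run is repeated with the
    complementary-color policy enabled (fraction 0.5) and disabled.
    """
    with_c3s, without_c3s = [], []
    for k in range(seeds):
        seed = base_seed + k
        spec = _spec_for(seed, image_size)
        train_set, test_set = make_polarity_split(spec, n_train, n_test)
        for policy, sink in ((C3SPolicy(0.5, seed), with_c3s), (None, without_c3s)):
            model = build_diunet(TINY_SEG, seed=seed)
            _seg_loop(model, train_set, steps, seed, policy)
            nfms = [segment(model, im) for im, _ in test_set]
            sink.append(mean_dice(nfms, [m for _, m in test_set]))
    return {
        "dice_with_c3s": float(np.mean(with_c3s)),
        "dice_without_c3s": float(np.mean(without_c3s)),
        "per_seed_with": with_c3s,
        "per_seed_without": without_c3s,
        "steps": steps, "n_seeds": seeds,
    }


#: classification-corpus domain shift relative to the segmentation corpus:
#: weaker nucleus contrast and heavier texture noise, mirroring the two-corpus
#: setting (segmentation and classification data come from different sources)
CLS_DOMAIN_SHIFT = dict(nucleus_contrast=0.15, texture_noise_sd=0.10,
                        background_noise_sd=0.05)


def joint_vs_separated(base_seed: int = 0, seeds: int = 5, steps: int = 240,
                       n_per_class_train: int = 16, n_per_class_test: int = 16
                       ) -> Dict:
    """Joint training versus the separated-training control.

    Class identity is encoded in nucleus morphology.  The classification
    corpus is domain-shifted from the segmentation corpus (lower contrast,
    heavier texture noise), so a focus map trained on segmentation data
    alone is suboptimal on classification images — the condition the joint
    scheme exists to fix.  Both modes get the same step budget and data and
    are scored by test accuracy of the segment -> fuse -> classify pipeline.
    """
    joint, separated = [], []
    for k in range(seeds):
        seed = base_seed + k
        spec = SyntheticSpec(seed=seed, **SMALL_SPEC)
        seg_data = make_seg_dataset(spec, 12)
        cls_spec = replace(spec, **CLS_DOMAIN_SHIFT)
        tr = make_cls_dataset(replace(cls_spec, seed=seed + 100), n_per_class_train)
        te = make_cls_dataset(replace(cls_spec, seed=seed + 200), n_per_class_test)
        cls_data = list(zip(tr.images, tr.labels))
        for mode, sink in (("joint", joint), ("separated", separated)):
            cfg = TrainConfig(total_steps=steps, seed=seed, mode=mode,
                              seg=TINY_SEG, cls=TINY_CLS)
            seg_model, cls_model, _ = train(seg_data, cls_data, cfg)
            probs = predict_proba(seg_model, cls_model, te.images)
            sink.append(accuracy(probs, te.labels))
    return {
        "accuracy_joint": float(np.mean(joint)),
        "accuracy_separated": float(np.mean(separated)),
        "per_seed_joint": joint,
        "per_seed_separated": separated,
        "steps": steps, "n_seeds": seeds,
    }


def lambda_c_sweep(values: Sequence[float], base_seed: int = 0,
                   steps: int = 240, n_per_class_train: int = 16,
                   n_per_class_test: int = 12) -> Dict[float, float]:
    """Grid utility: joint-training test accuracy as a function of the
    classification-loss weight lambda_c (0.99 is the recommended default)."""
    out: Dict[float, float] = {}
    spec = SyntheticSpec(seed=base_seed, **SMALL_SPEC)
    seg_data = make_seg_dataset(spec, 12)
    tr = make_cls_dataset(replace(spec, seed=base_seed + 100), n_per_class_train)
    te = make_cls_dataset(replace(spec, seed=base_seed + 200), n_per_class_test)
    cls_data = list(zip(tr.images, tr.labels))
    for lam in values:
        cfg = TrainConfig(total_steps=steps, seed=base_seed, mode="joint",
                          loss=LossConfig(lambda_c=lam),
                          seg=TINY_SEG, cls=TINY_CLS)
        seg_model, cls_model, _ = train(seg_data, cls_data, cfg)
        out[float(lam)] = accuracy(predict_proba(seg_model, cls_model, te.images),
                                   te.labels)
    return out
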