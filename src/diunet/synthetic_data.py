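"""Synthetic nucleus-image generator.

Renders tissue-like patches — elliptical nuclei on a smooth background —
with ground-truth masks and class labels, emulating the statistical
structure the joint model relies on:

* two staining polarities: nuclei *darker* than the background (typical
  H&E appearance) or *lighter* (fluorescence-like), driving the
  complementary-color generalization experiments;
* a nucleus area fraction well below one half (default about 0.1-0.2), the
  class-imbalance regime that motivates the dice+focal segmentation loss;
* class-dependent nucleus morphology (mean radius, eccentricity, density),
  so image-level labels are recoverable from nucleus regions alone.

Nuclei are ellipses: simple closed-form masks, parameterized morphology.
Per-class radius bands are deliberately narrow so the class signal lives in
morphology rather than in sampling noise.  Overlap between nuclei is allowed
up to a per-nucleus cap; masks are unions (semantic, not instance, masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "ClassMorphology", "SyntheticSpec", "SUBTYPE_NAMES",
    "make_seg_sample", "make_seg_dataset", "make_cls_dataset",
    "make_polarity_split", "morphology_oracle", "subtype_spec", "ClsDataset",
]

#: The eight tumor subtypes: adenosis, fibroadenoma, phyllodes tumor,
#: tubular adenoma (benign); ductal, lobular, mucinous, papillary
#: carcinoma (malignant).
SUBTYPE_NAMES = ("A", "F", "PT", "TA", "DC", "LC", "MC", "PC")


@dataclass(frozen=True)
class ClassMorphology:
    """Offsets a class applies to the base nucleus morphology."""

    radius_scale: float = 1.0
    eccentricity: float = 0.4   # 0 = circle, ->1 = elongated
    density_scale: float = 1.0  # multiplies the nucleus count


def _default_binary() -> Dict[str, ClassMorphology]:
    # benign-like: small, round, sparse; malignant-like: large, elongated, dense
    return {
        "benign": ClassMorphology(radius_scale=0.75, eccentricity=0.25,
                                  density_scale=0.8),
        "malignant": ClassMorphology(radius_scale=1.35, eccentricity=0.65,
                                     density_scale=1.2),
    }


def _default_subtypes() -> Dict[str, ClassMorphology]:
    # factorial design: four well-separated radius levels x two eccentricity
    # levels, so mask morphology identifies every subtype
    scales = (0.55, 0.55, 0.85, 0.85, 1.15, 1.15, 1.45, 1.45)
    eccs = (0.15, 0.75, 0.15, 0.75, 0.15, 0.75, 0.15, 0.75)
    dens = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.8, 0.8)
    return {name: ClassMorphology(s, e, d)
            for name, s, e, d in zip(SUBTYPE_NAMES, scales, eccs, dens)}


@dataclass
class SyntheticSpec:
    """Generator parameters (lengths in pixels, intensities in [0, 1])."""

    image_size: int = 64
    n_nuclei: Tuple[int, int] = (4, 9)          # inclusive range per image
    radius: Tuple[float, float] = (4.0, 6.5)    # semi-major axis range
    polarity: str = "darker"
    nucleus_contrast: float = 0.35              # |nucleus - background| offset
    texture_noise_sd: float = 0.06              # intra-nucleus texture
    background_noise_sd: float = 0.03
    eccentricity: float = 0.4
    max_overlap: float = 0.3                    # new-nucleus overlap cap
    class_morphology: Dict[str, ClassMorphology] = field(default_factory=_default_binary)
    seed: int = 0

    def __post_init__(self):
        if self.polarity not in ("darker", "lighter"):
            raise ValueError("polarity must be 'darker' or 'lighter'")
        if self.radius[0] < 2:
            raise ValueError("nucleus radii must be >= 2 px")
        # mean nucleus area must stay clearly below half the image
        mean_r = 0.5 * (self.radius[0] + self.radius[1])
        mean_n = 0.5 * (self.n_nuclei[0] + self.n_nuclei[1])
        if mean_n * np.pi * mean_r ** 2 >= 0.5 * self.image_size ** 2:
            raise ValueError("expected nucleus area exceeds half the image; "
                             "reduce n_nuclei or radius")


def _render(spec: SyntheticSpec, rng: np.random.Generator,
            morph: Optional[ClassMorphology] = None
            ) -> Tuple[np.ndarray, np.ndarray]:
    size = spec.image_size
    morph = morph or ClassMorphology(eccentricity=spec.eccentricity)

    lo, hi = spec.radius
    mid, half = 0.5 * (lo + hi) * morph.radius_scale, 0.5  # narrow class band
    n_lo = max(1, int(round(spec.n_nuclei[0] * morph.density_scale)))
    n_hi = max(n_lo, int(round(spec.n_nuclei[1] * morph.density_scale)))
    n_target = int(rng.integers(n_lo, n_hi + 1))

    # smooth background around a mid-grey tissue tone
    base = 0.55 if spec.polarity == "darker" else 0.45
    bg = base + gaussian_filter(
        rng.normal(0.0, 1.0, (size, size)), sigma=8) * 0.6
    bg = np.clip(bg, base - 0.12, base + 0.12)

    mask = np.zeros((size, size), dtype=np.uint8)
    nuclei = np.zeros((size, size), dtype=bool)
    placed = 0
    attempts = 0
    while placed < n_target:
        attempts += 1
        if attempts > 60 * n_target:
            raise ValueError(
                f"infeasible packing: placed {placed}/{n_target} nuclei "
                f"in {attempts} attempts (image {size}px, radius ~{mid:.1f}px)")
        a = float(rng.uniform(max(2.0, mid - half), mid + half))
        b = a * float(np.sqrt(1.0 - morph.eccentricity ** 2))
        cy, cx = rng.uniform(a, size - a), rng.uniform(a, size - a)
        angle = float(rng.uniform(0, np.pi))
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(size, size), rotation=angle)
        if rr.size == 0:
            continue
        new = np.zeros_like(nuclei)
        new[rr, cc] = True
        overlap = (new & nuclei).sum() / new.sum()
        if overlap > spec.max_overlap:
            continue
        nuclei |= new
        placed += 1
    mask[nuclei] = 1

    sign = -1.0 if spec.polarity == "darker" else 1.0
    intensity = bg + sign * spec.nucleus_contrast * nuclei
    # nuclei carry stronger (chromatin-like) texture than the background
    intensity = intensity + rng.normal(0.0, spec.background_noise_sd, (size, size))
    intensity = intensity + rng.normal(0.0, spec.texture_noise_sd, (size, size)) * nuclei

    # slight channel tinting so images are genuinely RGB
    tint = np.array([1.03, 0.97, 1.0]) if spec.polarity == "darker" \
        else np.array([0.97, 1.0, 1.03])
    image = np.clip(intensity[:, :, None] * tint[None, None, :], 0.0, 1.0)
    return image.astype(np.float32), mask


def make_seg_sample(spec: SyntheticSpec,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair; bitwise reproducible from ``spec.seed``."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    return _render(spec, rng)


def make_seg_dataset(spec: SyntheticSpec, n: int
                     ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """A list of ``n`` independent (image, mask) pairs."""
    rng = np.random.default_rng(spec.seed)
    return [_render(spec, rng) for _ in range(n)]


@dataclass
class ClsDataset:
    """A balanced labelled image set; masks are kept for oracle/diagnostic
    use only (image-level training must not touch them)."""

    images: List[np.ndarray]
    labels: List[int]
    class_names: List[str]
    masks: List[np.ndarray]


def make_cls_dataset(spec: SyntheticSpec, n_per_class: int,
                     classes: Optional[Sequence[str]] = None) -> ClsDataset:
    """Generate exactly ``n_per_class`` images per class; the class label
    determines the nucleus morphology distribution, so labels are
    recoverable from nucleus regions alone."""
    names = list(classes) if classes is not None else list(spec.class_morphology)
    missing = [c for c in names if c not in spec.class_morphology]
    if missing:
        raise KeyError(f"no morphology defined for classes: {missing}")
    morphs = [spec.class_morphology[c] for c in names]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if morphs[i] == morphs[j]:
                import warnings
                warnings.warn(f"classes {names[i]!r} and {names[j]!r} share "
                              "identical morphology; they are unidentifiable")
    rng = np.random.default_rng(spec.seed)
    images, labels, masks = [], [], []
    for idx, name in enumerate(names):
        for _ in range(n_per_class):
            img, m = _render(spec, rng, spec.class_morphology[name])
            images.append(img)
            labels.append(idx)
            masks.append(m)
    order = rng.permutation(len(images))
    return ClsDataset([images[i] for i in order], [labels[i] for i in order],
                      names, [masks[i] for i in order])


def subtype_spec(**overrides) -> SyntheticSpec:
    """A spec preconfigured with the eight-subtype morphology set."""
    return SyntheticSpec(class_morphology=_default_subtypes(), **overrides)


def make_polarity_split(spec: SyntheticSpec, n_train: int, n_test: int
                        ) -> Tuple[List[Tuple[np.ndarray, np.ndarray]],
                                   List[Tuple[np.ndarray, np.ndarray]]]:
    """Darker-type training set and lighter-type test set differing *only*
    in polarity, for the complementary-color generalization experiment."""
    train_spec = replace(spec, polarity="darker")
    test_spec = replace(spec, polarity="lighter", seed=spec.seed + 10_000)
    return make_seg_dataset(train_spec, n_train), make_seg_dataset(test_spec, n_test)


def _morph_features(mask: np.ndarray) -> np.ndarray:
    """(median equivalent radius, component count, median eccentricity).

    Medians are robust to the occasional merged component in the union mask.
    """
    lab = cc_label(mask)
    props = regionprops(lab)
    if not props:
        return np.array([0.0, 0.0, 0.0])
    radii = [np.sqrt(p.area / np.pi) for p in props]
    eccs = [p.eccentricity for p in props]
    return np.array([float(np.median(radii)), float(len(props)),
                     float(np.median(eccs))])


def morphology_oracle(train_masks: Sequence[np.ndarray],
                      train_labels: Sequence[int],
                      test_masks: Sequence[np.ndarray]) -> np.ndarray:
    """Brute-force nearest-centroid classifier on mask morphology.

    Features are measured from the ground-truth masks only (mean equivalent
    nucleus radius, nucleus count, mean eccentricity), standardised, and
    each test mask is assigned the label of the nearest class centroid.
    Serves as the independent check that class labels are recoverable from
    nucleus morphology.
    """
    X = np.stack([_morph_features(m) for m in train_masks])
    y = np.asarray(train_labels)
    classes = np.unique(y)
    # scale by pooled within-class spread so stable features dominate
    sd = np.mean([X[y == k].std(axis=0) for k in classes], axis=0) + 1e-9
    Xs = X / sd
    centroids = np.stack([Xs[y == k].mean(axis=0) for k in classes])
    T = np.stack([_morph_features(m) for m in test_masks]) / sd
    d = ((T[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return classes[d.argmin(axis=1)]
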