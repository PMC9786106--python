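# Methods

This note records the model as implemented, the parameters that matter, the
design decisions taken where several reasonable choices existed, and what
the synthetic experiments do and do not demonstrate.

## Model

**Segmentation.** The DIU-Net is an attention U-Net in which every
encoder/decoder convolution stage is a Dilated Inception (DI) block. A DI
block runs four parallel branches — 1×1; 1×1 then 3×3; 1×1 then 5×5; and a
dilated 3×3 (rate ≥ 2) followed by 1×1 — and concatenates their outputs on
the channel axis. The dilated branch occupies the position of the pooling
branch in a classic Inception module; the block therefore contains no
pooling operator (the test suite audits this structurally), while 2×2
max-pooling *between* U-Net levels and 2×2 transposed-convolution upsampling
are retained. Additive attention gates sit on every skip connection: the
upsampled decoder feature and the encoder skip are projected by 1×1
convolutions, summed, passed through ReLU, 1×1 convolution and sigmoid, and
the resulting map rescales the skip feature. The head is a 1×1 convolution
with sigmoid, so the output — the Nucleus Focus Map — is a per-pixel weight
in [0, 1]. It is deliberately *not* thresholded before fusion: soft
weighting is the point.

**Classification.** The classifier is a stem convolution followed by three
channel groups (c, 2c, 4c) of small SE-ResNet blocks with max-pooling
between groups, global average pooling and a softmax head. A small
SE-ResNet block is conv-norm-ReLU → conv-norm, a squeeze-and-excitation path
(global pool → C/r → ReLU → C → sigmoid, r = 16 at full scale, 4 in the tiny
preset) scaling the channels, then the residual addition and ReLU. The
depth-3 variant places one block per group; depth-6 places two. The two
variants differ only in depth, which is also asserted by a parameter-count
test.

**Fusion and joint training.** The classifier consumes the product
NFM × image. Segmentation batches update only the segmentation network via
L_seg = L_dice + λ_s·L_focal. Classification batches run
segment → fuse → classify and update *both* networks via
L_total = (1−λ_c)·L_seg + λ_c·L_c. Classification images carry no masks, so
L_seg cannot be evaluated on them; the segmentation term of L_total is
therefore zero on those batches and the effective signal is λ_c·L_c,
reaching the segmentation network purely through the fusion product. The
`separated` control trains the segmentation network for the first half of
the step budget, then freezes it (eval mode, no updates) while the
classifier trains on its weighted images.

## Losses and numerical choices

- Dice loss is two-sided (foreground and background overlap terms). The
  stabiliser ϵ (default 1e−6) is added once per numerator/denominator,
  outside the pixel sums, acting purely as a divide-by-zero guard.
- Logarithms are natural throughout. Focal exponent is fixed at 2.
- All probabilities are clamped to [δ, 1] (δ = 1e−7; [δ, 1−δ] for binary
  cross-entropy) before any logarithm, so every loss is finite for every
  contract-valid input.
- Losses are batch **sums** (a `reduction="mean"` switch exists); λ_s = 1
  and λ_c = 0.99 are calibrated against the summed forms. λ_c = 0.99 looks
  extreme but merely balances one image-level cross-entropy against a loss
  summed over tens of thousands of pixels.
- Loss arithmetic runs in float64 when given float64 inputs (the oracle
  tests exploit this); network training runs in float32.
- The complementary-color transform computes 1−v in float64, where it is
  exact for float32 inputs, making the transform a bit-exact involution.
- Optimiser: Adam (β = 0.9/0.999, eps 1e−8). The default learning rate is
  3e−3, chosen for the tiny presets: with Adam the rate sets the per-step
  parameter displacement almost independently of loss scale, and the
  few-hundred-step desk budgets need steps of that size. Larger
  configurations should lower it.
- Max-pooling routes gradient to every tied maximum; argmax classification
  ties break to the lowest class index (documented decision rule).

## Synthetic data: what it emulates, and what not

The generator renders elliptical nuclei on a smooth, slightly tinted
background, with stronger pixel noise inside nuclei (a crude chromatin
texture) and additive background noise. It reproduces the three properties
the method depends on:

1. **Staining polarity** — `darker` (nuclei below background intensity,
   the common H&E appearance) or `lighter` (fluorescence-like), with
   `make_polarity_split` producing train/test sets that differ only in
   polarity.
2. **Class imbalance** — default nucleus area fraction ≈ 0.1–0.2, the
   regime that motivates dice+focal over plain cross-entropy.
3. **Morphology-encoded labels** — each class shifts the nucleus radius,
   eccentricity and density. Per-class radius bands are narrow (±0.5 px
   around the class mean) so the class signal dominates sampling noise.
   The binary default uses small/round/sparse versus large/elongated/dense;
   the eight subtypes use a factorial grid of four radius levels × two
   eccentricity levels. A brute-force nearest-centroid oracle on mask
   morphology (median equivalent radius, component count, median
   eccentricity, scaled by pooled within-class spread) verifies labels are
   recoverable — ≥95% by test contract, in practice ~100%.

It does **not** emulate real histology: no stain-deconvolution physics, no
tissue architecture (glands, stroma), no instance-level mask separation
(overlaps up to IoU 0.3 per nucleus are unioned), no imaging artefacts.
Passing the synthetic studies shows the *mechanisms* work — the losses
optimise, color conversion removes the polarity shortcut, classification
gradients shape the focus map — not that real-data accuracy is reproduced.

## Desk-scale experiment conditions

All studies use the tiny presets (DIU-Net depth 3, base 8 channels;
BHCNet-3, base 8, SE reduction 4) and derive every random stream from one
base seed.

- **Tiny-overfit** (capacity check): 8 images at 64×64, 300 steps, batch 4;
  the training dice at threshold 0.5 must reach ≥ 0.95. The classifier
  check trains BHCNet-3 alone on 16 two-class images at 32×32 until 100%
  training accuracy (≤300 steps).
- **C3S generalization**: per seed (3 seeds), 12 darker-type training
  images and 8 lighter-type test images at 64×64, 150 steps, conversion
  fraction 0.5 versus none. Reported: mean test dice per condition. The
  conversion-free model learns the brightness polarity and inverts its
  prediction on the opposite polarity, collapsing its test dice toward
  zero, while the converted model transfers.
- **Joint vs separated**: per seed (5 seeds), 12 segmentation images and
  16 training / 16 test images per class at 32×32 (radii 3–4.5 px scaled to
  the canvas), 240 total steps split evenly between step kinds in both
  modes so budgets are comparable. The classification corpus is
  domain-shifted from the segmentation corpus — nucleus contrast 0.15
  instead of 0.35 and texture noise 0.10 instead of 0.06 — reflecting the
  two-corpus setting this training scheme targets: segmentation masks and
  class labels come from different image sources. Without the shift a
  segmentation-only focus map is already optimal and the comparison only
  measures noise; with it, the frozen separated pipeline degrades while
  joint training adapts the focus map to the classification domain.
  Reported: mean test accuracy per mode; the joint mean must be at least
  the separated mean. The training-set size is chosen so the classifier
  cannot simply memorise its inputs (at half this size both modes reach
  100% training accuracy while test accuracy degrades).

32×32 canvases are used wherever the classifier is in the loop; they keep
each full study in the low minutes on one CPU core while leaving every
mechanism intact.

## Known limitations

- The NumPy backend is single-threaded apart from BLAS matmuls; the `paper`
  presets (64-channel depth-4 DIU-Net, 224×224 inputs) are defined and
  functional but not practical to train here.
- Exact branch widths of the DI block and the filter schedule of the
  classifier follow standard Inception/SE-ResNet conventions (equal quarter
  channel splits; halved bottlenecks) where the source architecture leaves
  them open; dilation rate defaults to 2.
- Group normalisation (one group) follows every convolution rather than
  batch normalisation. Batch norm's running statistics cannot represent the
  deliberately bimodal input distribution the color-conversion scheme
  creates (darker and complemented batches), which desynchronises training
  and inference in the joint pipeline at these batch sizes; per-sample
  group statistics are identical in both modes and batch-size independent.
  A BatchNorm2d layer remains available in the backend.
- The joint-vs-separated margin on the synthetic task is small: with a
  morphology signal this clean, the separated pipeline is already strong,
  so the study checks direction (joint ≥ separated), not the magnitude seen
  on real data.
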