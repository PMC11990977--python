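# Methods

## Model

The detector is a standard two-stage pipeline. A residual bottleneck
backbone (stages C2–C5 at strides 4/8/16/32) feeds a top-down FPN
(lateral 1×1 projections, nearest-neighbour upsampling additions, 3×3
smoothing, plus a stride-2 P6), a shared-head RPN over P2–P6, and
ROI-align box heads (7×7 aligned bilinear pooling, two hidden layers,
softmax classification over K+1 classes, per-class box deltas). Two
presets share this structure: `resnet50` (3/4/6/3 blocks, widths
256/512/1024/2048, 256 FPN channels) and `tiny` (one block per stage,
widths 16/32/64/128, 64 FPN channels) for CPU-scale work.

Attention is strictly additive:

- **GCT** blocks sit before the 1×1/3×3/1×1 convolutions of each
  bottleneck (`layer123`) or before the last two (`layer23`). Each block
  computes an L2 global embedding per channel scaled by a learnable
  `alpha`, an across-channel L2 normalization with a `sqrt(C)` factor
  (a constant embedding then normalizes to exactly 1), and a
  `1 + tanh(gamma * s_hat + beta)` gate. `alpha=1, gamma=beta=0` at
  init makes every block the identity, which gives the package its
  degrade-to-baseline guarantee and is asserted bit-exactly in tests.
- **CBAM** blocks sit at configurable stage outputs before the FPN
  laterals (default in the full configuration: all of C2–C5). The
  channel gate applies a shared two-layer MLP (reduction ratio r,
  default 16; 8 in the tiny preset) to global max- and average-pooled
  descriptors and passes the sum through a logistic sigmoid; the
  spatial gate convolves the channel-wise max and mean maps (7×7
  kernel) and applies a sigmoid. The channel gate runs first, the
  spatial gate second. The gate nonlinearity is the canonical sigmoid
  (with ReLU inside the MLP): a ReLU-only output gate would be
  unbounded, which contradicts its role as an adaptive weight in (0,1).

### EIoU regression loss

`L_EIoU = 1 − IoU + rho²(A,B)/c² + (w_A−w_B)²/w_C² + (h_A−h_B)²/h_C²`,
with `c², w_C, h_C` from the minimum enclosing rectangle and `rho²` the
squared center distance. The width/height denominators are squared —
the dimensionally consistent form of the loss; with first-power
denominators the penalty terms would carry units of pixels. Denominators
are clamped at 1e-9 for degenerate boxes. The loss is zero iff the boxes
coincide, bounded below by 1−IoU, and exactly invariant under joint
translation and scaling — all property-tested. It replaces smooth-L1 in
the ROI head only; the RPN keeps smooth-L1, which is the common way
IoU-family losses are integrated into two-stage detectors. Both modes
are normalized identically (sum over positive ROIs divided by the number
of sampled ROIs) so switching the loss does not rescale the objective.

### Learning-rate schedules

All policies share a linear warmup from `f·base_lr` (f = 0.001) over W
steps. After warmup: single-cycle cosine annealing to `eta_min`
(default 0), or milestone decay by factor g = 0.1 at steps (2T/3, 7T/8)
by default. The "plain" policy is the same step-decay form and, with
early milestones, reproduces the failure mode where the rate collapses
to ~0 long before training ends. Stepping is per iteration; epoch
granularity is obtained by passing epoch counts. Warmup endpoints and
the cosine closed form are asserted to 1e-12.

## Autodiff engine

No deep-learning framework is assumed: `gcdetect.nn` is a tape-based
reverse-mode autodiff over float64 numpy arrays with exactly the
operations the detector needs (im2col convolution, batch norm with
running statistics, max pooling, nearest upsampling, bilinear ROI-align,
softmax/BCE/smooth-L1 losses, broadcasting arithmetic). Every operation
is verified against central finite differences (worst relative error
under 1e-3, typically 1e-9). SGD implements momentum and L2 weight
decay. Parameter initialization is He-normal, keyed per layer on
(seed, layer path), so model variants share identical weights for every
layer they have in common — adding attention blocks does not perturb
the initialization of the rest of the network, which both strengthens
the identity-at-init guarantee and removes initialization noise from
attention-vs-baseline comparisons. Detection heads are re-initialized
with small-std normals (0.01 classification, 0.001 box regression), and
CBAM output layers start at zero so fresh gates are the constant 0.5
rather than a source of per-sample noise; GCT starts as the identity.

## Detection plumbing defaults

Anchor sizes (32, 64, 128, 256, 512) across P2–P6 ((16…256) in the tiny
preset), ratios (0.5, 1, 2); RPN: 0.7/0.3 positive/negative IoU
thresholds, best-anchor forcing per ground truth, 256-anchor samples at
50% positive fraction, NMS 0.7, top-300 proposals (400/100 tiny);
ROI heads: 0.5/0.5 thresholds, 512 samples (64 tiny), score threshold
0.05, per-class NMS 0.5, 100 detections per image. ROI features pool
from the pyramid level given by the canonical `floor(4 + log2(sqrt(area)
/224))` rule. Boxes are corner-format, 0-based, half-open; the VOC
reader/writer shift 1-based inclusive file coordinates by −1/+1 at the
boundary and nowhere else.

Two small deviations from the long-schedule recipe are deliberate,
because desk-scale runs take a few hundred SGD steps rather than ~100k:
the tiny preset samples ROIs at a 50% positive fraction and appends
three lightly jittered copies of each ground-truth box to the ROI
sampler's pool (box-relative Gaussian jitter, sd 8%). Both enrich the
positive-classification signal that is otherwise drowned out by
background ROIs in short runs; neither changes the model or losses.

## Synthetic scenes

The generator emulates the statistical structure of multi-category pest
datasets with procedurally drawn targets: an elliptical body (rotated,
axis ratio per class) with spot or stripe markings, a brighter head cap
and leg segments, on a smoothed random-field background in earth tones
with pixel noise. The controllable difficulty axes are

- **scale**: body size log-uniform on [s_min, s_max] (defaults 10–40 px
  on 128×128 images) with an `outlier_fraction` (default 5%) drawn
  beyond s_max — strong intra- and inter-class scale variation with
  outliers;
- **inter-class similarity**: K classes (default 25) are δ-perturbations
  of S shared base prototypes (default max(2, K/3)); δ = 0 makes
  family members identical, and prototype separation grows monotonically
  with δ (tested). Default δ = 0.5;
- **density**: 1–4 targets per image, placed with at most 50% mutual
  box overlap (heavily occluded layouts are rejected).

Dataset augmentation (`gcdetect augment`) materializes blurred, noised or
brightness-shifted copies next to the originals with duplicated
annotations; when no parameters are given they are drawn per image from
label-preserving ranges (blur sigma 0.5–2 px, noise sigma 2–10 of 255,
brightness 0.7–1.3).

Scenes are deterministic functions of (config, seed); images are PNG, so
datasets regenerate byte-identically. What the generator does *not*
model: photographic texture, lighting, host-plant context, occlusion by
foliage, class imbalance. Tests passing on these scenes show the
pipeline's machinery is correct and its effect directions hold on data
with the stated statistical structure — they say nothing about absolute
accuracy on real field imagery.

## Desk-scale evaluation protocol

The end-to-end checks train the tiny preset on 200 generated scenes
(5 classes, 128×128, 8:1:1 split) for 10 epochs at batch 4 — about 400
SGD steps, a deliberate scale-down of the reference regime (200 epochs
on ~18k images on GPU). At this scale the attention-enhanced
configuration (GCT layer123 + CBAM C2–C5 + EIoU) reliably halves its
training loss, clears mAP0.5 ≈ 0.5–0.6 on held-out scenes, and its
mAP0.5:0.95 is compared against the plain baseline averaged over three
seeds. Effect sizes at a few hundred steps are much smaller and noisier
than in long-schedule training, which is why the comparison is averaged
and allows 0.01 ties.

## Numerical choices and edge cases

- IoU of two zero-area boxes is 0, not NaN; NMS ties break toward the
  lower index; matching sorts by score with stable index tie-breaks, so
  `evaluate()` is invariant to detection input order.
- AP uses the COCO 101-point interpolation of the precision envelope;
  classes without ground truth are excluded from class means; AR caps
  detections at 100 per image across classes.
- The confusion matrix pairs each ground truth with its best-IoU
  unclaimed detection above IoU 0.5 and score 0.5 regardless of class;
  unmatched ground truths fall in the background column, unmatched
  detections in the background row.
- Grad-CAM: gradients of the summed target-class logits over the
  model's proposals, spatially averaged into channel weights, rectified,
  nearest-upsampled and max-normalized; a constant-output model yields a
  defined all-zero map.
- Decoded box log-scales are clamped to ±4 before exponentiation.
- Batch norm uses batch statistics in training and running averages
  (momentum 0.1) at inference; oracle tests freeze them for exactness.

## Known limitations

- Pure-numpy training is ~1–2 orders of magnitude slower than a GPU
  framework; the `resnet50` preset is provided for structural fidelity
  and parameter-count checks, not for training at scale.
- The "bidirectional" multi-scale fusion is implemented as the standard
  top-down FPN (the backbone itself is the bottom-up path); an extra
  PANet-style bottom-up pass is out of scope.
- ECA and SE channel-attention variants are not implemented; the
  attention interface (modules applied at stage outputs / inside
  bottlenecks) accepts such plug-ins.
- Images inside one training batch must share a size (synthetic data
  guarantees this); prediction accepts any size ≥ 32×32.
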