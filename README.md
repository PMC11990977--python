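# gcdetect

Two-stage object detection for agricultural pest imagery, built around a
hybrid channel/spatial attention design and an improved bounding-box
regression loss, with a deterministic synthetic scene generator so the
whole pipeline trains and evaluates on a single CPU.

## Who this is for

Researchers studying small-object, many-category detection problems —
insect pests being the motivating case: targets vary strongly in scale
(with outlier sizes), classes look alike, and images contain one to a
few targets on textured natural backgrounds. The package provides both a
library (`gcdetect.*` modules), a scikit-learn style estimator
(`GCFasterRCNN`), and a CLI (`gcdetect generate/train/predict/evaluate/
trace/augment`).

## The model

The detector is a Faster R-CNN: a residual bottleneck backbone with FPN
multi-scale fusion, a region proposal network over five pyramid levels,
and ROI-align heads for classification (softmax) and per-class box
regression. Three additions are the point of the package:

**Gated Channel Transformation (GCT)** — placed before the convolutions
of every bottleneck (`layer23` or `layer123` policies). For input
`x_c` per channel:

    s_c   = alpha_c * ( sum_{i,j} x_c[i,j]^2 + eps )^(1/2)     (embedding)
    s_hat = sqrt(C) * s_c / ( sum_c s_c^2 + eps )^(1/2)         (normalization)
    x_hat = x_c * ( 1 + tanh(gamma_c * s_hat_c + beta_c) )      (gating)

With `gamma = beta = 0` (the default init) every GCT block is exactly
the identity, so the attention variant degrades gracefully to the plain
baseline.

**CBAM** — at configurable stage outputs (C2..C5): channel attention
`M_c = sigmoid(MLP(maxpool x) + MLP(avgpool x))` followed by spatial
attention `M_s = sigmoid(conv_{k x k}([max_c x ; mean_c x]))`.

**EIoU box loss** — selectable against smooth-L1 in the ROI heads:

    L_EIoU = 1 - IoU + rho^2(A,B)/c^2 + (w_A - w_B)^2 / w_C^2
             + (h_A - h_B)^2 / h_C^2

where `c`, `w_C`, `h_C` describe the minimum enclosing rectangle of the
two boxes. Unlike 1−IoU it has informative gradients for disjoint
boxes and penalizes aspect mismatch directly.

Training uses SGD (momentum 0.9, weight decay 1e-4, lr 0.01, batch 8 by
default) with a linear-warmup learning-rate schedule: single-cycle
cosine annealing or milestone decay (`gcdetect.schedule`).

Evaluation follows the COCO protocol (101-point interpolated AP; mAP at
IoU 0.5, 0.75 and 0.50:0.05:0.95; mAR with a 100-detection cap), plus
confusion matrices and Grad-CAM activation heatmaps.

Everything runs on a small reverse-mode autodiff engine over numpy
(`gcdetect.nn`) — no deep-learning framework required; CPU-deterministic
by construction.

## Worked example

```python
import numpy as np
from gcdetect import GCFasterRCNN, SceneConfig
from gcdetect.synthetic_scenes import generate_annotated

scenes = generate_annotated(100, SceneConfig(num_classes=5,
                                             image_size=(96, 96), seed=7))
train, heldout = scenes[:80], scenes[80:]

est = GCFasterRCNN(num_classes=5, epochs=10, batch_size=2, random_state=5)
est.fit(train)
print(f"epoch-0 loss {est.loss_history_[0]['loss']:.2f} -> "
      f"final {est.loss_history_[-1]['loss']:.2f}")
print(f"held-out mAP@0.5 = {est.score(heldout):.3f}")
for rec in est.predict(heldout[:1])[0][:3]:
    b = rec.box
    print(f"  {est.classes_[rec.class_id - 1]} score={rec.score:.2f} "
          f"box=({b.x_min:.0f},{b.y_min:.0f},{b.x_max:.0f},{b.y_max:.0f})")
```

Output from this exact snippet (a few minutes on one CPU):

```
epoch-0 loss 1.29 -> final 0.59
held-out mAP@0.5 = 0.416
  pest04 score=0.50 box=(41,23,66,51)
  pest02 score=0.40 box=(36,35,54,69)
  pest00 score=0.39 box=(32,41,57,64)
```

The loss halves over ten short epochs and the detector localizes many
held-out targets (the top detection above overlaps the scene's single
ground-truth `pest04` box at (30, 26, 65, 69)); scores are softmax
posteriors over the 5 pest classes plus background. Longer runs on more
scenes — the regime `scripts/acceptance.py` uses — reach mAP@0.5 around
0.6 on this task. The same pipeline is available from the shell:

```bash
gcdetect generate --n 200 --out data/ --seed 7
gcdetect train --data data/ --out run/ --seed 1
gcdetect predict --checkpoint run/checkpoint.npz --images data/JPEGImages --out dets.json
gcdetect evaluate --gt data/ --dets dets.json --out metrics.json
```

## Scope notes

The synthetic scenes emulate the statistical structure of multi-category
pest datasets (scale variation with outliers, inter-class similarity via
shared prototypes, 1-N targets per image) — not their photographic
appearance. Desk-scale runs use the `tiny` backbone preset, which keeps
the stage/stride structure of the full ResNet-50 configuration at a
fraction of the width.
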