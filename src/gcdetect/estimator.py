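"""Scikit-learn style estimator wrapping the detection pipeline.

`GCFasterRCNN` exposes the detector as a fit/predict estimator so it
composes with sklearn model selection utilities: hyperparameters are
constructor arguments, `fit` trains on annotated images, fitted state
lives in trailing-underscore attributes, and `score` returns validation
mAP at IoU 0.5.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import detector as _det
from .evaluation import DetectionRecord, GroundTruthRecord, evaluate
from .schedule import ScheduleConfig
from .voc_io import AnnotatedImage

__all__ = ["GCFasterRCNN"]


class GCFasterRCNN(BaseEstimator):
    """Two-stage pest detector with hybrid GCT+CBAM attention and EIoU loss.

    Parameters mirror the underlying detector configuration; the default
    switches reproduce the full attention-enhanced variant.  Pass
    ``gct_placement="none"``, ``cbam_locations=()`` and
    ``regression_loss="smooth_l1"`` for the plain baseline.

    Parameters
    ----------
    num_classes : foreground class count (background is implicit).
    preset : backbone size, "tiny" (desk-scale) or "resnet50".
    gct_placement : "none" | "layer23" | "layer123" GCT insertion policy.
    cbam_locations : backbone stages (C2..C5) receiving CBAM blocks.
    regression_loss : "smooth_l1" | "eiou" ROI-head box loss.
    schedule_policy : "plain" | "multistep_warmup" | "cosine_warmup".
    epochs, base_lr, batch_size, momentum, weight_decay : SGD settings.
    random_state : seed for weight init, sampling, and data order.

    Attributes
    ----------
    model_ : the trained FasterRCNN module.
    config_ : resolved DetectorConfig.
    classes_ : class-name list, index i maps to class id i + 1.
    loss_history_ : per-epoch training-loss log.
    """

    def __init__(self, num_classes: int = 5, preset: str = "tiny",
                 gct_placement: str = "layer123",
                 cbam_locations: tuple = ("C2", "C3", "C4", "C5"),
                 regression_loss: str = "eiou",
                 schedule_policy: str = "cosine_warmup",
                 epochs: int = 10, base_lr: float = 0.01, batch_size: int = 4,
                 momentum: float = 0.9, weight_decay: float = 1e-4,
                 random_state: int = 0):
        self.num_classes = num_classes
        self.preset = preset
        self.gct_placement = gct_placement
        self.cbam_locations = cbam_locations
        self.regression_loss = regression_loss
        self.schedule_policy = schedule_policy
        self.epochs = epochs
        self.base_lr = base_lr
        self.batch_size = batch_size
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.random_state = random_state

    def _make_config(self) -> _det.DetectorConfig:
        if self.preset == "tiny":
            cfg = _det.tiny_config(self.num_classes,
                                   gct_placement=self.gct_placement,
                                   cbam_locations=tuple(self.cbam_locations),
                                   regression_loss=self.regression_loss)
        else:
            from .backbone import BackboneConfig
            cfg = _det.DetectorConfig(
                num_classes=self.num_classes,
                backbone=BackboneConfig(preset=self.preset,
                                        gct_placement=self.gct_placement,
                                        cbam_locations=tuple(self.cbam_locations)),
                regression_loss=self.regression_loss)
        cfg.epochs = self.epochs
        cfg.base_lr = self.base_lr
        cfg.batch_size = self.batch_size
        cfg.momentum = self.momentum
        cfg.weight_decay = self.weight_decay
        return cfg

    def fit(self, X: list[AnnotatedImage], y=None) -> "GCFasterRCNN":
        """Train on annotated images (boxes and labels travel inside X)."""
        if not X:
            raise ValueError("empty training set")
        names = sorted({n for a in X for n, _ in a.objects})
        if len(names) > self.num_classes:
            raise ValueError(f"{len(names)} classes found, num_classes={self.num_classes}")
        # keep ids stable even when a class is absent from this sample
        from .synthetic_scenes import class_name
        canonical = [class_name(k) for k in range(self.num_classes)]
        self.classes_ = canonical if set(names) <= set(canonical) else names
        cfg = self._make_config()
        steps = max(2, self.epochs * int(np.ceil(len(X) / cfg.batch_size)))
        schedule = ScheduleConfig(total_steps=steps, base_lr=self.base_lr,
                                  warmup_steps=max(1, min(steps // 10, 500)),
                                  policy=self.schedule_policy)
        self.model_, self.loss_history_ = _det.train(
            list(X), cfg, schedule, seed=self.random_state,
            class_names=self.classes_, epochs=self.epochs)
        self.config_ = cfg
        return self

    def predict(self, X) -> list[list[DetectionRecord]]:
        """Detections per image; X holds AnnotatedImage or pixel arrays."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        out = []
        for i, item in enumerate(X):
            pixels = item.pixels if isinstance(item, AnnotatedImage) else np.asarray(item)
            recs = _det.predict(self.model_, pixels)
            out.append([DetectionRecord(i, r.class_id, r.score, r.box) for r in recs])
        return out

    def score(self, X: list[AnnotatedImage], y=None) -> float:
        """Mean average precision at IoU 0.5 on annotated images."""
        dets, gts = [], []
        for i, (ann, recs) in enumerate(zip(X, self.predict(X))):
            dets.extend(recs)
            for n, b in ann.objects:
                gts.append(GroundTruthRecord(i, self.classes_.index(n) + 1, b))
        return evaluate(dets, gts).map50
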