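"""Two-stage detection pipeline: anchors, RPN, ROI heads, training loop.

The pipeline is a standard FPN Faster R-CNN: anchors tiled over five
pyramid levels, a shared RPN head predicting objectness and box deltas,
greedy NMS proposal filtering, ROI-align pooling of region features, and
a two-layer box head with softmax classification and per-class box
regression.  The attention switches (GCT placement, CBAM locations) and
the EIoU regression loss are strictly additive: with attention off and
smooth-L1 selected the model is a plain Faster R-CNN.

Hyperparameters the source experiments leave unstated (anchor shapes,
NMS thresholds, sampling sizes) default to the canonical Faster R-CNN +
FPN recipe and are all configurable.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .backbone import BackboneConfig, BackboneWithFPN
from .losses import eiou_loss_tensor, iou_matrix
from .nn import Module, Tensor
from .schedule import ScheduleConfig, ScheduleState

__all__ = [
    "AnchorConfig", "DetectorConfig", "Proposal", "FasterRCNN",
    "generate_anchors", "assign_targets", "nms",
    "encode_boxes", "decode_boxes", "clip_boxes",
    "build_detector", "predict", "train",
    "save_checkpoint", "load_checkpoint", "tiny_config",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

RPN_LEVELS = ("P2", "P3", "P4", "P5", "P6")
ROI_LEVELS = ("P2", "P3", "P4", "P5")


@dataclass
class AnchorConfig:
    """One anchor size set per pyramid level, shared aspect ratios."""

    sizes: tuple[float, ...] = (32, 64, 128, 256, 512)
    ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    strides: tuple[int, ...] = (4, 8, 16, 32, 64)

    def __post_init__(self):
        if len(self.sizes) != len(self.strides):
            raise ValueError("one anchor size per level required")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("aspect ratios must be positive")

    @property
    def per_cell(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class Proposal:
    box: np.ndarray      # (4,), clipped to image bounds
    objectness: float


@dataclass
class DetectorConfig:
    num_classes: int = 25                      # foreground classes
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    anchors: AnchorConfig = field(default_factory=AnchorConfig)
    # RPN
    rpn_pre_nms_topk: int = 1000
    rpn_post_nms_topk: int = 300
    rpn_nms_thresh: float = 0.7
    rpn_pos_thr: float = 0.7
    rpn_neg_thr: float = 0.3
    rpn_batch: int = 256
    rpn_pos_fraction: float = 0.5
    # ROI heads
    roi_pos_thr: float = 0.5
    roi_neg_thr: float = 0.5
    roi_batch: int = 512
    roi_pos_fraction: float = 0.25
    # extra jittered ground-truth copies appended to the ROI sampler's pool;
    # enriches positive examples when few proposals clear the IoU threshold
    roi_gt_jitter: int = 0
    roi_pool_size: int = 7
    roi_sample_ratio: int = 2
    roi_head_dim: int = 1024
    score_thresh: float = 0.05
    roi_nms_thresh: float = 0.5
    max_detections: int = 100
    regression_loss: str = "smooth_l1"         # or "eiou"
    # optimization defaults
    epochs: int = 200
    base_lr: float = 0.01
    batch_size: int = 8
    weight_decay: float = 1e-4
    momentum: float = 0.9

    def __post_init__(self):
        if self.regression_loss not in ("smooth_l1", "eiou"):
            raise ValueError(f"unknown regression loss {self.regression_loss!r}")
        for thr in (self.rpn_nms_thresh, self.rpn_pos_thr, self.rpn_neg_thr,
                    self.roi_pos_thr, self.roi_neg_thr, self.roi_nms_thresh,
                    self.score_thresh):
            if not 0 <= thr <= 1:
                raise ValueError("thresholds must lie in [0, 1]")


def tiny_config(num_classes: int = 5, *, gct_placement: str = "none",
                cbam_locations: tuple[str, ...] = (),
                regression_loss: str = "smooth_l1") -> DetectorConfig:
    """Desk-scale preset: tiny backbone, small heads, small anchor sizes."""
    return DetectorConfig(
        num_classes=num_classes,
        backbone=BackboneConfig(preset="tiny", gct_placement=gct_placement,
                                cbam_locations=cbam_locations),
        anchors=AnchorConfig(sizes=(16, 32, 64, 128, 256)),
        rpn_pre_nms_topk=400, rpn_post_nms_topk=100,
        rpn_batch=128, roi_batch=64, roi_head_dim=256, roi_sample_ratio=1,
        # short-run convergence aids: richer positive sampling matters far
        # more at a few hundred SGD steps than at the usual 100k-step scale
        roi_pos_fraction=0.5, roi_gt_jitter=3,
        regression_loss=regression_loss,
        epochs=10, batch_size=4,
    )


# ---------------------------------------------------------------------------
# box utilities
# ---------------------------------------------------------------------------

def generate_anchors(level_shapes: list[tuple[int, int]],
                     cfg: AnchorConfig) -> list[np.ndarray]:
    """Anchors per level, ordered (row, col, anchor) to match head outputs.

    Each level gets H*W*A boxes centered on its stride grid.
    """
    out = []
    for (h, w), size, stride in zip(level_shapes, cfg.sizes, cfg.strides):
        shapes = []
        for r in cfg.ratios:
            aw = size / np.sqrt(r)
            ah = size * np.sqrt(r)
            shapes.append((aw, ah))
        shapes = np.asarray(shapes)  # (A, 2)
        cy = (np.arange(h) + 0.5) * stride
        cx = (np.arange(w) + 0.5) * stride
        ctr = np.stack(np.meshgrid(cy, cx, indexing="ij"), axis=-1)  # (h, w, 2)
        boxes = np.empty((h, w, len(shapes), 4))
        boxes[..., 0] = ctr[..., 1:2] - shapes[None, None, :, 0] / 2
        boxes[..., 1] = ctr[..., 0:1] - shapes[None, None, :, 1] / 2
        boxes[..., 2] = ctr[..., 1:2] + shapes[None, None, :, 0] / 2
        boxes[..., 3] = ctr[..., 0:1] + shapes[None, None, :, 1] / 2
        out.append(boxes.reshape(-1, 4))
    return out


def assign_targets(boxes: np.ndarray, gt_boxes: np.ndarray,
                   pos_thr: float, neg_thr: float,
                   force_match: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Label boxes against ground truth by IoU.

    Returns (labels, matched_gt): labels 1 = positive, 0 = negative,
    -1 = ignored; matched_gt holds the argmax gt index (or -1).  With
    `force_match`, every gt claims its best-IoU box as positive even
    below `pos_thr`.
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    n = boxes.shape[0]
    if gt_boxes.shape[0] == 0:
        return np.zeros(n, dtype=np.int8), np.full(n, -1, dtype=np.int64)
    ious = iou_matrix(boxes, gt_boxes)
    best = ious.max(axis=1)
    matched = ious.argmax(axis=1)
    labels = np.full(n, -1, dtype=np.int8)
    labels[best < neg_thr] = 0
    labels[best >= pos_thr] = 1
    if force_match:
        per_gt_best = ious.max(axis=0)
        for g in range(gt_boxes.shape[0]):
            if per_gt_best[g] <= 0:
                continue
            claim = np.nonzero(ious[:, g] == per_gt_best[g])[0]
            labels[claim] = 1
            matched[claim] = g
    return labels, np.where(labels == 1, matched, -1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; ties break toward the lower index."""
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    ordered = boxes[order]
    ious = iou_matrix(ordered, ordered)
    keep = []
    suppressed = np.zeros(len(order), dtype=bool)
    for oi in range(len(order)):
        if suppressed[oi]:
            continue
        keep.append(order[oi])
        suppressed[oi + 1:] |= ious[oi, oi + 1:] > iou_threshold
    return np.asarray(keep, dtype=np.int64)


def encode_boxes(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Corner boxes -> (dx, dy, dw, dh) deltas relative to anchors."""
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 4)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    w = np.maximum(boxes[:, 2] - boxes[:, 0], 1e-6)
    h = np.maximum(boxes[:, 3] - boxes[:, 1], 1e-6)
    cx = boxes[:, 0] + 0.5 * (boxes[:, 2] - boxes[:, 0])
    cy = boxes[:, 1] + 0.5 * (boxes[:, 3] - boxes[:, 1])
    return np.stack([(cx - ax) / aw, (cy - ay) / ah,
                     np.log(w / aw), np.log(h / ah)], axis=1)


def decode_boxes(deltas: np.ndarray, anchors: np.ndarray,
                 max_log_scale: float = 4.0) -> np.ndarray:
    """Inverse of `encode_boxes`; log-scales clamped for stability."""
    deltas = np.asarray(deltas, dtype=float).reshape(-1, 4)
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 4)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    cx = ax + deltas[:, 0] * aw
    cy = ay + deltas[:, 1] * ah
    w = aw * np.exp(np.clip(deltas[:, 2], -max_log_scale, max_log_scale))
    h = ah * np.exp(np.clip(deltas[:, 3], -max_log_scale, max_log_scale))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _decode_boxes_tensor(deltas: Tensor, anchors: np.ndarray,
                         max_log_scale: float = 4.0) -> Tensor:
    """Differentiable decode for EIoU training; anchors are constants."""
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 4)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    dx, dy, dw, dh = deltas[:, 0], deltas[:, 1], deltas[:, 2], deltas[:, 3]
    cx = dx * aw + ax
    cy = dy * ah + ay
    w = dw.minimum(max_log_scale).maximum(-max_log_scale).exp() * aw
    h = dh.minimum(max_log_scale).maximum(-max_log_scale).exp() * ah
    n = anchors.shape[0]
    return nn.concat([(cx - 0.5 * w).reshape(n, 1), (cy - 0.5 * h).reshape(n, 1),
                      (cx + 0.5 * w).reshape(n, 1), (cy + 0.5 * h).reshape(n, 1)],
                     axis=1)


def clip_boxes(boxes: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    """Clip corner boxes to [0, W] x [0, H]."""
    w, h = image_size
    out = np.asarray(boxes, dtype=float).reshape(-1, 4).copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0, w)
    out[:, 1::2] = np.clip(out[:, 1::2], 0, h)
    return out


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class RPNHead(Module):
    """Shared 3x3 conv + parallel 1x1 objectness/delta heads, all levels."""

    def __init__(self, channels: int, anchors_per_cell: int):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 3, padding=1)
        self.objectness = nn.Conv2d(channels, anchors_per_cell, 1)
        self.deltas = nn.Conv2d(channels, 4 * anchors_per_cell, 1)

    def forward(self, feat: Tensor) -> tuple[Tensor, Tensor]:
        h = self.conv(feat).relu()
        return self.objectness(h), self.deltas(h)


class BoxHead(Module):
    """Two hidden layers over pooled ROI features, then class/box branches."""

    def __init__(self, in_dim: int, hidden: int, num_classes: int):
        super().__init__()
        self.in_dim = in_dim
        self.fc1 = nn.Linear(in_dim, hidden)
        self.fc2 = nn.Linear(hidden, hidden)
        self.cls_score = nn.Linear(hidden, num_classes + 1)
        self.bbox_pred = nn.Linear(hidden, 4 * num_classes)

    def forward(self, pooled: Tensor) -> tuple[Tensor, Tensor]:
        n = pooled.shape[0]
        h = pooled.reshape(n, self.in_dim)
        h = self.fc1(h).relu()
        h = self.fc2(h).relu()
        return self.cls_score(h), self.bbox_pred(h)


class FasterRCNN(Module):
    """Configurable GC-Faster-RCNN: backbone+FPN, RPN, ROI heads."""

    def __init__(self, cfg: DetectorConfig):
        super().__init__()
        self.cfg = cfg
        self.backbone = BackboneWithFPN(cfg.backbone)
        ch = cfg.backbone.fpn_channels
        self.rpn_head = RPNHead(ch, cfg.anchors.per_cell)
        in_dim = ch * cfg.roi_pool_size ** 2
        self.box_head = BoxHead(in_dim, cfg.roi_head_dim, cfg.num_classes)
        self._rng = np.random.default_rng(0)

    def set_rng(self, rng: np.random.Generator) -> None:
        """Sampling rng for anchor/ROI subsampling during training."""
        self._rng = rng

    # -- RPN ---------------------------------------------------------------
    def _rpn(self, pyramid: dict[str, Tensor], image_size: tuple[int, int],
             targets: list[dict] | None):
        cfg = self.cfg
        levels = [pyramid[n] for n in RPN_LEVELS]
        shapes = [(f.shape[2], f.shape[3]) for f in levels]
        anchors = generate_anchors(shapes, cfg.anchors)
        n_img = levels[0].shape[0]
        obj_list, del_list = [], []
        for feat in levels:
            obj, dlt = self.rpn_head(feat)
            a = cfg.anchors.per_cell
            h, w = obj.shape[2], obj.shape[3]
            obj_list.append(obj.transpose(0, 2, 3, 1).reshape(n_img, h * w * a))
            del_list.append(dlt.reshape(n_img, a, 4, h, w)
                            .transpose(0, 3, 4, 1, 2).reshape(n_img, h * w * a, 4))
        proposals = []
        for i in range(n_img):
            boxes_all, scores_all = [], []
            for lvl, (obj, dlt, anc) in enumerate(zip(obj_list, del_list, anchors)):
                scores = obj.data[i]
                k = min(cfg.rpn_pre_nms_topk, scores.shape[0])
                top = np.argsort(-scores, kind="stable")[:k]
                boxes = decode_boxes(dlt.data[i][top], anc[top])
                boxes = clip_boxes(boxes, image_size)
                wh = boxes[:, 2:] - boxes[:, :2]
                valid = (wh > 1.0).all(axis=1)
                boxes, sc = boxes[valid], scores[top][valid]
                keep = nms(boxes, sc, cfg.rpn_nms_thresh)
                boxes_all.append(boxes[keep])
                scores_all.append(sc[keep])
            boxes_all = np.concatenate(boxes_all, axis=0)
            scores_all = np.concatenate(scores_all, axis=0)
            top = np.argsort(-scores_all, kind="stable")[:cfg.rpn_post_nms_topk]
            proposals.append(boxes_all[top])
        losses = {}
        if targets is not None:
            anchors_cat = np.concatenate(anchors, axis=0)
            obj_cat = nn.concat(obj_list, axis=1)
            del_cat = nn.concat(del_list, axis=1)
            obj_losses, box_losses = [], []
            for i in range(n_img):
                gt = targets[i]["boxes"]
                labels, matched = assign_targets(anchors_cat, gt,
                                                 cfg.rpn_pos_thr, cfg.rpn_neg_thr)
                pos = np.nonzero(labels == 1)[0]
                neg = np.nonzero(labels == 0)[0]
                n_pos = min(len(pos), int(cfg.rpn_batch * cfg.rpn_pos_fraction))
                n_neg = min(len(neg), cfg.rpn_batch - n_pos)
                if n_pos < len(pos):
                    pos = self._rng.choice(pos, n_pos, replace=False)
                if n_neg < len(neg):
                    neg = self._rng.choice(neg, n_neg, replace=False)
                sampled = np.concatenate([pos, neg])
                lab = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
                obj_losses.append(nn.binary_cross_entropy_with_logits(
                    obj_cat[i][sampled], lab))
                if len(pos):
                    tgt = encode_boxes(gt[matched[pos]], anchors_cat[pos])
                    diff = del_cat[i][pos] - tgt
                    box_losses.append(nn.smooth_l1(diff, 1.0 / 9.0).sum()
                                      * (1.0 / max(len(sampled), 1)))
            losses["rpn_objectness"] = _mean_losses(obj_losses)
            losses["rpn_box"] = _mean_losses(box_losses)
        return proposals, losses

    # -- ROI heads ---------------------------------------------------------
    def _pool_rois(self, pyramid: dict[str, Tensor], image_index: int,
                   rois: np.ndarray) -> Tensor:
        """ROI-align each box on its pyramid level, concatenated in order."""
        cfg = self.cfg
        if rois.shape[0] == 0:
            ch = cfg.backbone.fpn_channels
            return Tensor(np.zeros((0, ch, cfg.roi_pool_size, cfg.roi_pool_size)))
        areas = np.maximum((rois[:, 2] - rois[:, 0]) * (rois[:, 3] - rois[:, 1]), 1e-6)
        lvl = np.floor(4 + np.log2(np.sqrt(areas) / 224 + 1e-9)).astype(int)
        lvl = np.clip(lvl, 2, 5)
        pooled_parts: list[tuple[np.ndarray, Tensor]] = []
        for level in (2, 3, 4, 5):
            sel = np.nonzero(lvl == level)[0]
            if len(sel) == 0:
                continue
            feat = pyramid[f"P{level}"][image_index]
            pooled = nn.roi_align(feat, rois[sel], cfg.roi_pool_size,
                                  spatial_scale=1.0 / (2 ** level),
                                  sampling_ratio=cfg.roi_sample_ratio)
            pooled_parts.append((sel, pooled))
        order = np.concatenate([sel for sel, _ in pooled_parts])
        stacked = nn.concat([p for _, p in pooled_parts], axis=0)
        # restore original roi order
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        return stacked[inv]

    def _roi_heads(self, pyramid: dict[str, Tensor], proposals: list[np.ndarray],
                   image_size: tuple[int, int], targets: list[dict] | None):
        cfg = self.cfg
        n_img = len(proposals)
        if targets is not None:
            cls_losses, box_losses = [], []
            for i in range(n_img):
                gt_boxes = targets[i]["boxes"].reshape(-1, 4)
                gt_labels = targets[i]["labels"]
                extra = [proposals[i], gt_boxes]
                for _ in range(cfg.roi_gt_jitter):
                    if len(gt_boxes):
                        wh = np.tile(gt_boxes[:, 2:] - gt_boxes[:, :2], 2)
                        extra.append(gt_boxes + self._rng.normal(
                            0, 0.08, gt_boxes.shape) * wh)
                rois = np.concatenate(extra, axis=0)
                labels, matched = assign_targets(rois, gt_boxes, cfg.roi_pos_thr,
                                                 cfg.roi_neg_thr, force_match=False)
                pos = np.nonzero(labels == 1)[0]
                neg = np.nonzero(labels != 1)[0]  # below pos_thr = background
                n_pos = min(len(pos), int(cfg.roi_batch * cfg.roi_pos_fraction))
                n_neg = min(len(neg), cfg.roi_batch - n_pos)
                if n_pos < len(pos):
                    pos = self._rng.choice(pos, n_pos, replace=False)
                if n_neg < len(neg):
                    neg = self._rng.choice(neg, n_neg, replace=False)
                sampled = np.concatenate([pos, neg])
                rois_s = rois[sampled]
                cls_targets = np.zeros(len(sampled), dtype=np.int64)
                cls_targets[:len(pos)] = gt_labels[matched[pos]]
                pooled = self._pool_rois(pyramid, i, rois_s)
                logits, deltas = self.box_head(pooled)
                cls_losses.append(nn.softmax_cross_entropy(logits, cls_targets))
                if len(pos):
                    rows = np.arange(len(pos))
                    cols = (cls_targets[:len(pos)] - 1)[:, None] * 4 + np.arange(4)
                    pd = deltas[rows[:, None], cols]
                    gt_for_pos = gt_boxes[matched[pos]]
                    # both modes share one normalization (sum over positives
                    # divided by the number of sampled ROIs) so switching the
                    # regression loss does not rescale the total objective
                    if cfg.regression_loss == "eiou":
                        boxes_t = _decode_boxes_tensor(pd, rois_s[:len(pos)])
                        box_losses.append(eiou_loss_tensor(boxes_t, gt_for_pos).sum()
                                          * (1.0 / max(len(sampled), 1)))
                    else:
                        tgt = encode_boxes(gt_for_pos, rois_s[:len(pos)])
                        box_losses.append(nn.smooth_l1(pd - tgt, 1.0).sum()
                                          * (1.0 / max(len(sampled), 1)))
            return None, {"roi_class": _mean_losses(cls_losses),
                          "roi_box": _mean_losses(box_losses)}
        detections = []
        for i in range(n_img):
            rois = proposals[i]
            if rois.shape[0] == 0:
                detections.append([])
                continue
            pooled = self._pool_rois(pyramid, i, rois)
            logits, deltas = self.box_head(pooled)
            probs = _softmax(logits.data)
            dets = []
            for k in range(1, cfg.num_classes + 1):
                sc = probs[:, k]
                sel = np.nonzero(sc > cfg.score_thresh)[0]
                if len(sel) == 0:
                    continue
                d = deltas.data[sel, 4 * (k - 1):4 * k]
                boxes = clip_boxes(decode_boxes(d, rois[sel]), image_size)
                wh = boxes[:, 2:] - boxes[:, :2]
                ok = (wh > 0.5).all(axis=1)
                boxes, sck = boxes[ok], sc[sel][ok]
                keep = nms(boxes, sck, cfg.roi_nms_thresh)
                for j in keep:
                    dets.append((float(sck[j]), k, boxes[j]))
            dets.sort(key=lambda t: -t[0])
            detections.append(dets[:cfg.max_detections])
        return detections, {}

    def forward(self, images: Tensor, targets: list[dict] | None = None):
        """Training mode (targets given): loss dict.  Inference: detections.

        Detections are per image: list of (score, class_id, box)."""
        image_size = (images.shape[3], images.shape[2])  # (W, H)
        pyramid = self.backbone(images)
        proposals, rpn_losses = self._rpn(pyramid, image_size, targets)
        if targets is not None:
            _, roi_losses = self._roi_heads(pyramid, proposals, image_size, targets)
            return {**rpn_losses, **roi_losses}
        detections, _ = self._roi_heads(pyramid, proposals, image_size, None)
        return detections


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _mean_losses(parts: list[Tensor]) -> Tensor:
    if not parts:
        return Tensor(0.0)
    total = parts[0]
    for p in parts[1:]:
        total = total + p
    return total * (1.0 / len(parts))


def build_detector(cfg: DetectorConfig, seed: int) -> FasterRCNN:
    """Construct and deterministically initialize a detector."""
    model = FasterRCNN(cfg)
    nn.initialize(model, seed)
    head_rng = np.random.default_rng([seed, 17])
    for conv in (model.rpn_head.objectness, model.rpn_head.deltas):
        conv.weight.data = head_rng.normal(0, 0.01, conv.weight.shape)
        conv.bias.data = np.zeros_like(conv.bias.data)
    model.box_head.cls_score.weight.data = head_rng.normal(
        0, 0.01, model.box_head.cls_score.weight.shape)
    model.box_head.cls_score.bias.data *= 0
    model.box_head.bbox_pred.weight.data = head_rng.normal(
        0, 0.001, model.box_head.bbox_pred.weight.shape)
    model.box_head.bbox_pred.bias.data *= 0
    return model


# ---------------------------------------------------------------------------
# data plumbing, prediction, training
# ---------------------------------------------------------------------------

def normalize_images(batch: np.ndarray) -> Tensor:
    """uint8 (N, H, W, 3) -> normalized float Tensor (N, 3, H, W)."""
    x = batch.astype(np.float64) / 255.0
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return Tensor(x.transpose(0, 3, 1, 2))


def targets_from_annotation(ann, class_names: list[str]) -> dict:
    """AnnotatedImage -> {boxes, labels} with labels in 1..K."""
    index = {n: i + 1 for i, n in enumerate(class_names)}
    boxes = np.array([[b.x_min, b.y_min, b.x_max, b.y_max]
                      for _, b in ann.objects], dtype=float).reshape(-1, 4)
    labels = np.array([index[n] for n, _ in ann.objects], dtype=np.int64)
    return {"boxes": boxes, "labels": labels}


def predict(model: FasterRCNN, image: np.ndarray, class_names: list[str] | None = None):
    """Run one image through an eval-mode model.

    Returns DetectionRecord objects with boxes in image coordinates.
    """
    from .evaluation import DetectionRecord
    from .losses import Box
    model.eval()
    batch = normalize_images(image[None])
    dets = model(batch)[0]
    out = []
    for score, k, box in dets:
        out.append(DetectionRecord(image_id=0, class_id=int(k), score=float(score),
                                   box=Box(*np.asarray(box, dtype=float))))
    return out


def save_checkpoint(path: str | Path, model: FasterRCNN, optimizer: nn.SGD | None,
                    epoch: int, rng_state: dict | None = None) -> None:
    """Single-file .npz archive holding weights, optimizer, and config."""
    payload = {f"model/{k}": v for k, v in model.state_dict().items()}
    meta = {"epoch": epoch,
            "config": _config_to_dict(model.cfg),
            "rng_state": rng_state}
    payload["meta"] = np.array(json.dumps(meta))
    if optimizer is not None:
        for i, v in enumerate(optimizer.velocity):
            payload[f"opt/velocity/{i}"] = v
    np.savez(str(path), **payload)


def load_checkpoint(path: str | Path):
    """Returns (model, optimizer_velocity or None, epoch, rng_state)."""
    with np.load(str(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = _config_from_dict(meta["config"])
        model = FasterRCNN(cfg)
        state = {k[len("model/"):]: data[k] for k in data.files
                 if k.startswith("model/")}
        model.load_state_dict(state)
        vel_keys = sorted([k for k in data.files if k.startswith("opt/velocity/")],
                          key=lambda k: int(k.rsplit("/", 1)[1]))
        velocity = [data[k] for k in vel_keys] if vel_keys else None
    return model, velocity, meta["epoch"], meta.get("rng_state")


def _config_to_dict(cfg: DetectorConfig) -> dict:
    return dataclasses.asdict(cfg)


def _config_from_dict(d: dict) -> DetectorConfig:
    d = dict(d)
    d["backbone"] = BackboneConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                      for k, v in d["backbone"].items()})
    d["anchors"] = AnchorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in d["anchors"].items()})
    return DetectorConfig(**d)


def train(dataset: list, cfg: DetectorConfig, schedule_cfg: ScheduleConfig | None,
          seed: int, class_names: list[str], *, epochs: int | None = None,
          resume: str | Path | None = None, checkpoint_path: str | Path | None = None,
          log: list | None = None) -> tuple[FasterRCNN, list[dict]]:
    """SGD training loop over annotated images.

    `dataset` is a list of AnnotatedImage with pixels loaded; all images
    in a batch must share one size.  Reproducible: `seed` drives weight
    init, sampling, and data order.  Returns (model, per-epoch log).
    """
    if not dataset:
        raise ValueError("empty dataset")
    epochs = epochs if epochs is not None else cfg.epochs
    n = len(dataset)
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = max(epochs * steps_per_epoch, 2)
    if schedule_cfg is None:
        schedule_cfg = ScheduleConfig(
            total_steps=total_steps, base_lr=cfg.base_lr,
            warmup_steps=max(1, min(total_steps // 10, 500)))
    start_epoch = 0
    if resume is not None:
        model, velocity, start_epoch, rng_state = load_checkpoint(resume)
        rng = np.random.default_rng([seed, 29])
        if rng_state is not None:
            rng.bit_generator.state = rng_state
        optimizer = nn.SGD(model.parameters(), cfg.base_lr, cfg.momentum,
                           cfg.weight_decay)
        if velocity is not None:
            optimizer.velocity = [np.asarray(v) for v in velocity]
    else:
        model = build_detector(cfg, seed)
        rng = np.random.default_rng([seed, 29])
        optimizer = nn.SGD(model.parameters(), cfg.base_lr, cfg.momentum,
                           cfg.weight_decay)
    model.set_rng(rng)
    targets_all = [targets_from_annotation(a, class_names) for a in dataset]
    images_all = [a.pixels for a in dataset]
    history: list[dict] = log if log is not None else []
    state = ScheduleState(schedule_cfg, t=start_epoch * steps_per_epoch)
    model.train()
    for epoch in range(start_epoch, epochs):
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        parts_sum: dict[str, float] = {}
        t0 = time.time()
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            batch = normalize_images(np.stack([images_all[i] for i in idx]))
            targets = [targets_all[i] for i in idx]
            losses = model(batch, targets)
            total = _mean_losses(list(losses.values())) * float(len(losses))
            optimizer.zero_grad()
            total.backward()
            optimizer.lr = state.step()
            optimizer.step()
            epoch_losses.append(float(total.data))
            for k, v in losses.items():
                parts_sum[k] = parts_sum.get(k, 0.0) + float(v.data)
        entry = {"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                 "lr": optimizer.lr, "seconds": time.time() - t0}
        entry.update({k: v / steps_per_epoch for k, v in parts_sum.items()})
        history.append(entry)
        if checkpoint_path is not None:
            save_checkpoint(checkpoint_path, model, optimizer, epoch + 1,
                            rng_state=rng.bit_generator.state)
    return model, history
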