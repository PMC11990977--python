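"""COCO-protocol detection metrics, confusion matrices, and Grad-CAM maps.

Metrics follow the COCO evaluation convention: average precision is the
mean of the precision envelope sampled at 101 recall points
(0, 0.01, ..., 1.00), computed per class and IoU threshold; headline
numbers are mAP at IoU 0.5 and 0.75, mAP averaged over IoU 0.50:0.05:0.95,
and mean average recall (mAR) over the same threshold sweep with a
100-detections-per-image cap.  Classes without ground truth are excluded
from the class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import Box, iou_matrix

__all__ = [
    "DetectionRecord", "GroundTruthRecord", "EvalResult",
    "match_detections", "average_precision", "evaluate",
    "confusion_matrix", "activation_heatmap",
    "COCO_IOU_THRESHOLDS",
]

COCO_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
RECALL_POINTS = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class DetectionRecord:
    image_id: int
    class_id: int
    score: float
    box: Box


@dataclass(frozen=True)
class GroundTruthRecord:
    image_id: int
    class_id: int
    box: Box


@dataclass
class EvalResult:
    map50: float
    map75: float
    map5095: float
    mar5095: float
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    confusion: np.ndarray | None = None  # (K+1) x (K+1), see confusion_matrix

    def as_dict(self) -> dict:
        return {"map50": self.map50, "map75": self.map75,
                "map5095": self.map5095, "mar5095": self.mar5095,
                "per_class": {str(k): v for k, v in self.per_class.items()}}


def _boxes_array(records) -> np.ndarray:
    return np.array([[r.box.x_min, r.box.y_min, r.box.x_max, r.box.y_max]
                     for r in records], dtype=float).reshape(-1, 4)


def match_detections(dets: list[DetectionRecord], gts: list[GroundTruthRecord],
                     iou_thr: float) -> tuple[np.ndarray, int]:
    """Greedy score-ordered matching for one class on one image.

    Detections (descending score, ties by input order) each claim the
    highest-IoU unmatched ground truth with IoU >= `iou_thr`.  Returns
    (per-detection TP flags in input order, number of unmatched gts).
    """
    order = np.argsort([-d.score for d in dets], kind="stable")
    tp = np.zeros(len(dets), dtype=bool)
    if len(gts) == 0 or len(dets) == 0:
        return tp, len(gts)
    ious = iou_matrix(_boxes_array(dets), _boxes_array(gts))
    taken = np.zeros(len(gts), dtype=bool)
    for di in order:
        row = np.where(taken, -1.0, ious[di])
        gi = int(np.argmax(row))
        if row[gi] >= iou_thr and row[gi] >= 0:
            tp[di] = True
            taken[gi] = True
    return tp, int((~taken).sum())


def average_precision(tp_flags: np.ndarray, scores: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from per-detection TP flags.

    Returns NaN when n_gt == 0 (class excluded from the mean).
    """
    if n_gt == 0:
        return float("nan")
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    tp = np.asarray(tp_flags, dtype=bool)[order]
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(~tp)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # precision envelope: best precision at any recall >= r
    env = precision.copy()
    for i in range(len(env) - 2, -1, -1):
        env[i] = max(env[i], env[i + 1])
    ap = 0.0
    for r in RECALL_POINTS:
        idx = np.searchsorted(recall, r, side="left")
        ap += env[idx] if idx < len(env) else 0.0
    return float(ap / len(RECALL_POINTS))


def _cap_detections(dets: list[DetectionRecord], max_dets: int) -> list[DetectionRecord]:
    """Keep the top `max_dets` detections per image across classes."""
    by_image: dict[int, list[DetectionRecord]] = {}
    for d in dets:
        by_image.setdefault(d.image_id, []).append(d)
    kept: list[DetectionRecord] = []
    for recs in by_image.values():
        order = np.argsort([-r.score for r in recs], kind="stable")[:max_dets]
        kept.extend(recs[i] for i in sorted(order))
    return kept


def evaluate(dets: list[DetectionRecord], gts: list[GroundTruthRecord],
             iou_thresholds=COCO_IOU_THRESHOLDS, max_dets: int = 100) -> EvalResult:
    """COCO-protocol mAP/mAR over all (class, threshold) cells."""
    dets = _cap_detections(dets, max_dets)
    class_ids = sorted({g.class_id for g in gts} | {d.class_id for d in dets})
    image_ids = sorted({g.image_id for g in gts} | {d.image_id for d in dets})
    ap = {}   # (class, thr) -> AP
    ar = {}   # (class, thr) -> recall
    for k in class_ids:
        dets_k = [d for d in dets if d.class_id == k]
        gts_k = [g for g in gts if g.class_id == k]
        n_gt = len(gts_k)
        for thr in iou_thresholds:
            flags, scores = [], []
            matched_total = 0
            for img in image_ids:
                d_img = [d for d in dets_k if d.image_id == img]
                g_img = [g for g in gts_k if g.image_id == img]
                tp, unmatched = match_detections(d_img, g_img, thr)
                flags.extend(tp.tolist())
                scores.extend(d.score for d in d_img)
                matched_total += len(g_img) - unmatched
            ap[(k, thr)] = average_precision(np.array(flags, dtype=bool),
                                             np.array(scores), n_gt)
            ar[(k, thr)] = matched_total / n_gt if n_gt else float("nan")

    def mean_over(thrs) -> tuple[float, float]:
        aps = [ap[(k, t)] for k in class_ids for t in thrs
               if not np.isnan(ap[(k, t)])]
        ars = [ar[(k, t)] for k in class_ids for t in thrs
               if not np.isnan(ar[(k, t)])]
        return (float(np.mean(aps)) if aps else 0.0,
                float(np.mean(ars)) if ars else 0.0)

    map50, _ = mean_over([t for t in iou_thresholds if abs(t - 0.5) < 1e-9])
    map75, _ = mean_over([t for t in iou_thresholds if abs(t - 0.75) < 1e-9])
    map5095, mar5095 = mean_over(iou_thresholds)
    per_class = {}
    for k in class_ids:
        aps = [ap[(k, t)] for t in iou_thresholds if not np.isnan(ap[(k, t)])]
        ars = [ar[(k, t)] for t in iou_thresholds if not np.isnan(ar[(k, t)])]
        if aps:
            per_class[k] = {"ap5095": float(np.mean(aps)),
                            "ar5095": float(np.mean(ars))}
    return EvalResult(map50=map50, map75=map75, map5095=map5095,
                      mar5095=mar5095, per_class=per_class)


def confusion_matrix(dets: list[DetectionRecord], gts: list[GroundTruthRecord],
                     num_classes: int, iou_thr: float = 0.5,
                     score_thr: float = 0.5) -> np.ndarray:
    """(K+1) x (K+1) count matrix, class-agnostic best-IoU pairing.

    Rows are true classes, columns predictions; index K is background.
    Each ground truth pairs with its best-IoU unclaimed detection above
    both thresholds regardless of predicted class; unmatched gts count as
    (true, background) and unmatched detections as (background, pred).
    Class ids are 1-based; row/col ``k - 1`` holds class ``k``.
    """
    k_bg = num_classes
    mat = np.zeros((num_classes + 1, num_classes + 1), dtype=np.int64)
    image_ids = sorted({g.image_id for g in gts} | {d.image_id for d in dets})
    for img in image_ids:
        d_img = [d for d in dets if d.image_id == img and d.score >= score_thr]
        g_img = [g for g in gts if g.image_id == img]
        order = np.argsort([-d.score for d in d_img], kind="stable")
        taken_d = np.zeros(len(d_img), dtype=bool)
        if d_img and g_img:
            ious = iou_matrix(_boxes_array(g_img), _boxes_array(d_img))
        else:
            ious = np.zeros((len(g_img), len(d_img)))
        for gi, g in enumerate(g_img):
            best, best_di = 0.0, -1
            for di in order:
                if taken_d[di]:
                    continue
                if ious[gi, di] >= iou_thr and ious[gi, di] > best:
                    best, best_di = ious[gi, di], di
            if best_di >= 0:
                taken_d[best_di] = True
                mat[g.class_id - 1, d_img[best_di].class_id - 1] += 1
            else:
                mat[g.class_id - 1, k_bg] += 1
        for di, d in enumerate(d_img):
            if not taken_d[di]:
                mat[k_bg, d.class_id - 1] += 1
    return mat


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def activation_heatmap(model, image: np.ndarray, target_layer: str,
                       target_class: int) -> np.ndarray:
    """Gradient-weighted class activation map for one image.

    The target layer is a backbone stage name (C2..C5).  The class score
    backpropagated is the summed classification logit of `target_class`
    over the model's proposals.  Returns an (H, W) map normalized to
    [0, 1] (all-zero when the model carries no class evidence).
    """
    from .backbone import STAGE_NAMES
    from .detector import normalize_images
    if target_layer not in STAGE_NAMES:
        raise ValueError(f"unknown layer {target_layer!r}; one of {STAGE_NAMES}")
    model.eval()
    model.backbone.capture_layers = (target_layer,)
    try:
        images = normalize_images(image[None])
        image_size = (images.shape[3], images.shape[2])
        pyramid = model.backbone(images)
        act = model.backbone.captured[target_layer]
        proposals, _ = model._rpn(pyramid, image_size, None)
        rois = proposals[0]
        if rois.shape[0] == 0:
            return np.zeros(image.shape[:2])
        pooled = model._pool_rois(pyramid, 0, rois)
        logits, _ = model.box_head(pooled)
        score = logits[:, target_class].sum()
        score.backward()
    finally:
        model.backbone.capture_layers = ()
    if act.grad is None:
        return np.zeros(image.shape[:2])
    weights = act.grad[0].mean(axis=(1, 2))          # (C,)
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    h, w = image.shape[:2]
    ys = (np.arange(h) * cam.shape[0]) // h
    xs = (np.arange(w) * cam.shape[1]) // w
    cam = cam[ys][:, xs]
    peak = cam.max()
    if peak <= 0:
        return np.zeros_like(cam)
    return cam / peak
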