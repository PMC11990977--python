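"""Axis-aligned box geometry and bounding-box regression losses.

The regression loss used by the detection heads is selectable between the
classic smooth-L1 on encoded deltas and the EIoU loss

    L_EIoU = 1 - IoU + rho^2(A, B) / c^2
             + (w_A - w_B)^2 / w_C^2 + (h_A - h_B)^2 / h_C^2

where ``A``/``B`` are the box centers, ``c`` the diagonal of the minimum
enclosing rectangle and ``w_C``/``h_C`` its width and height.  Unlike a
pure IoU loss, the center-distance term gives a useful gradient even for
disjoint box pairs; the width/height terms penalize aspect mismatch
directly.  All three penalty terms are ratios, so the loss is invariant
under joint translation and scaling of both boxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, astensor, smooth_l1

__all__ = [
    "Box", "EnclosureGeometry",
    "iou", "iou_matrix", "enclosure", "eiou_loss", "eiou_loss_tensor",
    "box_regression_loss",
]

_EPS = 1e-9  # lower clamp for degenerate-box denominators


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in pixel coordinates, corner format."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(f"inverted box: {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def asarray(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max])

    @classmethod
    def from_array(cls, a) -> "Box":
        a = np.asarray(a, dtype=float)
        return cls(a[0], a[1], a[2], a[3])


@dataclass(frozen=True)
class EnclosureGeometry:
    """Geometry of the minimum rectangle enclosing two boxes."""

    c2: float            # squared diagonal of the enclosing rectangle
    wC: float            # its width
    hC: float            # its height
    rho2_centers: float  # squared Euclidean distance between box centers


def _as_box_array(b) -> np.ndarray:
    if isinstance(b, Box):
        return b.asarray()
    return np.asarray(b, dtype=float)


def iou(a, b) -> float:
    """Intersection-over-union of two boxes; 0 for degenerate pairs."""
    a, b = _as_box_array(a), _as_box_array(b)
    iw = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    ih = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = iw * ih
    union = ((a[2] - a[0]) * (a[3] - a[1])
             + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    if union <= 0.0:
        return 0.0
    return float(inter / union)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N, 4) and (M, 4) box arrays -> (N, M)."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    iw = np.clip(np.minimum(a[:, None, 2], b[None, :, 2])
                 - np.maximum(a[:, None, 0], b[None, :, 0]), 0, None)
    ih = np.clip(np.minimum(a[:, None, 3], b[None, :, 3])
                 - np.maximum(a[:, None, 1], b[None, :, 1]), 0, None)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    out = np.zeros_like(inter)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def enclosure(a, b) -> EnclosureGeometry:
    """Minimum enclosing rectangle of two boxes plus center distance."""
    a, b = _as_box_array(a), _as_box_array(b)
    wc = max(a[2], b[2]) - min(a[0], b[0])
    hc = max(a[3], b[3]) - min(a[1], b[1])
    ca = 0.5 * (a[:2] + a[2:])
    cb = 0.5 * (b[:2] + b[2:])
    rho2 = float(np.sum((ca - cb) ** 2))
    return EnclosureGeometry(c2=float(wc * wc + hc * hc), wC=float(wc),
                             hC=float(hc), rho2_centers=rho2)


def eiou_loss(pred, gt) -> float:
    """EIoU loss between one predicted and one ground-truth box."""
    p, g = _as_box_array(pred), _as_box_array(gt)
    geo = enclosure(p, g)
    wp, hp = p[2] - p[0], p[3] - p[1]
    wg, hg = g[2] - g[0], g[3] - g[1]
    loss = 1.0 - iou(p, g)
    loss += geo.rho2_centers / max(geo.c2, _EPS)
    loss += (wp - wg) ** 2 / max(geo.wC ** 2, _EPS)
    loss += (hp - hg) ** 2 / max(geo.hC ** 2, _EPS)
    return float(loss)


def eiou_loss_tensor(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Differentiable EIoU over (N, 4) predicted boxes vs. fixed targets.

    Returns a length-N loss tensor; gradients flow to ``pred`` only.
    """
    gt = np.asarray(gt, dtype=float).reshape(-1, 4)
    g = astensor(gt)
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    gx1, gy1, gx2, gy2 = g[:, 0], g[:, 1], g[:, 2], g[:, 3]
    iw = px2.minimum(gx2) - px1.maximum(gx1)
    ih = py2.minimum(gy2) - py1.maximum(gy1)
    inter = iw.clamp_min(0.0) * ih.clamp_min(0.0)
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = (area_p + area_g - inter).clamp_min(_EPS)
    iou_t = inter / union
    wc = px2.maximum(gx2) - px1.minimum(gx1)
    hc = py2.maximum(gy2) - py1.minimum(gy1)
    c2 = (wc * wc + hc * hc).clamp_min(_EPS)
    dx = 0.5 * ((px1 + px2) - (gx1 + gx2))
    dy = 0.5 * ((py1 + py2) - (gy1 + gy2))
    rho2 = dx * dx + dy * dy
    dw = (px2 - px1) - (gx2 - gx1)
    dh = (py2 - py1) - (gy2 - gy1)
    return (1.0 - iou_t + rho2 / c2
            + dw * dw / (wc * wc).clamp_min(_EPS)
            + dh * dh / (hc * hc).clamp_min(_EPS))


def box_regression_loss(pred_boxes, target_boxes, mode: str = "smooth_l1",
                        reduction: str = "mean", anchors=None,
                        beta: float = 1.0):
    """Aggregate regression loss over paired box lists.

    mode="smooth_l1": Huber loss on box parameterizations — on encoded
    deltas relative to ``anchors`` when given, else on raw corners.
    mode="eiou": EIoU on the (decoded) boxes themselves.
    Accepts numpy arrays (returns float) or Tensors (returns Tensor).
    """
    if mode not in ("smooth_l1", "eiou"):
        raise ValueError(f"unknown regression loss mode: {mode!r}")
    pred_t = _to_boxes_tensor(pred_boxes)
    tgt = _to_boxes_array(target_boxes)
    if pred_t.shape[0] != tgt.shape[0]:
        raise ValueError("pred/target length mismatch")
    if pred_t.shape[0] == 0:
        return Tensor(0.0) if isinstance(pred_boxes, Tensor) else 0.0
    if mode == "eiou":
        per = eiou_loss_tensor(pred_t, tgt)
    else:
        if anchors is not None:
            from .detector import encode_boxes  # local import avoids a cycle
            anchors = np.asarray(anchors, dtype=float).reshape(-1, 4)
            pe = _encode_tensor(pred_t, anchors)
            te = astensor(encode_boxes(tgt, anchors))
            per = smooth_l1(pe - te, beta).sum(axis=1)
        else:
            per = smooth_l1(pred_t - astensor(tgt), beta).sum(axis=1)
    out = per.mean() if reduction == "mean" else per.sum()
    return out if isinstance(pred_boxes, Tensor) else float(out.data)


def _to_boxes_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x.reshape(-1, 4)
    return astensor(_to_boxes_array(x))


def _to_boxes_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        x = x.data
    if isinstance(x, Box):
        return x.asarray().reshape(1, 4)
    x = list(x) if isinstance(x, (list, tuple)) else x
    if isinstance(x, list):
        if not x:
            return np.zeros((0, 4))
        return np.stack([_as_box_array(b) for b in x])
    return np.asarray(x, dtype=float).reshape(-1, 4)


def _encode_tensor(boxes: Tensor, anchors: np.ndarray) -> Tensor:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    w = (boxes[:, 2] - boxes[:, 0]).clamp_min(_EPS)
    h = (boxes[:, 3] - boxes[:, 1]).clamp_min(_EPS)
    cx = 0.5 * (boxes[:, 0] + boxes[:, 2])
    cy = 0.5 * (boxes[:, 1] + boxes[:, 3])
    dx = (cx - ax) / aw
    dy = (cy - ay) / ah
    dw = (w / aw).log()
    dh = (h / ah).log()
    n = boxes.shape[0]
    from . import nn
    return nn.concat([dx.reshape(n, 1), dy.reshape(n, 1),
                      dw.reshape(n, 1), dh.reshape(n, 1)], axis=1)
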