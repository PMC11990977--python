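"""Procedural generator of pest-like detection scenes.

Real multi-category pest datasets have three statistical properties that
make detection hard: strong inter- and intra-class scale variation with
occasional outlier sizes, high visual similarity between classes, and a
variable number of targets per image on cluttered natural backgrounds.
This module emulates exactly those axes with procedurally drawn targets
(an elliptical body with markings and leg-like appendages on a textured
background), so a detector can be trained and evaluated end to end with
no external data, and the difficulty axes stay parametric:

* target scale is log-uniform on ``[s_min, s_max]`` with an
  ``outlier_fraction`` of draws beyond ``s_max`` (scale outliers);
* the ``num_classes`` classes are perturbations of ``num_prototypes``
  shared base prototypes; the perturbation magnitude ``delta`` controls
  inter-class similarity (small delta = near-identical classes);
* targets per image are uniform on ``[min_targets, max_targets]`` and
  placed with at most 50% mutual box overlap.

Everything is a deterministic function of the configuration and seed;
images are written as PNG so regeneration is byte-exact.
"""

from __future__ import annotations

import colorsys
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .losses import Box, iou
from .voc_io import (AnnotatedImage, SplitManifest, save_split_manifest,
                     split_dataset, save_image, write_voc_xml)

__all__ = [
    "SceneConfig", "ClassPrototype", "GenerationError",
    "class_prototype", "prototype_distance", "generate_scene",
    "generate_annotated", "generate_dataset", "class_name",
]


class GenerationError(RuntimeError):
    """Raised when a scene cannot host the requested targets."""


@dataclass
class SceneConfig:
    """Study conditions for one synthetic dataset."""

    num_classes: int = 25
    num_prototypes: int | None = None   # default max(2, K // 3)
    delta: float = 0.5                  # inter-class perturbation magnitude
    image_size: tuple[int, int] = (128, 128)  # (W, H)
    min_targets: int = 1
    max_targets: int = 4
    s_min: float = 10.0
    s_max: float = 40.0
    outlier_fraction: float = 0.05
    outlier_max_scale: float | None = None
    background_noise: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.s_min < 8:
            raise ValueError("s_min must be >= 8 px")
        if not (0 <= self.outlier_fraction <= 0.2):
            raise ValueError("outlier_fraction must be in [0, 0.2]")
        if self.num_prototypes is None:
            self.num_prototypes = max(2, self.num_classes // 3)
        if self.num_prototypes >= self.num_classes:
            self.num_prototypes = max(1, self.num_classes - 1)
        if self.outlier_max_scale is None:
            self.outlier_max_scale = min(0.6 * min(self.image_size),
                                         2.5 * self.s_max)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ClassPrototype:
    """Appearance parameters of one pest class."""

    axis_ratio: float       # body ellipse major/minor
    hue: float              # in [0, 1)
    saturation: float
    value: float
    marking_kind: int       # 0 = spots, 1 = stripes
    marking_count: int
    marking_scale: float    # relative to body size
    appendage_count: int    # legs per side


def class_name(k: int) -> str:
    return f"pest{k:02d}"


def _base_prototype(b: int, seed: int) -> ClassPrototype:
    rng = np.random.default_rng([seed, 7919, b])
    return ClassPrototype(
        axis_ratio=float(rng.uniform(1.5, 3.0)),
        hue=float(rng.uniform(0.0, 1.0)),
        saturation=float(rng.uniform(0.55, 0.95)),
        value=float(rng.uniform(0.5, 0.9)),
        marking_kind=int(rng.integers(0, 2)),
        marking_count=int(rng.integers(2, 6)),
        marking_scale=float(rng.uniform(0.10, 0.22)),
        appendage_count=int(rng.choice([0, 2, 3])),
    )


def class_prototype(k: int, cfg: SceneConfig) -> ClassPrototype:
    """Prototype for class ``k``: a delta-perturbed copy of its base.

    Classes with the same ``k % num_prototypes`` share a base; with
    ``delta = 0`` all classes in a family are identical.
    """
    if not 0 <= k < cfg.num_classes:
        raise ValueError(f"class index {k} out of range")
    base = _base_prototype(k % cfg.num_prototypes, cfg.seed)
    rng = np.random.default_rng([cfg.seed, 104729, k])
    d = cfg.delta
    return ClassPrototype(
        axis_ratio=float(np.clip(base.axis_ratio * (1 + d * rng.uniform(-0.35, 0.35)),
                                 1.2, 4.0)),
        hue=float((base.hue + d * rng.uniform(-0.18, 0.18)) % 1.0),
        saturation=float(np.clip(base.saturation + d * rng.uniform(-0.2, 0.2), 0.3, 1.0)),
        value=float(np.clip(base.value + d * rng.uniform(-0.2, 0.2), 0.35, 1.0)),
        marking_kind=base.marking_kind if rng.random() > d * 0.5
        else int(rng.integers(0, 2)),
        marking_count=int(np.clip(base.marking_count + rng.integers(-1, 2) * (d > 0.25),
                                  1, 8)),
        marking_scale=float(np.clip(base.marking_scale * (1 + d * rng.uniform(-0.4, 0.4)),
                                    0.05, 0.3)),
        appendage_count=base.appendage_count,
    )


def prototype_distance(a: ClassPrototype, b: ClassPrototype) -> float:
    """Euclidean distance in a normalized appearance space (hue is circular)."""
    va = _embed(a)
    vb = _embed(b)
    return float(np.linalg.norm(va - vb))


def _embed(p: ClassPrototype) -> np.ndarray:
    return np.array([
        p.axis_ratio / 4.0,
        np.cos(2 * np.pi * p.hue), np.sin(2 * np.pi * p.hue),
        p.saturation, p.value,
        p.marking_kind, p.marking_count / 8.0, p.marking_scale,
        p.appendage_count / 3.0,
    ])


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _hsv(h: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb(h % 1.0, min(s, 1.0), min(v, 1.0))) * 255.0


def _render_target(size: float, proto: ClassPrototype, angle: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render one target on a local patch.

    Returns (mask bool (P, P), color float (P, P, 3)).
    """
    a = size / 2.0                     # semi-major axis
    b = max(a / proto.axis_ratio, 1.5)  # semi-minor axis
    leg_len = 0.45 * a
    ext = int(np.ceil(a + leg_len + 2))
    p = 2 * ext + 1
    yy, xx = np.mgrid[0:p, 0:p].astype(float)
    dx = xx - ext
    dy = yy - ext
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa              # along major axis
    v = -dx * sa + dy * ca
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = body.copy()
    color = np.zeros((p, p, 3))
    body_rgb = _hsv(proto.hue, proto.saturation, proto.value)
    color[body] = body_rgb
    # markings, darker than the body
    dark = _hsv(proto.hue, proto.saturation, proto.value * 0.35)
    if proto.marking_kind == 0:  # spots
        for _ in range(proto.marking_count):
            mu = rng.uniform(-0.7, 0.7) * a
            mv = rng.uniform(-0.6, 0.6) * b
            r = proto.marking_scale * a
            spot = ((u - mu) ** 2 + (v - mv) ** 2 <= r * r) & body
            color[spot] = dark
    else:  # stripes across the body
        freq = max(2, proto.marking_count)
        stripes = (np.sin(u / a * freq * np.pi) > 0.25) & body
        color[stripes] = dark
    # head: a brighter cap at one end of the major axis
    head = ((u - 0.8 * a) ** 2 + v ** 2 <= (0.35 * b) ** 2 + 1.0)
    color[head & body] = _hsv(proto.hue, proto.saturation * 0.8,
                              min(proto.value * 1.3, 1.0))
    # legs: thin segments from the body edge outwards
    dark_leg = dark * 0.8
    for side in (-1, 1):
        for i in range(proto.appendage_count):
            frac = -0.5 + (i + 0.5) / max(proto.appendage_count, 1)
            u0 = frac * a
            v0 = side * b * np.sqrt(max(1 - (u0 / a) ** 2, 0.0))
            phi = np.arctan2(side, 0.35 * np.sign(frac + 1e-9))
            u1 = u0 + leg_len * np.cos(phi) * 0.4
            v1 = v0 + side * leg_len * 0.9
            seg = _segment_mask(u, v, u0, v0, u1, v1, 0.8)
            mask |= seg
            color[seg & ~body] = dark_leg
    return mask, color


def _segment_mask(u, v, u0, v0, u1, v1, halfwidth) -> np.ndarray:
    du, dv = u1 - u0, v1 - v0
    l2 = du * du + dv * dv
    if l2 < 1e-9:
        return (u - u0) ** 2 + (v - v0) ** 2 <= halfwidth ** 2
    t = np.clip(((u - u0) * du + (v - v0) * dv) / l2, 0.0, 1.0)
    dist2 = (u - (u0 + t * du)) ** 2 + (v - (v0 + t * dv)) ** 2
    return dist2 <= halfwidth ** 2


def _background(w: int, h: int, noise_std: float,
                rng: np.random.Generator) -> np.ndarray:
    # two earth-tone anchor colours blended through a smoothed random field
    h0 = rng.uniform(0.18, 0.38)  # greens / browns
    c0 = _hsv(h0, rng.uniform(0.3, 0.6), rng.uniform(0.25, 0.45))
    c1 = _hsv(h0 + rng.uniform(-0.08, 0.08), rng.uniform(0.2, 0.5),
              rng.uniform(0.5, 0.75))
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    field -= field.min()
    field /= max(field.max(), 1e-9)
    img = c0[None, None, :] + field[:, :, None] * (c1 - c0)[None, None, :]
    img += rng.normal(0.0, noise_std, img.shape)
    return img


def _sample_scale(cfg: SceneConfig, rng: np.random.Generator) -> float:
    if rng.random() < cfg.outlier_fraction:
        lo, hi = np.log(cfg.s_max), np.log(cfg.outlier_max_scale)
    else:
        lo, hi = np.log(cfg.s_min), np.log(cfg.s_max)
    return float(np.exp(rng.uniform(lo, hi)))


def generate_scene(cfg: SceneConfig, rng: np.random.Generator,
                   filename: str = "scene.png") -> tuple[np.ndarray, AnnotatedImage]:
    """Generate one scene: textured background plus rendered targets.

    Returns (uint8 image (H, W, 3), annotation with one tight box per
    target).  Raises GenerationError when the image cannot host a target.
    """
    w, h = cfg.image_size
    img = _background(w, h, cfg.background_noise, rng)
    n_targets = int(rng.integers(cfg.min_targets, cfg.max_targets + 1))
    objects: list[tuple[str, Box]] = []
    boxes: list[np.ndarray] = []
    for _ in range(n_targets):
        placed = False
        for _attempt in range(60):
            size = _sample_scale(cfg, rng)
            k = int(rng.integers(0, cfg.num_classes))
            proto = class_prototype(k, cfg)
            angle = float(rng.uniform(0, np.pi))
            mask, color = _render_target(size, proto, angle, rng)
            p = mask.shape[0]
            if p >= min(w, h):
                if size <= cfg.s_min + 1e-6:
                    raise GenerationError(
                        f"image {w}x{h} too small for minimum target size")
                continue
            x0 = int(rng.integers(0, w - p))
            y0 = int(rng.integers(0, h - p))
            ys, xs = np.nonzero(mask)
            box = np.array([x0 + xs.min(), y0 + ys.min(),
                            x0 + xs.max() + 1, y0 + ys.max() + 1], dtype=float)
            if any(iou(box, other) > 0.5 for other in boxes):
                continue
            img[y0:y0 + p, x0:x0 + p][mask] = color[mask]
            boxes.append(box)
            objects.append((class_name(k), Box(*box)))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place target {len(objects) + 1}/{n_targets} "
                f"in a {w}x{h} image")
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    ann = AnnotatedImage(filename=filename, size=(w, h, 3),
                         objects=objects, pixels=pixels)
    return pixels, ann


def generate_annotated(n_images: int, cfg: SceneConfig) -> list[AnnotatedImage]:
    """Generate ``n_images`` scenes in memory, deterministically from cfg.seed."""
    out = []
    for i in range(n_images):
        rng = np.random.default_rng([cfg.seed, 65537, i])
        _, ann = generate_scene(cfg, rng, filename=f"scene_{i:05d}.png")
        out.append(ann)
    return out


def generate_dataset(n_images: int, cfg: SceneConfig,
                     out_dir: str | Path) -> SplitManifest:
    """Materialize a VOC-layout dataset directory tree.

    Layout: JPEGImages/*.png, Annotations/*.xml, ImageSets/Main/{split}.txt,
    manifest.json recording the full configuration for regeneration.
    """
    out_dir = Path(out_dir)
    (out_dir / "JPEGImages").mkdir(parents=True, exist_ok=True)
    (out_dir / "Annotations").mkdir(parents=True, exist_ok=True)
    names = []
    for ann in generate_annotated(n_images, cfg):
        stem = Path(ann.filename).stem
        names.append(stem)
        save_image(ann.pixels, out_dir / "JPEGImages" / ann.filename)
        write_voc_xml(ann, out_dir / "Annotations" / f"{stem}.xml")
    manifest = split_dataset(names, seed=cfg.seed)
    save_split_manifest(manifest, out_dir / "ImageSets" / "Main")
    (out_dir / "manifest.json").write_text(json.dumps(
        {"n_images": n_images, "config": cfg.to_dict()}, indent=2) + "\n")
    return manifest
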