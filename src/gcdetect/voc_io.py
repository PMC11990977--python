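"""Pascal VOC annotation I/O, dataset splitting, and pixel augmentations.

Coordinate convention: VOC XML stores 1-based pixel coordinates.  This
library works in 0-based coordinates throughout; the reader subtracts 1
from every bndbox coordinate and the writer adds it back, so a
read -> write -> read cycle is a fixed point.  A box's width/height is
``x_max - x_min`` / ``y_max - y_min`` in library coordinates.

The augmentation operators (Gaussian blur, additive noise, brightness)
act on pixels only — bounding boxes and labels pass through untouched,
which is what makes them safe label-preserving augmentations for
detection datasets.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .losses import Box

__all__ = [
    "AnnotatedImage", "SplitManifest", "VOCParseError",
    "read_voc_xml", "write_voc_xml", "split_dataset",
    "save_split_manifest", "load_split_manifest",
    "augment", "crop_to_targets", "load_image", "save_image",
]


class VOCParseError(ValueError):
    """Raised for malformed VOC XML; message names the offending file."""


@dataclass
class AnnotatedImage:
    """One image plus its object annotations.

    `pixels` may be None for annotation-only workflows; `size` is
    (width, height, depth) as in the VOC <size> element.
    """

    filename: str
    size: tuple[int, int, int]
    objects: list[tuple[str, Box]] = field(default_factory=list)
    pixels: np.ndarray | None = None  # (H, W, 3) uint8
    folder: str = "VOC"

    def validate(self, label_set: set[str] | None = None) -> None:
        w, h, _ = self.size
        for name, box in self.objects:
            if not (0 <= box.x_min <= box.x_max <= w
                    and 0 <= box.y_min <= box.y_max <= h):
                raise ValueError(f"box {box} outside image {w}x{h} in {self.filename}")
            if label_set is not None and name not in label_set:
                raise ValueError(f"unknown class {name!r} in {self.filename}")


@dataclass
class SplitManifest:
    train: list[str]
    val: list[str]
    test: list[str]
    seed: int
    ratios: tuple[float, float, float]

    def all_samples(self) -> list[str]:
        return self.train + self.val + self.test


def read_voc_xml(path: str | Path) -> AnnotatedImage:
    """Parse one VOC XML annotation into library (0-based) coordinates."""
    path = Path(path)
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise VOCParseError(f"{path}: malformed XML ({exc})") from exc
    filename = root.findtext("filename") or path.stem
    size_el = root.find("size")
    if size_el is None:
        raise VOCParseError(f"{path}: missing <size>")
    size = (int(size_el.findtext("width")), int(size_el.findtext("height")),
            int(size_el.findtext("depth") or 3))
    objects: list[tuple[str, Box]] = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if name is None or bnd is None:
            raise VOCParseError(f"{path}: object missing <name> or <bndbox>")
        try:
            coords = [float(bnd.findtext(k)) for k in ("xmin", "ymin", "xmax", "ymax")]
        except (TypeError, ValueError) as exc:
            raise VOCParseError(f"{path}: bad bndbox coordinates") from exc
        xmin, ymin, xmax, ymax = coords
        if xmax < xmin or ymax < ymin:
            raise VOCParseError(f"{path}: inverted bndbox {coords}")
        # 1-based VOC -> 0-based library coordinates
        objects.append((name, Box(xmin - 1, ymin - 1, xmax - 1, ymax - 1)))
    return AnnotatedImage(filename=filename, size=size, objects=objects,
                          folder=root.findtext("folder") or "VOC")


def write_voc_xml(ann: AnnotatedImage, path: str | Path) -> None:
    """Write VOC-dialect XML with integer, 1-based coordinates."""
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = ann.folder
    ET.SubElement(root, "filename").text = ann.filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.size[0])
    ET.SubElement(size, "height").text = str(ann.size[1])
    ET.SubElement(size, "depth").text = str(ann.size[2])
    for name, box in ann.objects:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = name
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        # 0-based library -> 1-based VOC
        ET.SubElement(bnd, "xmin").text = str(int(round(box.x_min)) + 1)
        ET.SubElement(bnd, "ymin").text = str(int(round(box.y_min)) + 1)
        ET.SubElement(bnd, "xmax").text = str(int(round(box.x_max)) + 1)
        ET.SubElement(bnd, "ymax").text = str(int(round(box.y_max)) + 1)
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="unicode")


def split_dataset(samples: list[str], ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> SplitManifest:
    """Deterministic shuffled train/val/test split (default 8:1:1).

    Sizes are floor(r_train * n), floor(r_val * n), remainder.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    samples = sorted(samples)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    shuffled = [samples[i] for i in order]
    n = len(samples)
    n_train = int(ratios[0] * n)
    n_val = int(ratios[1] * n)
    return SplitManifest(train=shuffled[:n_train],
                         val=shuffled[n_train:n_train + n_val],
                         test=shuffled[n_train + n_val:],
                         seed=seed, ratios=tuple(ratios))


def save_split_manifest(manifest: SplitManifest, directory: str | Path) -> None:
    """Write ImageSets/Main-style plain-text file lists."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for split in ("train", "val", "test"):
        (directory / f"{split}.txt").write_text(
            "".join(s + "\n" for s in getattr(manifest, split)))


def load_split_manifest(directory: str | Path, seed: int = 0,
                        ratios=(0.8, 0.1, 0.1)) -> SplitManifest:
    directory = Path(directory)
    parts = {}
    for split in ("train", "val", "test"):
        text = (directory / f"{split}.txt").read_text()
        parts[split] = [line for line in text.splitlines() if line]
    return SplitManifest(seed=seed, ratios=tuple(ratios), **parts)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUGMENT_OPS = ("gaussian_blur", "additive_noise", "brightness")


def augment(ann: AnnotatedImage, op: str, *, sigma: float | None = None,
            factor: float | None = None,
            rng: np.random.Generator | None = None) -> AnnotatedImage:
    """Apply one pixel-level augmentation; geometry is untouched.

    op="gaussian_blur":  Gaussian filter with std `sigma` (pixels).
    op="additive_noise": i.i.d. Gaussian noise with std `sigma` (of 255).
    op="brightness":     multiply pixels by `factor`.
    """
    if ann.pixels is None:
        raise ValueError("augment requires loaded pixels")
    img = ann.pixels.astype(np.float64)
    if op == "gaussian_blur":
        if sigma is None or sigma <= 0:
            raise ValueError("gaussian_blur needs sigma > 0")
        out = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    elif op == "additive_noise":
        if sigma is None or sigma <= 0:
            raise ValueError("additive_noise needs sigma > 0")
        if rng is None:
            raise ValueError("additive_noise needs an rng")
        out = img + rng.normal(0.0, sigma, img.shape)
    elif op == "brightness":
        if factor is None or factor <= 0:
            raise ValueError("brightness needs factor > 0")
        out = img * factor
    else:
        raise ValueError(f"unknown augmentation {op!r}; one of {AUGMENT_OPS}")
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return replace(ann, pixels=out,
                   objects=[(n, b) for n, b in ann.objects])


def crop_to_targets(ann: AnnotatedImage, margin: int = 8,
                    min_size: int = 32) -> AnnotatedImage:
    """Crop to the union of all boxes plus `margin`, never clipping a box.

    Boxes are translated into crop coordinates; widths/heights are
    preserved exactly.  Without objects the image is returned unchanged.
    """
    if ann.pixels is None:
        raise ValueError("crop_to_targets requires loaded pixels")
    if not ann.objects:
        return ann
    w, h, d = ann.size
    x0 = min(b.x_min for _, b in ann.objects)
    y0 = min(b.y_min for _, b in ann.objects)
    x1 = max(b.x_max for _, b in ann.objects)
    y1 = max(b.y_max for _, b in ann.objects)
    cx0 = max(0, int(np.floor(x0 - margin)))
    cy0 = max(0, int(np.floor(y0 - margin)))
    cx1 = min(w, int(np.ceil(x1 + margin)))
    cy1 = min(h, int(np.ceil(y1 + margin)))
    # honour a minimum window size where the image allows it
    if cx1 - cx0 < min_size:
        grow = min_size - (cx1 - cx0)
        cx0 = max(0, cx0 - grow // 2)
        cx1 = min(w, cx0 + min_size)
        cx0 = max(0, cx1 - min_size)
    if cy1 - cy0 < min_size:
        grow = min_size - (cy1 - cy0)
        cy0 = max(0, cy0 - grow // 2)
        cy1 = min(h, cy0 + min_size)
        cy0 = max(0, cy1 - min_size)
    pixels = ann.pixels[cy0:cy1, cx0:cx1].copy()
    objects = [(n, Box(b.x_min - cx0, b.y_min - cy0, b.x_max - cx0, b.y_max - cy0))
               for n, b in ann.objects]
    return AnnotatedImage(filename=ann.filename,
                          size=(cx1 - cx0, cy1 - cy0, d),
                          objects=objects, pixels=pixels, folder=ann.folder)


def load_image(path: str | Path) -> np.ndarray:
    from PIL import Image
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    from PIL import Image
    Image.fromarray(pixels).save(str(path))
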