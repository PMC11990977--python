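"""VOC XML round-trips, coordinate conventions, splits, augmentations."""

import numpy as np
import pytest

from gcdetect.losses import Box
from gcdetect.voc_io import (AnnotatedImage, VOCParseError, augment,
                             crop_to_targets, read_voc_xml, split_dataset,
                             save_split_manifest, load_split_manifest,
                             write_voc_xml)

MINIMAL_VOC = """<annotation>
  <folder>VOC</folder>
  <filename>bug.png</filename>
  <size><width>300</width><height>400</height><depth>3</depth></size>
  <object>
    <name>pest01</name>
    <bndbox><xmin>10</xmin><ymin>20</ymin><xmax>110</xmax><ymax>220</ymax></bndbox>
  </object>
</annotation>
"""


def make_ann(rng, n_objects=3, size=(64, 48)):
    w, h = size
    objects = []
    for i in range(n_objects):
        x1, y1 = rng.integers(0, w - 10), rng.integers(0, h - 10)
        objects.append((f"pest{i % 3:02d}",
                        Box(float(x1), float(y1),
                            float(x1 + rng.integers(4, 10)),
                            float(y1 + rng.integers(4, 10)))))
    pixels = rng.integers(0, 256, (h, w, 3), dtype=np.uint8)
    return AnnotatedImage(filename="t.png", size=(w, h, 3), objects=objects,
                          pixels=pixels)


def test_voc_coordinates_shift_to_zero_based(tmp_path):
    p = tmp_path / "a.xml"
    p.write_text(MINIMAL_VOC)
    ann = read_voc_xml(p)
    assert ann.size == (300, 400, 3)
    (name, box), = ann.objects
    assert name == "pest01"
    assert (box.x_min, box.y_min, box.x_max, box.y_max) == (9, 19, 109, 219)
    assert (box.width, box.height) == (100, 200)


def test_voc_write_read_is_a_fixed_point(tmp_path, rng):
    ann = make_ann(rng)
    p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
    write_voc_xml(ann, p1)
    back = read_voc_xml(p1)
    assert back.filename == ann.filename and back.size == ann.size
    assert [(n, b.asarray().tolist()) for n, b in back.objects] \
        == [(n, b.asarray().tolist()) for n, b in ann.objects]
    write_voc_xml(back, p2)
    assert p1.read_text() == p2.read_text()


def test_voc_write_emits_one_based_integer_bndbox(tmp_path):
    ann = AnnotatedImage("x.png", (50, 50, 3), [("pest00", Box(0, 0, 10, 10))])
    path = tmp_path / "x.xml"
    write_voc_xml(ann, path)
    text = path.read_text()
    assert "<xmin>1</xmin>" in text and "<xmax>11</xmax>" in text
    empty = AnnotatedImage("y.png", (50, 50, 3), [])
    write_voc_xml(empty, tmp_path / "y.xml")
    assert len(read_voc_xml(tmp_path / "y.xml").objects) == 0


@pytest.mark.parametrize("mutation", [
    lambda s: s.replace("</annotation>", ""),                      # malformed
    lambda s: s.replace("<bndbox>", "<b>").replace("</bndbox>", "</b>"),
    lambda s: s.replace("<xmin>10</xmin>", "<xmin>150</xmin>"),    # inverted
    lambda s: s.replace("<size><width>300</width><height>400</height>"
                        "<depth>3</depth></size>", ""),
])
def test_voc_parse_errors_name_the_file(tmp_path, mutation):
    p = tmp_path / "broken.xml"
    p.write_text(mutation(MINIMAL_VOC))
    with pytest.raises(VOCParseError, match="broken.xml"):
        read_voc_xml(p)


def test_split_sizes_and_determinism(tmp_path):
    samples = [f"img{i:03d}" for i in range(100)]
    m = split_dataset(samples, seed=3)
    assert (len(m.train), len(m.val), len(m.test)) == (80, 10, 10)
    assert sorted(m.all_samples()) == samples
    assert not (set(m.train) & set(m.val)) and not (set(m.val) & set(m.test))
    m2 = split_dataset(samples, seed=3)
    assert (m.train, m.val, m.test) == (m2.train, m2.val, m2.test)
    # different seeds permute membership but keep the exact sizes
    perms = {tuple(split_dataset(samples, seed=s).train) for s in range(10)}
    assert len(perms) == 10
    for s in range(10):
        ms = split_dataset(samples, seed=s)
        assert (len(ms.train), len(ms.val), len(ms.test)) == (80, 10, 10)
    save_split_manifest(m, tmp_path)
    loaded = load_split_manifest(tmp_path, seed=3)
    assert (loaded.train, loaded.val, loaded.test) == (m.train, m.val, m.test)


def test_split_rejects_bad_ratios():
    with pytest.raises(ValueError):
        split_dataset(["a", "b"], ratios=(0.5, 0.2, 0.2))


@pytest.mark.parametrize("op,kw", [
    ("gaussian_blur", {"sigma": 1.2}),
    ("additive_noise", {"sigma": 5.0}),
    ("brightness", {"factor": 1.2}),
])
def test_augmentations_preserve_geometry_and_pixel_range(op, kw, rng):
    ann = make_ann(rng)
    out = augment(ann, op, rng=np.random.default_rng(0), **kw)
    assert [(n, b.asarray().tolist()) for n, b in out.objects] \
        == [(n, b.asarray().tolist()) for n, b in ann.objects]
    assert out.pixels.dtype == np.uint8
    assert out.pixels.shape == ann.pixels.shape
    assert not np.array_equal(out.pixels, ann.pixels)


def test_brightness_identity_factor_is_a_noop(rng):
    ann = make_ann(rng)
    out = augment(ann, "brightness", factor=1.0)
    assert np.array_equal(out.pixels, ann.pixels)


def test_additive_noise_preserves_mean_statistically(rng):
    ann = make_ann(rng, size=(128, 128))
    sigma = 6.0
    out = augment(ann, "additive_noise", sigma=sigma, rng=np.random.default_rng(11))
    n = ann.pixels.size
    tol = 3 * sigma / np.sqrt(n) + 0.5  # + rounding slack
    assert abs(out.pixels.mean() - ann.pixels.mean()) < tol


def test_augment_rejects_bad_parameters(rng):
    ann = make_ann(rng)
    for op, kw in [("gaussian_blur", {"sigma": 0.0}),
                   ("brightness", {"factor": -1.0}),
                   ("additive_noise", {"sigma": -2.0, "rng": np.random.default_rng(0)}),
                   ("posterize", {})]:
        with pytest.raises(ValueError):
            augment(ann, op, **kw)


def test_crop_to_targets_translates_boxes_exactly(rng):
    ann = make_ann(rng, n_objects=2, size=(64, 64))
    cropped = crop_to_targets(ann, margin=4, min_size=8)
    w, h, _ = cropped.size
    assert cropped.pixels.shape == (h, w, 3)
    for (n0, b0), (n1, b1) in zip(ann.objects, cropped.objects):
        assert n0 == n1
        assert (b1.width, b1.height) == (b0.width, b0.height)
        assert 0 <= b1.x_min <= b1.x_max <= w
        assert 0 <= b1.y_min <= b1.y_max <= h
    # a margin covering the whole image keeps it intact
    full = crop_to_targets(ann, margin=1000, min_size=8)
    assert full.size == ann.size
    assert np.array_equal(full.pixels, ann.pixels)


def test_crop_to_targets_manual_coordinates(rng):
    pixels = rng.integers(0, 255, (40, 60, 3), dtype=np.uint8)
    ann = AnnotatedImage("m.png", (60, 40, 3),
                         [("pest00", Box(20, 10, 30, 18))], pixels=pixels)
    out = crop_to_targets(ann, margin=5, min_size=4)
    assert out.size == (20, 18, 3)  # [15, 35) x [5, 23)
    b = out.objects[0][1]
    assert (b.x_min, b.y_min, b.x_max, b.y_max) == (5, 5, 15, 13)
    assert np.array_equal(out.pixels, pixels[5:23, 15:35])
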