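"""Detector plumbing: anchors, target assignment, NMS vs an O(n^2) oracle,
box coding, heads, and the training loop's determinism and resumability."""

import numpy as np
import pytest

from gcdetect import detector as D
from gcdetect import nn
from gcdetect.detector import (AnchorConfig, assign_targets,
                               build_detector, decode_boxes, encode_boxes,
                               generate_anchors, load_checkpoint, nms, predict,
                               save_checkpoint, tiny_config, train)
from gcdetect.losses import iou

from conftest import SMOKE_NAMES


def test_anchor_counts_and_grid_centers():
    cfg = AnchorConfig(sizes=(32,), ratios=(0.5, 1.0, 2.0), strides=(4,))
    (anchors,) = generate_anchors([(2, 2)], cfg)
    assert anchors.shape == (12, 4)  # 2*2 cells x 3 ratios
    centers_x = (anchors[:, 0] + anchors[:, 2]) / 2
    centers_y = (anchors[:, 1] + anchors[:, 3]) / 2
    assert set(np.round(centers_x, 6)) == {2.0, 6.0}  # stride/2 + stride*k
    assert set(np.round(centers_y, 6)) == {2.0, 6.0}
    areas = (anchors[:, 2] - anchors[:, 0]) * (anchors[:, 3] - anchors[:, 1])
    assert np.allclose(areas, 32 * 32)


def test_anchors_match_nested_loop_oracle():
    cfg = AnchorConfig(sizes=(16, 32), ratios=(0.5, 2.0), strides=(8, 16))
    got = generate_anchors([(4, 3), (2, 2)], cfg)
    for lvl, (h, w) in enumerate([(4, 3), (2, 2)]):
        expected = []
        stride, size = cfg.strides[lvl], cfg.sizes[lvl]
        for i in range(h):
            for j in range(w):
                for r in cfg.ratios:
                    cw, ch = size / np.sqrt(r), size * np.sqrt(r)
                    cx, cy = (j + 0.5) * stride, (i + 0.5) * stride
                    expected.append([cx - cw / 2, cy - ch / 2,
                                     cx + cw / 2, cy + ch / 2])
        assert np.allclose(got[lvl], np.asarray(expected))


def test_assign_targets_basic_cases():
    gt = np.array([[0, 0, 10, 10.0]])
    labels, matched = assign_targets(gt.copy(), gt, 0.7, 0.3)
    assert labels.tolist() == [1] and matched.tolist() == [0]
    labels, matched = assign_targets(np.array([[0, 0, 10, 10.0]]),
                                     np.zeros((0, 4)), 0.7, 0.3)
    assert labels.tolist() == [0] and matched.tolist() == [-1]


@pytest.mark.parametrize("seed", range(5))
def test_assign_targets_matches_iou_matrix_oracle(seed):
    rng = np.random.default_rng(seed)
    anchors = np.sort(rng.uniform(0, 40, (5, 2, 2)), axis=2).reshape(5, 4)[:, [0, 2, 1, 3]]
    gts = np.sort(rng.uniform(0, 40, (2, 2, 2)), axis=2).reshape(2, 4)[:, [0, 2, 1, 3]]
    pos_thr, neg_thr = 0.5, 0.2
    labels, matched = assign_targets(anchors, gts, pos_thr, neg_thr)
    ious = np.array([[iou(a, g) for g in gts] for a in anchors])
    for i in range(5):
        best = ious[i].max()
        forced = any(ious[i, g] == ious[:, g].max() > 0 for g in range(2))
        if best >= pos_thr or forced:
            assert labels[i] == 1
            assert ious[i, matched[i]] == best or forced
        elif best < neg_thr:
            assert labels[i] == 0 and matched[i] == -1
        else:
            assert labels[i] == -1


def oracle_nms(boxes, scores, thr):
    order = np.argsort(-scores, kind="stable").tolist()
    keep = []
    while order:
        i = order.pop(0)
        keep.append(i)
        order = [j for j in order if iou(boxes[i], boxes[j]) <= thr]
    return keep


def test_nms_exact_cases():
    boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.0]])
    assert nms(boxes, np.array([0.5, 0.9]), 0.5).tolist() == [1]
    assert nms(boxes, np.array([0.9, 0.9]), 0.5).tolist() == [0]  # tie: low index
    disjoint = np.array([[0, 0, 1, 1], [5, 5, 6, 6], [9, 9, 11, 11.0]])
    assert sorted(nms(disjoint, np.array([0.1, 0.9, 0.5]), 0.3).tolist()) == [0, 1, 2]


@pytest.mark.parametrize("n", [20, 80, 200])
def test_nms_agrees_with_quadratic_oracle(n):
    rng = np.random.default_rng(n)
    xy = rng.uniform(0, 50, (n, 2))
    wh = rng.uniform(2, 20, (n, 2))
    boxes = np.hstack([xy, xy + wh])
    scores = rng.random(n)
    assert nms(boxes, scores, 0.4).tolist() == oracle_nms(boxes, scores, 0.4)


def test_box_encode_decode_roundtrip(rng):
    anchors = np.array([[0, 0, 16, 16], [8, 4, 40, 28.0]])
    boxes = np.array([[2, 3, 20, 17], [10, 10, 30, 30.0]])
    deltas = encode_boxes(boxes, anchors)
    assert np.allclose(decode_boxes(deltas, anchors), boxes, atol=1e-9)


def test_untrained_model_predicts_wellformed_output(rng):
    cfg = tiny_config(3)
    model = build_detector(cfg, 0)
    image = rng.integers(0, 255, (96, 96, 3), dtype=np.uint8)
    dets = predict(model, image)
    assert isinstance(dets, list)
    for r in dets:
        assert 1 <= r.class_id <= 3
        assert 0 < r.score <= 1
        assert 0 <= r.box.x_min <= r.box.x_max <= 96
        assert 0 <= r.box.y_min <= r.box.y_max <= 96


def test_zero_features_give_uniform_class_posterior():
    cfg = tiny_config(4)
    model = build_detector(cfg, 0)
    ch = cfg.backbone.fpn_channels
    pooled = nn.Tensor(np.zeros((2, ch, cfg.roi_pool_size, cfg.roi_pool_size)))
    logits, _ = model.box_head(pooled)
    probs = D._softmax(logits.data)
    assert np.allclose(probs, 1.0 / 5.0)  # K+1 = 5 classes incl. background


def test_eiou_and_smooth_l1_modes_differ_only_in_box_loss(smoke_dataset):
    train_set, _ = smoke_dataset
    names = SMOKE_NAMES
    losses = {}
    for mode in ("smooth_l1", "eiou"):
        cfg = tiny_config(5, regression_loss=mode)
        model = build_detector(cfg, 0)
        model.set_rng(np.random.default_rng(3))
        batch = D.normalize_images(np.stack([a.pixels for a in train_set[:2]]))
        targets = [D.targets_from_annotation(a, names) for a in train_set[:2]]
        losses[mode] = {k: float(v.data) for k, v in model(batch, targets).items()}
    assert losses["smooth_l1"]["roi_class"] == pytest.approx(
        losses["eiou"]["roi_class"], rel=1e-9)
    assert losses["smooth_l1"]["roi_box"] != pytest.approx(
        losses["eiou"]["roi_box"], rel=1e-3)


def test_rpn_loss_decreases_over_short_training(smoke_dataset):
    train_set, _ = smoke_dataset
    cfg = tiny_config(5)
    cfg.batch_size = 2
    model, history = train(train_set[:8], cfg, None, seed=2,
                           class_names=SMOKE_NAMES, epochs=8)
    first = history[0]["rpn_objectness"]
    last = history[-1]["rpn_objectness"]
    assert np.isfinite([h["loss"] for h in history]).all()
    assert last < first
    assert history[-1]["loss"] < history[0]["loss"]


def test_training_is_seed_deterministic(smoke_dataset):
    train_set, _ = smoke_dataset
    cfg = tiny_config(5)
    cfg.batch_size = 2
    _, h1 = train(train_set[:6], cfg, None, seed=4, class_names=SMOKE_NAMES, epochs=2)
    _, h2 = train(train_set[:6], cfg, None, seed=4, class_names=SMOKE_NAMES, epochs=2)
    assert [h["loss"] for h in h1] == [h["loss"] for h in h2]
    _, h3 = train(train_set[:6], cfg, None, seed=5, class_names=SMOKE_NAMES, epochs=2)
    assert [h["loss"] for h in h1] != [h["loss"] for h in h3]


def test_checkpoint_resume_reproduces_trajectory(tmp_path, smoke_dataset):
    train_set, _ = smoke_dataset
    data = train_set[:6]
    cfg = tiny_config(5)
    cfg.batch_size = 2
    from gcdetect.schedule import ScheduleConfig
    sched = ScheduleConfig(total_steps=4 * 3, base_lr=cfg.base_lr, warmup_steps=2)
    model_full, h_full = train(data, cfg, sched, seed=6,
                               class_names=SMOKE_NAMES, epochs=4)
    ckpt = tmp_path / "ck.npz"
    train(data, cfg, sched, seed=6, class_names=SMOKE_NAMES, epochs=2,
          checkpoint_path=ckpt)
    model_res, h_res = train(data, cfg, sched, seed=6, class_names=SMOKE_NAMES,
                             epochs=4, resume=ckpt)
    assert [h["loss"] for h in h_res] == pytest.approx(
        [h["loss"] for h in h_full[2:]], rel=1e-12)
    sf, sr = model_full.state_dict(), model_res.state_dict()
    for k in sf:
        assert np.allclose(sf[k], sr[k], atol=1e-12), k


def test_checkpoint_roundtrip_preserves_weights_and_config(tmp_path):
    cfg = tiny_config(4, gct_placement="layer23", cbam_locations=("C3",),
                      regression_loss="eiou")
    model = build_detector(cfg, 9)
    path = tmp_path / "model.npz"
    save_checkpoint(path, model, None, epoch=7)
    loaded, velocity, epoch, _ = load_checkpoint(path)
    assert epoch == 7 and velocity is None
    assert loaded.cfg.regression_loss == "eiou"
    assert loaded.cfg.backbone.gct_placement == "layer23"
    s0, s1 = model.state_dict(), loaded.state_dict()
    assert s0.keys() == s1.keys()
    for k in s0:
        assert np.array_equal(s0[k], s1[k])


def test_trained_model_detects_heldout_target(trained_tiny, smoke_dataset):
    model, history = trained_tiny
    _, heldout = smoke_dataset
    assert history[-1]["loss"] < history[0]["loss"]
    hits = 0
    for ann in heldout:
        dets = predict(model, ann.pixels)
        for _, gt_box in ann.objects:
            g = gt_box.asarray()
            if any(iou(r.box.asarray(), g) >= 0.5 for r in dets):
                hits += 1
                break
    assert hits >= len(heldout) // 2  # most held-out scenes hit at IoU 0.5


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        train([], tiny_config(3), None, seed=0, class_names=["a"])
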