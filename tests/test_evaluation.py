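"""Metrics: greedy matching, 101-point AP, full COCO-protocol sweep against
an independently coded loop oracle, confusion matrices, Grad-CAM maps."""

import numpy as np
import pytest

from gcdetect.evaluation import (COCO_IOU_THRESHOLDS, DetectionRecord,
                                 GroundTruthRecord, activation_heatmap,
                                 average_precision, confusion_matrix, evaluate,
                                 match_detections)
from gcdetect.losses import Box, iou


def det(img, cls, score, x1, y1, x2, y2):
    return DetectionRecord(img, cls, score, Box(x1, y1, x2, y2))


def gt(img, cls, x1, y1, x2, y2):
    return GroundTruthRecord(img, cls, Box(x1, y1, x2, y2))


def random_records(rng, n_images=8, n_classes=3, dets_per_img=6, gts_per_img=3):
    dets, gts_ = [], []
    for img in range(n_images):
        for _ in range(gts_per_img):
            x, y = rng.uniform(0, 60, 2)
            w, h = rng.uniform(5, 25, 2)
            gts_.append(gt(img, int(rng.integers(1, n_classes + 1)),
                           x, y, x + w, y + h))
        for _ in range(dets_per_img):
            if rng.random() < 0.7 and gts_:
                # perturb a gt box so scores/IoUs span the threshold sweep
                base = gts_[int(rng.integers(0, len(gts_)))]
                if base.image_id != img:
                    continue
                b = base.box
                jit = rng.normal(0, 3, 4)
                x1, y1 = b.x_min + jit[0], b.y_min + jit[1]
                x2, y2 = max(b.x_max + jit[2], x1 + 1), max(b.y_max + jit[3], y1 + 1)
                cls = base.class_id if rng.random() < 0.8 \
                    else int(rng.integers(1, n_classes + 1))
                dets.append(det(img, cls, float(rng.random()), x1, y1, x2, y2))
            else:
                x, y = rng.uniform(0, 60, 2)
                w, h = rng.uniform(5, 25, 2)
                dets.append(det(img, int(rng.integers(1, n_classes + 1)),
                                float(rng.random()), x, y, x + w, y + h))
    return dets, gts_


# -- independent protocol oracle ---------------------------------------------

def oracle_ap(dets, gts_, thr):
    """Greedy matching + all-recall-point envelope mean, written separately."""
    dets = sorted(dets, key=lambda d: -d.score)
    taken = set()
    flags = []
    for d in dets:
        best_iou, best_g = thr, None
        for gi, g in enumerate(gts_):
            if gi in taken or g.image_id != d.image_id:
                continue
            v = iou(d.box.asarray(), g.box.asarray())
            if v >= best_iou:
                best_iou, best_g = v, gi
        if best_g is not None:
            taken.add(best_g)
            flags.append(True)
        else:
            flags.append(False)
    n_gt = len(gts_)
    if n_gt == 0:
        return float("nan"), float("nan")
    recall_pts = [i / 100 for i in range(101)]
    tp = 0
    prec_at = []
    rec_at = []
    for i, f in enumerate(flags):
        tp += f
        prec_at.append(tp / (i + 1))
        rec_at.append(tp / n_gt)
    ap = 0.0
    for r in recall_pts:
        best = 0.0
        for p, rr in zip(prec_at, rec_at):
            if rr >= r:
                best = max(best, p)
        ap += best
    return ap / 101, len(taken) / n_gt


def oracle_evaluate(dets, gts_, thresholds, max_dets=100):
    capped = []
    for img in {d.image_id for d in dets}:
        recs = sorted([d for d in dets if d.image_id == img], key=lambda d: -d.score)
        capped.extend(recs[:max_dets])
    classes = sorted({g.class_id for g in gts_} | {d.class_id for d in capped})
    aps, ars = [], []
    ap50, ap75 = [], []
    for k in classes:
        dk = [d for d in capped if d.class_id == k]
        gk = [g for g in gts_ if g.class_id == k]
        if not gk:
            continue
        for t in thresholds:
            a, r = oracle_ap(dk, gk, t)
            aps.append(a)
            ars.append(r)
            if abs(t - 0.5) < 1e-9:
                ap50.append(a)
            if abs(t - 0.75) < 1e-9:
                ap75.append(a)
    return (np.mean(ap50), np.mean(ap75), np.mean(aps), np.mean(ars))


def test_match_detections_basic_cases():
    g = [gt(0, 1, 0, 0, 10, 10)]
    tp, unmatched = match_detections([det(0, 1, 0.9, 0, 0, 10, 10)], g, 0.5)
    assert tp.tolist() == [True] and unmatched == 0
    tp, unmatched = match_detections([det(0, 1, 0.9, 0, 0, 10, 10)], [], 0.5)
    assert tp.tolist() == [False] and unmatched == 0
    tp, unmatched = match_detections([], g, 0.5)
    assert tp.size == 0 and unmatched == 1


def test_match_detections_greedy_by_score():
    g = [gt(0, 1, 0, 0, 10, 10), gt(0, 1, 20, 0, 30, 10)]
    dets = [det(0, 1, 0.3, 0, 0, 10, 10),    # overlaps gt0 but low score
            det(0, 1, 0.9, 1, 0, 11, 10),    # claims gt0 first
            det(0, 1, 0.5, 0, 0, 9, 10)]     # gt0 already taken -> FP
    tp, unmatched = match_detections(dets, g, 0.5)
    assert tp.tolist() == [False, True, False]
    assert unmatched == 1


def test_average_precision_closed_forms():
    assert average_precision(np.array([True]), np.array([0.9]), 1) == 1.0
    assert average_precision(np.array([False]), np.array([0.9]), 1) == 0.0
    # [TP, FP, TP] with 2 gts: envelope 1.0 up to recall .5, then 2/3
    ap = average_precision(np.array([True, False, True]),
                           np.array([0.9, 0.8, 0.7]), 2)
    assert ap == pytest.approx((51 * 1.0 + 50 * (2 / 3)) / 101)
    assert np.isnan(average_precision(np.array([True]), np.array([0.9]), 0))


def test_perfect_and_empty_detections():
    gts_ = [gt(i, 1 + i % 2, 5, 5, 20, 20) for i in range(4)]
    perfect = [det(g.image_id, g.class_id, 1.0, 5, 5, 20, 20) for g in gts_]
    res = evaluate(perfect, gts_)
    assert (res.map50, res.map75, res.map5095, res.mar5095) == (1, 1, 1, 1)
    res0 = evaluate([], gts_)
    assert (res0.map50, res0.map75, res0.map5095, res0.mar5095) == (0, 0, 0, 0)


@pytest.mark.parametrize("seed", range(20))
def test_evaluate_matches_protocol_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    dets, gts_ = random_records(rng)
    res = evaluate(dets, gts_)
    o50, o75, o_map, o_mar = oracle_evaluate(dets, gts_, COCO_IOU_THRESHOLDS)
    assert res.map50 == pytest.approx(o50, abs=1e-6)
    assert res.map75 == pytest.approx(o75, abs=1e-6)
    assert res.map5095 == pytest.approx(o_map, abs=1e-6)
    assert res.mar5095 == pytest.approx(o_mar, abs=1e-6)


def test_evaluate_is_invariant_to_detection_order(rng):
    dets, gts_ = random_records(rng)
    res = evaluate(dets, gts_)
    perm = [dets[i] for i in rng.permutation(len(dets))]
    res2 = evaluate(perm, gts_)
    assert res.map5095 == pytest.approx(res2.map5095, abs=1e-12)
    assert res.mar5095 == pytest.approx(res2.mar5095, abs=1e-12)


def test_duplicate_detection_never_improves_metrics(rng):
    dets, gts_ = random_records(rng)
    base = evaluate(dets, gts_)
    dup = dets + [dets[0]]
    res = evaluate(dup, gts_)
    assert res.map50 <= base.map50 + 1e-12
    assert res.map5095 <= base.map5095 + 1e-12
    assert res.mar5095 <= base.mar5095 + 1e-12


def test_max_dets_cap_limits_recall():
    gts_ = [gt(0, 1, 10 * i, 0, 10 * i + 8, 8) for i in range(5)]
    dets = [det(0, 1, 0.9 - 0.1 * i, 10 * i, 0, 10 * i + 8, 8) for i in range(5)]
    res = evaluate(dets, gts_, max_dets=2)
    assert res.mar5095 == pytest.approx(2 / 5)


def test_confusion_matrix_diagonal_and_background_conventions():
    gts_ = [gt(0, 1, 0, 0, 10, 10), gt(0, 2, 20, 20, 30, 30)]
    dets = [det(0, 1, 0.9, 0, 0, 10, 10), det(0, 2, 0.8, 20, 20, 30, 30)]
    m = confusion_matrix(dets, gts_, num_classes=3)
    assert m[0, 0] == 1 and m[1, 1] == 1 and m.sum() == 2
    # no detections: all gt mass in the background column
    m2 = confusion_matrix([], gts_, num_classes=3)
    assert m2[0, 3] == 1 and m2[1, 3] == 1 and m2.sum() == 2
    # unmatched detection lands in the background row
    m3 = confusion_matrix([det(0, 3, 0.9, 50, 50, 60, 60)], gts_, num_classes=3)
    assert m3[3, 2] == 1 and m3[0, 3] == 1 and m3[1, 3] == 1


def test_confusion_matrix_class_agnostic_pairing():
    # a misclassified but well-localized detection pairs with the gt
    gts_ = [gt(0, 1, 0, 0, 10, 10)]
    dets = [det(0, 2, 0.9, 0, 0, 10, 10)]
    m = confusion_matrix(dets, gts_, num_classes=2)
    assert m[0, 1] == 1 and m.sum() == 1


@pytest.mark.parametrize("seed", range(5))
def test_confusion_matrix_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    dets, gts_ = random_records(rng, n_images=4)
    num_classes = 3
    m = confusion_matrix(dets, gts_, num_classes, iou_thr=0.5, score_thr=0.5)
    ref = np.zeros((num_classes + 1, num_classes + 1), dtype=int)
    for img in sorted({g.image_id for g in gts_} | {d.image_id for d in dets}):
        d_img = [d for d in dets if d.image_id == img and d.score >= 0.5]
        g_img = [g for g in gts_ if g.image_id == img]
        used = set()
        for g in g_img:
            pairs = [(iou(g.box.asarray(), d.box.asarray()), -d.score, di)
                     for di, d in enumerate(d_img) if di not in used]
            pairs = [p for p in pairs if p[0] >= 0.5]
            if pairs:
                best = max(pairs, key=lambda p: (p[0], p[1]))
                used.add(best[2])
                ref[g.class_id - 1, d_img[best[2]].class_id - 1] += 1
            else:
                ref[g.class_id - 1, num_classes] += 1
        for di, d in enumerate(d_img):
            if di not in used:
                ref[num_classes, d.class_id - 1] += 1
    assert np.array_equal(m, ref)
    row_sums = m[:num_classes].sum(axis=1)
    gt_counts = np.bincount([g.class_id - 1 for g in gts_], minlength=num_classes)
    assert np.array_equal(row_sums, gt_counts)


def test_activation_heatmap_bounds_and_focus(trained_tiny, smoke_dataset):
    model, _ = trained_tiny
    _, heldout = smoke_dataset
    with pytest.raises(ValueError):
        activation_heatmap(model, heldout[0].pixels, "C7", 1)
    from conftest import SMOKE_NAMES
    focused = 0
    for ann in heldout[:8]:
        # target the class of an object actually present in the scene
        target = SMOKE_NAMES.index(ann.objects[0][0]) + 1
        heat = activation_heatmap(model, ann.pixels, "C3", target)
        assert heat.shape == ann.pixels.shape[:2]
        assert heat.min() >= 0 and heat.max() <= 1.0
        if heat.max() > 0:
            assert heat.max() == pytest.approx(1.0)
        mask = np.zeros(heat.shape, dtype=bool)
        for _, b in ann.objects:
            mask[int(b.y_min):int(b.y_max) + 1, int(b.x_min):int(b.x_max) + 1] = True
        inside = heat[mask].mean() if mask.any() else 0.0
        outside = heat[~mask].mean()
        if inside > outside:
            focused += 1
    assert focused >= 5  # >= 60% of the held-out scenes
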