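"""Inner-IoU geometry, target assignment, composite loss and NMS."""

import warnings

import numpy as np
import pytest

import sgsnet as sg
from sgsnet._tensor import Tensor
from sgsnet.head import (Detection, InnerIoUConfig, assign_targets,
                         composite_loss, decode_and_nms, inner_iou,
                         inner_iou_loss, inner_iou_tensor, nms, N_BINS,
                         RawPrediction)


def rasterized_iou(a, b, ratio=1.0, cells=2000):
    """Count-overlap oracle on a fine grid covering both (rescaled) boxes."""
    def shrink(box):
        x0, y0, x1, y1 = box
        cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
        w, h = (x1 - x0) * ratio, (y1 - y0) * ratio
        return cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2
    a, b = shrink(a), shrink(b)
    lo = min(a[0], b[0]), min(a[1], b[1])
    hi = max(a[2], b[2]), max(a[3], b[3])
    xs = np.linspace(lo[0], hi[0], cells)
    ys = np.linspace(lo[1], hi[1], cells)
    xx, yy = np.meshgrid(xs, ys)
    ina = (xx >= a[0]) & (xx <= a[2]) & (yy >= a[1]) & (yy <= a[3])
    inb = (xx >= b[0]) & (xx <= b[2]) & (yy >= b[1]) & (yy <= b[3])
    union = (ina | inb).sum()
    return (ina & inb).sum() / union if union else 0.0


class TestInnerIoU:
    def test_identical_boxes_are_one(self):
        box = np.array([1.0, 2.0, 4.0, 7.0])
        for ratio in (0.5, 0.75, 1.0, 1.5):
            assert inner_iou(box, box, ratio) == pytest.approx(1.0)
            assert inner_iou_loss(box, box, ratio) == pytest.approx(0.0)

    def test_worked_value_one_seventh(self):
        p = np.array([0.0, 0.0, 2.0, 2.0])
        g = np.array([1.0, 1.0, 3.0, 3.0])
        assert inner_iou(p, g, 1.0) == pytest.approx(1 / 7)
        assert inner_iou(p, g, 1.0) == pytest.approx(
            rasterized_iou(p, g, 1.0), abs=2e-3)

    def test_worked_value_shrunk_to_touching(self):
        p = np.array([0.0, 0.0, 2.0, 2.0])
        g = np.array([1.0, 1.0, 3.0, 3.0])
        assert inner_iou(p, g, 0.5) == 0.0
        assert inner_iou_loss(p, g, 0.5) == 1.0

    def test_matches_rasterized_oracle_random_pairs(self):
        g = np.random.default_rng(7)
        for _ in range(25):
            a = np.sort(g.uniform(0, 10, 4).reshape(2, 2), axis=0).T.ravel()[[0, 2, 1, 3]]
            b = np.sort(g.uniform(0, 10, 4).reshape(2, 2), axis=0).T.ravel()[[0, 2, 1, 3]]
            a = np.array([min(a[0], a[2]), min(a[1], a[3]),
                          min(a[0], a[2]) + 1 + abs(a[2] - a[0]),
                          min(a[1], a[3]) + 1 + abs(a[3] - a[1])])
            b = np.array([min(b[0], b[2]), min(b[1], b[3]),
                          min(b[0], b[2]) + 1 + abs(b[2] - b[0]),
                          min(b[1], b[3]) + 1 + abs(b[3] - b[1])])
            for ratio in (0.6, 1.0, 1.3):
                assert inner_iou(a, b, ratio) == pytest.approx(
                    rasterized_iou(a, b, ratio, cells=1500), abs=5e-3)

    def test_ratio_one_equals_standard_iou_property(self):
        g = np.random.default_rng(1)
        xy = g.uniform(0, 50, (10000, 2, 2))
        wh = g.uniform(0.5, 20, (10000, 2, 2))
        boxes = np.concatenate([xy, xy + wh], axis=-1)   # (N, 2, 4)
        a, b = boxes[:, 0], boxes[:, 1]
        # independent standard IoU
        iw = np.maximum(0, np.minimum(a[:, 2], b[:, 2]) - np.maximum(a[:, 0], b[:, 0]))
        ih = np.maximum(0, np.minimum(a[:, 3], b[:, 3]) - np.maximum(a[:, 1], b[:, 1]))
        inter = iw * ih
        union = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
                 + (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1]) - inter)
        want = inter / union
        got = inner_iou(a, b, 1.0)
        assert np.abs(got - want).max() < 1e-9

    def test_symmetry_and_translation_monotonicity(self):
        g = np.random.default_rng(3)
        a = np.array([0.0, 0.0, 4.0, 4.0])
        for _ in range(50):
            b = np.concatenate([g.uniform(-2, 2, 2), g.uniform(3, 8, 2)])
            for r in (0.5, 1.0):
                assert inner_iou(a, b, r) == pytest.approx(inner_iou(b, a, r))
                assert 0.0 <= inner_iou(a, b, r) <= 1.0
        prev = np.inf
        for shift in np.linspace(0, 10, 30):
            v = inner_iou(a, a + np.array([shift, 0, shift, 0]), 0.75)
            assert v <= prev + 1e-12
            prev = v

    def test_degenerate_box_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            v = inner_iou(np.array([0, 0, 0, 2.0]), np.array([0, 0, 1.0, 1.0]))
        assert v == 0.0

    def test_tensor_version_matches_numpy(self):
        g = np.random.default_rng(5)
        pred = np.concatenate([g.uniform(0, 5, (64, 2)),
                               g.uniform(6, 12, (64, 2))], axis=1)
        gt = np.concatenate([g.uniform(0, 5, (64, 2)),
                             g.uniform(6, 12, (64, 2))], axis=1)
        got = inner_iou_tensor(Tensor(pred.astype(np.float32)), gt, 0.75).data
        want = inner_iou(pred, gt, 0.75)
        assert np.allclose(got, want, atol=1e-5)


def _fake_preds(n_img=1, sizes=((8, 8), (4, 4), (2, 2)), strides=(8, 16, 32),
                nc=5, seed=0, scale=0.01):
    g = np.random.default_rng(seed)
    reg = [Tensor(g.standard_normal((n_img, 4 * N_BINS, h, w)).astype(np.float32) * scale)
           for h, w in sizes]
    cls = [Tensor(g.standard_normal((n_img, nc, h, w)).astype(np.float32) * scale - 4)
           for h, w in sizes]
    obj = [Tensor(g.standard_normal((n_img, 1, h, w)).astype(np.float32) * scale - 4)
           for h, w in sizes]
    return RawPrediction(reg, cls, obj, strides)


class TestAssignment:
    def test_single_cell_box_assigned_at_matching_scale(self):
        preds = _fake_preds()
        # a box covering exactly the P5 cell centered at (16, 16)
        gts = [[(2, (0.0, 0.0, 32.0, 32.0))]]
        a = assign_targets(preds, gts, 64)
        assert a.pos_index[0].size >= 1
        # every positive must lie inside the box
        import sgsnet.head as H
        centers = np.concatenate([H._cell_centers(h, w, s).reshape(-1, 2)
                                  for (h, w), s in zip(a.level_sizes, a.strides)])
        for i in a.pos_index[0]:
            assert 0 < centers[i, 0] < 32 and 0 < centers[i, 1] < 32
        assert np.all(a.pos_gt_cls[0] == 2)

    def test_no_ground_truth_all_negative(self):
        a = assign_targets(_fake_preds(), [[]], 64)
        assert a.pos_index[0].size == 0
        loss = composite_loss(_fake_preds(), a)
        assert loss.box_loss == 0.0 and loss.dfl_loss == 0.0
        assert loss.total > 0          # objectness still penalized

    def test_duplicate_gts_each_cell_assigned_once(self):
        preds = _fake_preds(sizes=((4, 4),), strides=(8,))
        box = (0.0, 0.0, 32.0, 32.0)
        a = assign_targets(preds, [[(1, box), (1, box)]], 32)
        idx = a.pos_index[0]
        assert len(idx) == len(set(idx.tolist()))

    def test_at_most_topk_per_gt(self):
        preds = _fake_preds(sizes=((16, 16),), strides=(8,))
        a = assign_targets(preds, [[(0, (0.0, 0.0, 128.0, 128.0))]], 128, topk=10)
        assert a.pos_index[0].size <= 10


class TestCompositeLoss:
    def test_half_probability_cls_term_is_ln2(self):
        preds = _fake_preds(sizes=((2, 2),), strides=(8,), scale=0.0)
        for c in preds.cls:
            c.data[:] = 0.0            # sigmoid -> 0.5 everywhere
        a = assign_targets(preds, [[(0, (0.0, 0.0, 16.0, 16.0))]], 16)
        loss = composite_loss(preds, a)
        assert loss.cls_loss == pytest.approx(np.log(2), abs=1e-6)

    def test_perfect_prediction_limit(self):
        # logits strongly aligned with the targets drive every term near 0
        preds = _fake_preds(sizes=((4, 4),), strides=(8,), scale=0.0)
        gt_box = (0.0, 0.0, 16.0, 16.0)
        a = assign_targets(preds, [[(3, gt_box)]], 32)
        idx = a.pos_index[0]
        obj = np.full((1, 1, 16), -20.0, np.float32)
        obj[0, 0, idx] = 20.0
        preds.obj[0].data[:] = obj.reshape(1, 1, 4, 4)
        cls = np.full((1, 5, 16), -20.0, np.float32)
        cls[0, 3, idx] = 20.0
        preds.cls[0].data[:] = cls.reshape(1, 5, 4, 4)
        # set regression distributions to a sharp peak at the true distance
        import sgsnet.head as H
        centers = H._cell_centers(4, 4, 8).reshape(-1, 2)
        reg = preds.reg[0].data.reshape(1, 4, N_BINS, 16)
        for i in idx:
            d = [centers[i, 0] - gt_box[0], centers[i, 1] - gt_box[1],
                 gt_box[2] - centers[i, 0], gt_box[3] - centers[i, 1]]
            for side, dist in enumerate(d):
                t = dist / 8.0
                reg[0, side, :, i] = -50.0
                lo = int(np.floor(t))
                reg[0, side, lo, i] = 50.0 * (1 - (t - lo))
                reg[0, side, min(lo + 1, N_BINS - 1), i] = 50.0 * (t - lo)
        loss = composite_loss(preds, a)
        assert loss.obj_loss < 1e-4 and loss.cls_loss < 1e-4
        assert loss.box_loss < 0.1

    def test_box_weight_scales_linearly(self):
        preds = _fake_preds(sizes=((4, 4),), strides=(8,))
        a = assign_targets(preds, [[(0, (2.0, 2.0, 20.0, 20.0))]], 32)
        w1 = dict(sg.head.LOSS_WEIGHTS)
        w2 = dict(w1, box=2 * w1["box"])
        l1 = composite_loss(preds, a, weights=w1)
        l2 = composite_loss(preds, a, weights=w2)
        assert l2.total - l1.total == pytest.approx(
            w1["box"] * l1.box_loss, rel=1e-6)


def brute_force_nms(dets, thr):
    """All-pairs suppression oracle."""
    keep = []
    for cls in {d.class_id for d in dets}:
        cand = sorted([d for d in dets if d.class_id == cls], key=lambda d: -d.score)
        removed = set()
        for i, d in enumerate(cand):
            if i in removed:
                continue
            keep.append(d)
            for j in range(i + 1, len(cand)):
                if j in removed:
                    continue
                from sgsnet.head import iou_matrix
                if iou_matrix(d.xyxy[None], cand[j].xyxy[None])[0, 0] > thr:
                    removed.add(j)
    return sorted(keep, key=lambda d: -d.score)


class TestNMS:
    def test_duplicate_boxes_keep_highest_score(self):
        d1 = Detection(0, 0.9, 0, 0, 10, 10)
        d2 = Detection(0, 0.8, 0, 0, 10, 10)
        out = nms([d1, d2], 0.5)
        assert out == [d1]

    def test_disjoint_boxes_both_survive(self):
        d1 = Detection(0, 0.9, 0, 0, 10, 10)
        d2 = Detection(0, 0.8, 20, 20, 30, 30)
        assert len(nms([d1, d2], 0.5)) == 2

    def test_matches_brute_force_on_random_boxes(self):
        g = np.random.default_rng(11)
        dets = []
        for _ in range(50):
            x0, y0 = g.uniform(0, 50, 2)
            w, h = g.uniform(5, 25, 2)
            dets.append(Detection(int(g.integers(0, 3)), float(g.random()),
                                  x0, y0, x0 + w, y0 + h))
        assert nms(dets, 0.5) == brute_force_nms(dets, 0.5)

    def test_decode_shapes_and_ordering(self):
        preds = _fake_preds(seed=3, scale=1.0)
        out = decode_and_nms(preds, conf_thr=0.001, nms_iou=0.7)
        scores = [d.score for d in out[0]]
        assert scores == sorted(scores, reverse=True)
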