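"""Metrics (matching, PR/AP/mAP), the complexity audit and Grad-CAM++."""

import numpy as np
import pytest

import sgsnet as sg
from sgsnet.head import Detection
from sgsnet.evaluate import (audit_model, average_precision, gradcam_pp,
                             map_at_05, match_detections, precision_recall_f1)


def det(c, s, x0, y0, x1, y1):
    return Detection(c, s, x0, y0, x1, y1)


class TestMatching:
    def test_single_overlapping_detection_is_tp(self):
        labels, fn = match_detections([det(0, 0.9, 0, 0, 10, 10)],
                                      [(0, (0, 0, 8, 10))], 0.5)
        assert labels.tolist() == [True] and fn == 0

    def test_second_detection_on_same_gt_is_fp(self):
        dets = [det(0, 0.9, 0, 0, 10, 10), det(0, 0.8, 1, 1, 10, 10)]
        labels, fn = match_detections(dets, [(0, (0, 0, 10, 10))], 0.5)
        assert labels.tolist() == [True, False] and fn == 0

    def test_class_mismatch_never_matches(self):
        labels, fn = match_detections([det(1, 0.9, 0, 0, 10, 10)],
                                      [(0, (0, 0, 10, 10))], 0.5)
        assert labels.tolist() == [False] and fn == 1

    def test_random_instance_matches_independent_oracle(self):
        g = np.random.default_rng(4)
        gts = []
        for _ in range(10):
            x0, y0 = g.uniform(0, 60, 2)
            w, h = g.uniform(8, 20, 2)
            gts.append((int(g.integers(0, 2)), (x0, y0, x0 + w, y0 + h)))
        dets = []
        for _ in range(20):
            x0, y0 = g.uniform(0, 60, 2)
            w, h = g.uniform(8, 20, 2)
            dets.append(det(int(g.integers(0, 2)), float(g.random()),
                            x0, y0, x0 + w, y0 + h))
        dets.sort(key=lambda d: -d.score)
        labels, fn = match_detections(dets, gts, 0.5)

        # independent oracle: same greedy policy, separate implementation
        from sgsnet.head import iou_matrix
        taken = set()
        want = []
        for d in dets:
            pick, best = -1, 0.5 - 1e-12
            for gi, (gc, gb) in enumerate(gts):
                if gi in taken or gc != d.class_id:
                    continue
                iou = iou_matrix(d.xyxy[None], np.asarray(gb)[None])[0, 0]
                if iou > best:
                    best, pick = iou, gi
            if pick >= 0:
                taken.add(pick)
                want.append(True)
            else:
                want.append(False)
        assert labels.tolist() == want
        assert fn == len(gts) - len(taken)


class TestScalarMetrics:
    def test_worked_values(self):
        p, r, f1 = precision_recall_f1(2, 1, 0)
        assert (p, r, f1) == pytest.approx((2 / 3, 1.0, 0.8))

    def test_zero_over_zero_convention(self):
        assert precision_recall_f1(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_f1_equals_p_when_p_equals_r(self):
        p, r, f1 = precision_recall_f1(5, 5, 5)
        assert p == r == f1 == 0.5


def brute_force_ap(scores, labels, n_gt, grid=200001):
    """Numeric integration of the exhaustive PR staircase (oracle)."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    lab = np.asarray(labels, bool)[order]
    tps = np.cumsum(lab)
    fps = np.cumsum(~lab)
    rec = tps / n_gt
    prec = tps / np.maximum(tps + fps, 1)
    # precision envelope sampled on a dense recall grid
    rr = np.linspace(0, rec[-1] if len(rec) else 0.0, grid)
    env = np.zeros_like(rr)
    for i, r in enumerate(rr):
        mask = rec >= r - 1e-12
        env[i] = prec[mask].max() if mask.any() else 0.0
    return float(np.trapezoid(env, rr))


class TestAveragePrecision:
    def test_single_tp(self):
        assert average_precision([0.9], [True], 1) == 1.0

    def test_tp_then_fp_envelope(self):
        assert average_precision([0.9, 0.8], [True, False], 1) == 1.0

    def test_no_gt_flagged_zero(self):
        assert average_precision([], [], 0) == 0.0

    def test_matches_staircase_integration(self):
        g = np.random.default_rng(9)
        for _ in range(10):
            n = 30
            scores = g.random(n)
            labels = g.random(n) < 0.4
            n_gt = int(labels.sum() + g.integers(0, 4))
            if n_gt == 0:
                continue
            got = average_precision(scores, labels, n_gt)
            want = brute_force_ap(scores, labels, n_gt)
            assert got == pytest.approx(want, abs=5e-5)

    def test_appending_low_scored_fp_never_increases_ap(self):
        g = np.random.default_rng(2)
        scores = list(g.uniform(0.5, 1.0, 20))
        labels = list(g.random(20) < 0.5)
        base = average_precision(scores, labels, 12)
        worse = average_precision(scores + [0.1], labels + [False], 12)
        assert worse <= base + 1e-12


class TestMAP:
    def _toy(self):
        gts = [[(0, (0, 0, 10, 10)), (1, (20, 20, 30, 30))],
               [(0, (5, 5, 15, 15))],
               [(2, (0, 0, 8, 8))]]
        return gts

    def test_echo_detector_scores_one(self):
        gts = self._toy()
        dets = [[det(c, 1.0, *b) for c, b in img] for img in gts]
        rep = map_at_05(dets, gts)
        assert rep.map50 == 1.0

    def test_silent_detector_scores_zero(self):
        gts = self._toy()
        rep = map_at_05([[], [], []], gts)
        assert rep.map50 == 0.0

    def test_hand_computed_toy_aps(self):
        gts = self._toy()
        dets = [
            [det(0, 0.9, 0, 0, 10, 10),          # TP class 0
             det(1, 0.8, 100, 100, 110, 110)],    # FP class 1
            [det(0, 0.7, 50, 50, 60, 60)],        # FP class 0
            [],                                   # class 2 missed
        ]
        rep = map_at_05(dets, gts)
        # class 0: ranked TP(0.9), FP(0.7), 2 gts -> AP = 0.5
        assert rep.per_class["Flowering"]["ap"] == pytest.approx(0.5)
        # class 1: one FP, one gt -> AP 0; class 2: nothing -> AP 0
        assert rep.map50 == pytest.approx((0.5 + 0 + 0) / 3)

    def test_classes_without_gt_excluded_from_mean(self):
        gts = [[(0, (0, 0, 10, 10))]]
        dets = [[det(0, 1.0, 0, 0, 10, 10)]]
        rep = map_at_05(dets, gts)
        assert rep.map50 == 1.0
        assert rep.per_class["Maturation"]["n_gt"] == 0


class TestAudit:
    def test_single_conv_params(self):
        from sgsnet.layers import Conv2dLayer, ConvSpec
        lyr = Conv2dLayer(ConvSpec(3, 3, 3, 16), np.random.default_rng(0))
        recs, _, _ = lyr.audit_records(320, 320)
        assert recs[0]["params"] == 432

    def test_single_conv_flops_at_320(self):
        from sgsnet.layers import Conv2dLayer, ConvSpec
        lyr = Conv2dLayer(ConvSpec(3, 3, 3, 16), np.random.default_rng(0))
        recs, _, _ = lyr.audit_records(320, 320)
        assert recs[0]["flops"] == 44_236_800
        assert recs[0]["flops"] / 1e9 == pytest.approx(0.0442368)

    def test_totals_sum_of_layers_and_gflops_scaling(self, tiny_model):
        rep = audit_model(tiny_model, 320)
        assert rep.total_params == sum(r["params"] for r in rep.layers)
        assert rep.gflops == rep.total_flops / 1e9

    def test_audit_equals_actual_parameter_count(self, tiny_model):
        rep = audit_model(tiny_model, 320)
        assert rep.total_params == tiny_model.n_params()

    def test_audit_deterministic_across_calls(self, tiny_model):
        a = audit_model(tiny_model, 320)
        b = audit_model(tiny_model, 320)
        assert a.total_params == b.total_params and a.total_flops == b.total_flops

    def test_indivisible_input_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            audit_model(tiny_model, 100)


class _LinearProbe:
    """One-conv linear model stub: feature map = 2x the gray input, class
    score = its sum (analytic gradient is uniform and positive)."""

    def preprocess(self, image):
        x = np.asarray(image, np.float32).mean(axis=2) / 255.0
        return x[None, None]

    def set_training(self, mode):
        pass

    def class_score(self, x, class_id, layer):
        from sgsnet._tensor import conv2d, Tensor as T
        w = T(np.full((1, 1, 1, 1), 2.0, np.float32), requires_grad=True)
        feats = conv2d(x, w)
        return feats, feats.sum()


def test_gradcam_linear_model_peaks_at_input_maximum():
    g = np.random.default_rng(0)
    img = g.integers(0, 180, (12, 12, 3)).astype(np.uint8)
    img[7, 3] = 255                      # unique bright pixel
    cam = gradcam_pp(_LinearProbe(), img, class_id=0)
    assert np.unravel_index(cam.argmax(), cam.shape) == (7, 3)
    assert cam[7, 3] == pytest.approx(1.0)


class TestGradCAM:
    def test_output_range_and_shape(self, tiny_model, small_scenes):
        img = small_scenes[0].pixels[:160, :160]
        cam = gradcam_pp(tiny_model, img, class_id=0)
        assert cam.shape == (160, 160)
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_invariant_to_uniform_logit_rescaling(self, tiny_model, small_scenes):
        img = small_scenes[1].pixels[:160, :160]
        cam1 = gradcam_pp(tiny_model, img, class_id=2)
        for lyr in tiny_model.head.cls_convs:
            lyr.weight.data *= 3.0
            lyr.bias.data *= 3.0
        try:
            cam2 = gradcam_pp(tiny_model, img, class_id=2)
        finally:
            for lyr in tiny_model.head.cls_convs:
                lyr.weight.data /= 3.0
                lyr.bias.data /= 3.0
        # heat concentrates at the same argmax either way
        assert np.unravel_index(cam1.argmax(), cam1.shape) \
            == np.unravel_index(cam2.argmax(), cam2.shape)
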