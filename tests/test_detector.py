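"""Detector scaffold: shapes, assignment, loss, decoding, training."""

import numpy as np
import pytest

from organodet.autodiff import Tensor
from organodet.detector import (DetectorConfig, TrainSchedule, assign_targets,
                                build_detector, decode_and_nms, detection_loss,
                                level_points, load_detector, nms,
                                save_detector, train)
from organodet.head import HeadOutputs
from organodet.synthdata import AnnotatedScene, SceneSpec, render_scene
from organodet.types import ConfigError, GroundTruth, ShapeError

from oracles import brute_assign, brute_nms


def _small_cfg(**over):
    base = dict(neck_channels=8, backbone_widths=(4, 8, 8, 8, 8),
                kernel_size=5, heads=2)
    base.update(over)
    return DetectorConfig(**base)


def _bce(logit, target):
    return max(logit, 0) - logit * target + np.log1p(np.exp(-abs(logit)))


class TestBuildDetector:
    def test_seeded_initialisation_is_reproducible(self):
        a = build_detector(_small_cfg(), seed=3)
        b = build_detector(_small_cfg(), seed=3)
        for (na, pa), (nb, pb) in zip(sorted(a.named_parameters()),
                                      sorted(b.named_parameters())):
            assert na == nb and np.array_equal(pa.data, pb.data)
        c = build_detector(_small_cfg(), seed=4)
        assert any(not np.array_equal(pa.data, pc.data)
                   for (_, pa), (_, pc) in zip(sorted(a.named_parameters()),
                                               sorted(c.named_parameters())))

    def test_pyramid_spatial_sizes_follow_strides(self):
        det = build_detector(_small_cfg(), seed=0)
        outs = det.forward_np(np.zeros((1, 1, 256, 256), dtype=np.float32))
        assert [o.cls.shape[-1] for o in outs] == [32, 16, 8]

    def test_class_channels_match_config(self):
        det = build_detector(_small_cfg(num_classes=4), seed=0)
        outs = det.forward_np(np.zeros((1, 1, 64, 64), dtype=np.float32))
        assert all(o.cls.shape[1] == 4 for o in outs)
        assert all(o.reg.shape[1] == 4 for o in outs)

    def test_shape_contract_for_any_multiple_of_max_stride(self):
        det = build_detector(_small_cfg(), seed=0)
        for side in (32, 96, 160):
            outs = det.forward_np(np.zeros((1, 1, side, side), dtype=np.float32))
            assert [o.cls.shape[-1] for o in outs] == [side // 8, side // 16,
                                                       side // 32]
        with pytest.raises(ShapeError):
            det.forward_np(np.zeros((1, 1, 48, 48), dtype=np.float32))

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            _small_cfg(strides=(8, 16, 24))
        with pytest.raises(ConfigError):
            _small_cfg(backbone_widths=(4, 8))
        with pytest.raises(ConfigError):
            _small_cfg(head_type="hydra")


class TestAssignment:
    def test_empty_image_is_all_background(self):
        pts = level_points(_small_cfg(), (64, 64))
        for labels, _ in assign_targets(pts, []):
            assert np.all(labels == -1)

    def test_centered_box_claims_its_point(self):
        cfg = _small_cfg()
        pts = level_points(cfg, (64, 64))
        # a 20px box -> level 0 (size < 8*8); covers points around its centre
        gt = GroundTruth((22.0, 22.0, 42.0, 42.0), 2)
        out = assign_targets(pts, [gt])
        labels0, boxes0 = out[0]
        p0 = pts[0][0]
        inside = ((p0[:, 0] >= 22) & (p0[:, 0] < 42)
                  & (p0[:, 1] >= 22) & (p0[:, 1] < 42))
        assert np.all(labels0[inside] == 2)
        assert np.all(boxes0[inside] == np.array(gt.box))
        assert np.all(labels0[~inside] == -1)
        assert all(np.all(l == -1) for l, _ in out[1:])

    def test_tiny_box_gets_nearest_point_fallback(self):
        cfg = _small_cfg()
        pts = level_points(cfg, (64, 64))
        # 2px box between grid points: no centre is inside -> fallback
        gt = GroundTruth((8.2, 8.2, 10.2, 10.2), 1)
        out = assign_targets(pts, [gt])
        labels0, _ = out[0]
        assert (labels0 == 1).sum() == 1

    def test_random_scene_matches_brute_force_rule(self, rng):
        cfg = _small_cfg()
        pts = level_points(cfg, (128, 128))
        for _ in range(5):
            gts = []
            for _ in range(5):
                x, y = rng.uniform(0, 100, 2)
                w, h = rng.uniform(4, 100, 2)
                gts.append(GroundTruth((x, y, min(x + w, 128), min(y + h, 128)),
                                       int(rng.integers(0, 4))))
            mine = assign_targets(pts, gts)
            ref = brute_assign([p for p, _ in pts], gts, [s for _, s in pts])
            for (labels, boxes), owners, (p, _) in zip(mine, ref, pts):
                want = np.where(owners >= 0,
                                [gts[o].label if o >= 0 else -1 for o in owners],
                                -1)
                assert np.array_equal(labels, want)

    def test_every_gt_assigned_at_least_one_point(self, rng):
        cfg = _small_cfg()
        pts = level_points(cfg, (128, 128))
        gts = [GroundTruth((1.0, 1.0, 3.0, 3.0), 0),
               GroundTruth((1.5, 1.5, 3.5, 3.5), 1),
               GroundTruth((100.0, 100.0, 127.0, 127.0), 2)]
        out = assign_targets(pts, gts)
        assigned_boxes = set()
        for labels, boxes in out:
            for l, b in zip(labels, boxes):
                if l >= 0:
                    assigned_boxes.add(tuple(b))
        assert assigned_boxes == {g.box for g in gts}


class TestLoss:
    def _outputs(self, cfg, hw, cls_val=-9.0, reg_fill=0.0):
        pts = level_points(cfg, hw)
        outs = []
        for p, s in pts:
            n = len(p)
            side = int(np.sqrt(n))
            cls = np.full((1, cfg.num_classes, side, side), cls_val, np.float32)
            reg = np.full((1, 4, side, side), reg_fill, np.float32)
            outs.append((Tensor(cls), Tensor(reg)))
        return outs, pts

    def test_no_positives_gives_zero_box_term(self):
        cfg = _small_cfg()
        outs, pts = self._outputs(cfg, (64, 64))
        targets = [assign_targets(pts, [])]
        loss = detection_loss(outs, targets, pts, cfg.num_classes)
        assert loss.box_term == 0.0 and loss.n_pos == 0
        assert loss.cls_term > 0 and float(loss.total.data) == loss.cls_term

    def test_perfect_predictions_zero_box_term(self):
        """Feed targets back: saturated logits and exact distances."""
        cfg = _small_cfg()
        gt = GroundTruth((16.0, 16.0, 48.0, 48.0), 1)
        pts = level_points(cfg, (64, 64))
        targets = assign_targets(pts, [gt])
        outs = []
        for (p, s), (labels, boxes) in zip(pts, targets):
            side = int(np.sqrt(len(p)))
            cls = np.full((1, cfg.num_classes, side, side), -30.0, np.float32)
            reg = np.zeros((1, 4, side, side), np.float32)
            for i in np.nonzero(labels >= 0)[0]:
                y, x = divmod(i, side)
                cls[0, labels[i], y, x] = 30.0
                px, py = p[i]
                d = np.array([px - boxes[i][0], py - boxes[i][1],
                              boxes[i][2] - px, boxes[i][3] - py])
                reg[0, :, y, x] = np.log(d / s)
            outs.append((Tensor(cls), Tensor(reg)))
        loss = detection_loss(outs, [targets], pts, cfg.num_classes)
        assert loss.box_term <= 1e-5
        assert loss.cls_term <= 1e-8

    def test_toy_loss_equals_hand_computed_scalar_arithmetic(self):
        """One positive point, one background point, single level."""
        cfg = DetectorConfig(num_classes=2, strides=(8, 16, 32),
                             neck_channels=8, backbone_widths=(4, 4, 4, 4, 8),
                             kernel_size=5, heads=2)
        pts = [(np.array([[4.0, 4.0], [12.0, 4.0]]), 8)]
        gt_box = (0.0, 0.0, 8.0, 8.0)
        labels = np.array([0, -1])
        boxes = np.array([gt_box, (0, 0, 1, 1)], dtype=float)
        cls = np.array([[[[0.3, -0.2]]], [[[0.1, 0.4]]]],
                       np.float32).reshape(1, 2, 1, 2)
        reg = np.zeros((1, 4, 1, 2), np.float32)
        outs = [(Tensor(cls), Tensor(reg))]
        loss = detection_loss(outs, [[(labels, boxes)]], pts, 2)
        # hand arithmetic: logits at point0 = (0.3, 0.1) target (1, 0);
        # point1 = (-0.2, 0.4) target (0, 0)
        bce = (_bce(0.3, 1) + _bce(0.1, 0) + _bce(-0.2, 0) + _bce(0.4, 0))
        # decoded box at point0: exp(0)*8 = 8 each side -> (-4,-4,12,12)
        inter = 8 * 8
        union = 16 * 16 + 8 * 8 - inter
        want = bce / 1 + (1 - inter / (union + 1e-9)) / 1
        assert abs(float(loss.total.data) - want) <= 1e-6
        assert loss.n_pos == 1

    def test_nan_input_is_reported_with_component(self):
        cfg = _small_cfg()
        outs, pts = self._outputs(cfg, (64, 64))
        outs[0][1].data[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="regression"):
            detection_loss(outs, [assign_targets(pts, [])], pts, cfg.num_classes)


class TestDecodeAndNMS:
    def test_duplicate_boxes_same_class_one_survivor(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.0]])
        scores = np.array([0.9, 0.8])
        assert nms(boxes, scores, 0.5) == [0]

    def test_identical_boxes_different_classes_both_survive(self):
        cfg = _small_cfg(score_threshold=0.5)
        pts = level_points(cfg, (64, 64))
        outs = []
        for p, s in pts:
            side = int(np.sqrt(len(p)))
            cls = np.full((1, cfg.num_classes, side, side), -30.0, np.float32)
            reg = np.zeros((1, 4, side, side), np.float32)
            outs.append(HeadOutputs(cls=cls, reg=reg))
        outs[0].cls[0, 0, 2, 2] = 5.0
        outs[0].cls[0, 3, 2, 2] = 4.0
        dets = decode_and_nms(outs, cfg, (64, 64))
        assert len(dets) == 2
        assert {d.label for d in dets} == {0, 3}
        assert dets[0].score >= dets[1].score

    def test_random_boxes_match_brute_force_suppression(self, rng):
        for _ in range(5):
            n = 50
            xy = rng.uniform(0, 80, (n, 2))
            wh = rng.uniform(5, 30, (n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1)
            scores = rng.uniform(size=n)
            assert nms(boxes, scores, 0.5) == brute_nms(boxes, scores, 0.5)

    def test_nms_stable_under_equal_score_ties(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [40, 40, 50, 50.0]])
        scores = np.array([0.7, 0.7, 0.7])
        assert nms(boxes, scores, 0.3) == [0, 2]  # lower index wins the tie

    def test_decoded_boxes_lie_inside_canvas(self, rng):
        cfg = _small_cfg(score_threshold=0.0)
        det = build_detector(cfg, seed=1)
        img = rng.uniform(0, 1, (1, 1, 64, 64)).astype(np.float32)
        dets = decode_and_nms(det.forward_np(img), cfg, (64, 64))
        for d in dets:
            x1, y1, x2, y2 = d.box
            assert 0 <= x1 < x2 <= 64 and 0 <= y1 < y2 <= 64


def _tiny_dataset(n=8, size=64, seed0=100):
    spec = lambda s: SceneSpec(image_size=(size, size), n_instances=(1, 3),
                               radius_range=(4.0, 12.0), seed=s)
    return [render_scene(spec(seed0 + i)) for i in range(n)]


class TestTraining:
    def test_one_epoch_runs_and_logs_history(self):
        det = build_detector(_small_cfg(), seed=0)
        hist = train(det, _tiny_dataset(8), TrainSchedule(epochs=1, batch_size=4))
        assert len(hist) == 1
        assert set(hist[0]) == {"epoch", "loss", "cls", "box"}
        assert np.isfinite(hist[0]["loss"])

    def test_empty_dataset_rejected(self):
        det = build_detector(_small_cfg(), seed=0)
        with pytest.raises(ValueError):
            train(det, [], TrainSchedule(epochs=1))

    def test_save_load_round_trip_reproduces_outputs(self, tmp_path):
        det = build_detector(_small_cfg(), seed=0)
        train(det, _tiny_dataset(4), TrainSchedule(epochs=1, batch_size=4))
        p = save_detector(det, tmp_path / "w.npz")
        det2 = load_detector(p)
        x = np.zeros((1, 1, 64, 64), dtype=np.float32)
        x[0, 0, 20:40, 20:40] = 1.0
        a = det.forward_np(x)
        b = det2.forward_np(x)
        for oa, ob in zip(a, b):
            assert np.array_equal(oa.cls, ob.cls)
            assert np.array_equal(oa.reg, ob.reg)

    def test_loss_decreases_across_seeds(self):
        """Optimisation sanity: final-epoch mean loss below first-epoch."""
        data = _tiny_dataset(12)
        for seed in (0, 1, 2):
            det = build_detector(_small_cfg(), seed=seed)
            hist = train(det, data, TrainSchedule(epochs=4, batch_size=4,
                                                  seed=seed))
            assert hist[-1]["loss"] < hist[0]["loss"]

    def test_plain_head_variant_also_trains(self):
        det = build_detector(_small_cfg(head_type="plain"), seed=0)
        hist = train(det, _tiny_dataset(12), TrainSchedule(epochs=4, batch_size=4))
        assert hist[-1]["loss"] < hist[0]["loss"]
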