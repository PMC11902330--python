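"""Loss assembly, assignment, optimizer, and training-loop contracts."""

import numpy as np
import pytest

from gpcyolo.boxes import Box, eiou_loss
from gpcyolo.network import build_model, variant_config
from gpcyolo.nn.tensor import Tensor
from gpcyolo.train import (SGD, TrainConfig, ciou_loss_xyxy, detection_loss,
                           eiou_loss_xyxy, prepare_samples,
                           task_aligned_assign, train)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(variant_config("gpc", input_size=64), seed=0)


def _targets():
    return [np.array([[0, .5, .5, .4, .4], [1, .2, .3, .2, .2]], dtype=np.float32),
            np.array([[2, .6, .6, .3, .3]], dtype=np.float32)]


def _loss(tiny_model, cfg, targets=None, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.random((2, 3, 64, 64), dtype=np.float32)
    tiny_model.train()
    outs = tiny_model(x)
    return detection_loss(outs, targets if targets is not None else _targets(),
                          cfg, tiny_model.strides, 3)


class TestPairwiseLosses:
    def test_identity_gives_zero_loss_and_zero_gradient(self):
        """At a perfect prediction the EIoU loss and all four coordinate
        gradients vanish."""
        g = np.array([[10.0, 20.0, 40.0, 50.0]], dtype=np.float32)
        t = Tensor(g.copy(), requires_grad=True)
        loss = eiou_loss_xyxy(t, g).sum()
        assert loss.item() == pytest.approx(0.0, abs=1e-6)
        loss.backward()
        # analytic gradient at the optimum
        np.testing.assert_allclose(t.grad, 0.0, atol=1e-4)
        # finite differences agree
        for k in range(4):
            e = 1e-2
            gp, gm = g.copy(), g.copy()
            gp[0, k] += e
            gm[0, k] -= e
            num = (eiou_loss_xyxy(Tensor(gp), g).data.sum()
                   - eiou_loss_xyxy(Tensor(gm), g).data.sum()) / (2 * e)
            assert num == pytest.approx(0.0, abs=5e-2)

    def test_matches_scalar_implementation(self, rng):
        P = rng.uniform(0, 60, (100, 4)).astype(np.float32)
        P[:, 2:] += P[:, :2]
        G = rng.uniform(0, 60, (100, 4)).astype(np.float32)
        G[:, 2:] += G[:, :2] + 1.0
        ev = eiou_loss_xyxy(Tensor(P), G).data

        def to_box(r):
            return Box((r[0] + r[2]) / 2, (r[1] + r[3]) / 2,
                       r[2] - r[0], r[3] - r[1])

        ref = [eiou_loss(to_box(p), to_box(g)) for p, g in zip(P, G)]
        np.testing.assert_allclose(ev, ref, atol=1e-5)

    def test_disjoint_worked_pair(self):
        p = np.array([[-1.0, -1.0, 1.0, 1.0]], dtype=np.float32)
        g = np.array([[3.0, -1.0, 5.0, 1.0]], dtype=np.float32)
        assert eiou_loss_xyxy(Tensor(p), g).data[0] == pytest.approx(1.4, rel=1e-5)
        assert ciou_loss_xyxy(Tensor(p), g).data[0] == pytest.approx(1.4, rel=1e-5)


class TestAssignment:
    def test_anchors_inside_box_are_assigned_to_it(self):
        pts = np.array([[8.0, 8.0], [24.0, 8.0], [100.0, 100.0]], dtype=np.float32)
        scores = np.full((1, 3, 3), 0.5, dtype=np.float32)
        pred = np.tile(np.array([0, 0, 16, 16], np.float32), (1, 3, 1))
        pred[0, 1] = [16, 0, 32, 16]
        gt = [np.array([[0.0, 0.0, 32.0, 16.0]], dtype=np.float32)]
        asg = task_aligned_assign(scores, pred, pts, gt, [np.array([1])], 3)
        assert asg.fg_mask[0, 0] and asg.fg_mask[0, 1]
        assert not asg.fg_mask[0, 2]
        np.testing.assert_array_equal(asg.target_boxes[0, 0], gt[0][0])
        assert 0.0 <= asg.target_scores.max() <= 1.0
        assert asg.target_scores[0, 0].argmax() == 1

    def test_no_objects_yields_empty_foreground(self):
        pts = np.array([[8.0, 8.0]], dtype=np.float32)
        asg = task_aligned_assign(np.full((1, 1, 3), 0.5, np.float32),
                                  np.zeros((1, 1, 4), np.float32), pts,
                                  [np.zeros((0, 4), np.float32)],
                                  [np.zeros(0, int)], 3)
        assert not asg.fg_mask.any()
        assert asg.target_scores.sum() == 0


class TestDetectionLoss:
    def test_all_terms_finite_and_composition_linear(self, tiny_model):
        cfg = TrainConfig(input_size=64, epochs=1)
        total, b, c, d = _loss(tiny_model, cfg)
        assert np.isfinite([total.item(), b, c, d]).all()
        assert total.item() == pytest.approx(7.5 * b + 0.5 * c + 1.5 * d, rel=1e-5)
        cfg0 = TrainConfig(input_size=64, epochs=1, loss_weights=(0.0, 1.0, 0.0))
        total0, b0, c0, d0 = _loss(tiny_model, cfg0)
        assert (b0, d0) == (b, d)  # term values unchanged, only the mix
        assert total0.item() == pytest.approx(c0, rel=1e-5)

    def test_swapping_iou_type_touches_only_the_box_term(self, tiny_model):
        te = _loss(tiny_model, TrainConfig(input_size=64, epochs=1))
        tc = _loss(tiny_model, TrainConfig(input_size=64, epochs=1,
                                           iou_type="ciou"))
        assert te[2] == pytest.approx(tc[2], rel=1e-6)  # cls identical
        assert te[3] == pytest.approx(tc[3], rel=1e-6)  # dfl identical
        assert te[1] != pytest.approx(tc[1], rel=1e-6)  # box differs

    def test_no_positive_assignments(self, tiny_model):
        cfg = TrainConfig(input_size=64, epochs=1)
        empty = [np.zeros((0, 5), np.float32), np.zeros((0, 5), np.float32)]
        total, b, c, d = _loss(tiny_model, cfg, targets=empty)
        assert b == 0.0 and d == 0.0 and c > 0.0
        assert np.isfinite(total.item())


class TestOptimizerAndLoop:
    def test_sgd_single_step_arithmetic(self):
        from gpcyolo.nn.tensor import Parameter

        w = Parameter(np.ones((2, 2), dtype=np.float32))
        b = Parameter(np.ones(2, dtype=np.float32))
        opt = SGD([w, b], lr=0.1, momentum=0.5, weight_decay=0.01)
        w.grad = np.full((2, 2), 2.0, np.float32)
        b.grad = np.full(2, 2.0, np.float32)
        opt.step()
        # weight decay applies to the matrix only
        np.testing.assert_allclose(w.data, 1 - 0.1 * (2.0 + 0.01))
        np.testing.assert_allclose(b.data, 1 - 0.1 * 2.0)
        w.grad = np.zeros((2, 2), np.float32)
        b.grad = np.zeros(2, np.float32)
        opt.step()  # momentum keeps moving
        np.testing.assert_allclose(b.data, 1 - 0.1 * 2.0 - 0.1 * 0.5 * 2.0)

    def test_one_epoch_is_deterministic_given_seed(self, tiny_scenes):
        ds = [(img, np.array([[b.class_id, b.cx, b.cy, b.w, b.h]
                              for b in li.boxes], dtype=np.float32))
              for li, img in tiny_scenes[:2]]
        losses = []
        for _ in range(2):
            model = build_model(variant_config("gpc", input_size=64), seed=0)
            cfg = TrainConfig(batch_size=2, epochs=1, input_size=64, seed=0)
            recs = train(model, ds, cfg)
            losses.append(recs[0]["loss"])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_training_never_mutates_the_input_samples(self, tiny_scenes):
        li, img = tiny_scenes[0]
        labels = np.array([[b.class_id, b.cx, b.cy, b.w, b.h]
                           for b in li.boxes], dtype=np.float32)
        img_copy, lab_copy = img.copy(), labels.copy()
        model = build_model(variant_config("gpc", input_size=64), seed=0)
        train(model, [(img, labels)], TrainConfig(batch_size=1, epochs=1,
                                                  input_size=64, seed=0))
        np.testing.assert_array_equal(img, img_copy)
        np.testing.assert_array_equal(labels, lab_copy)

    def test_empty_dataset_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            train(tiny_model, [], TrainConfig(epochs=1, input_size=64))

    def test_checkpoints_and_log_written(self, tiny_scenes, tmp_path):
        ds = [(img, np.array([[b.class_id, b.cx, b.cy, b.w, b.h]
                              for b in li.boxes], dtype=np.float32))
              for li, img in tiny_scenes[:2]]
        model = build_model(variant_config("gpc", input_size=64), seed=0)
        train(model, ds, TrainConfig(batch_size=2, epochs=2, input_size=64,
                                     seed=0), out_dir=tmp_path)
        assert (tmp_path / "last.npz").exists()
        assert (tmp_path / "best.npz").exists()
        lines = (tmp_path / "train_log.jsonl").read_text().strip().splitlines()
        assert len(lines) == 2


def test_prepare_samples_letterboxes_labels_consistently(rng):
    img = (rng.random((60, 120, 3)) * 255).astype(np.uint8)
    labels = np.array([[0, 0.5, 0.5, 0.5, 0.5]], dtype=np.float32)
    (x, lab), = prepare_samples([(img, labels)], 64)
    assert x.shape == (3, 64, 64)
    # a centered box stays centered; width scales by r=64/120, height pads
    assert lab[0, 1] == pytest.approx(0.5, abs=0.02)
    assert lab[0, 2] == pytest.approx(0.5, abs=0.02)
    assert lab[0, 3] == pytest.approx(0.5, abs=0.02)
    assert lab[0, 4] == pytest.approx(0.5 * 60 * (64 / 120) / 64, abs=0.02)
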