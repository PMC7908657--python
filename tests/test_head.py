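"""Center-point head: target rendering, focal/L1 loss, decoding."""

import numpy as np
import pytest

from mitodet.geometry import Box
from mitodet.head import (
    CenterHead,
    HeadConfig,
    HeadOutput,
    STRIDE,
    decode,
    detection_loss,
    gaussian_radius,
    render_targets,
)
from mitodet.nn import Adam, Tensor


class TestRenderTargets:
    def test_single_box_single_peak(self):
        maps = render_targets([Box(cx=30, cy=22, w=8, h=8)], (16, 16))
        assert (maps.heatmap == 1.0).sum() == 1
        assert maps.center_mask.sum() == 1
        py, px = np.argwhere(maps.center_mask[0])[0]
        assert (px, py) == (30 // STRIDE, 22 // STRIDE)
        assert tuple(maps.size_map[:, py, px]) == (8, 8)
        np.testing.assert_allclose(
            maps.offset_map[:, py, px], (30 / 4 - 7, 22 / 4 - 5)
        )

    def test_empty_annotations_zero_maps(self):
        maps = render_targets([], (8, 8))
        assert not maps.heatmap.any()
        assert not maps.center_mask.any()

    def test_duplicate_boxes_idempotent_under_max(self):
        one = render_targets([Box(cx=20, cy=20, w=10, h=6)], (16, 16))
        two = render_targets([Box(cx=20, cy=20, w=10, h=6)] * 2, (16, 16))
        np.testing.assert_array_equal(one.heatmap, two.heatmap)
        np.testing.assert_array_equal(one.size_map, two.size_map)

    def test_offmap_boxes_skipped_with_count(self):
        maps = render_targets([Box(cx=500, cy=500, w=4, h=4)], (16, 16))
        assert maps.n_skipped == 1
        assert not maps.heatmap.any()

    def test_gaussian_radius_shrinks_with_overlap(self):
        r_strict = gaussian_radius(10, 10, min_overlap=0.9)
        r_loose = gaussian_radius(10, 10, min_overlap=0.5)
        assert 0 < r_strict < r_loose


class TestDetectionLoss:
    @staticmethod
    def _raw_from_targets(maps, sharp=12.0):
        """Raw head outputs whose activation approximates the targets."""
        logits = sharp * (maps.heatmap[None] - 0.5)
        return {
            "heatmap": Tensor(logits, requires_grad=True),
            "size": Tensor(maps.size_map[None], requires_grad=True),
            "offset": Tensor(maps.offset_map[None], requires_grad=True),
        }

    def test_loss_approaches_zero_at_the_target(self):
        maps = render_targets([Box(cx=30, cy=22, w=8, h=8)], (16, 16))
        losses = []
        for sharp in (8.0, 16.0, 32.0):
            raw = self._raw_from_targets(maps, sharp)
            loss, _ = detection_loss(raw, [maps])
            losses.append(float(loss.data))
        assert losses[0] > losses[1] > losses[2]
        assert losses[-1] < 0.05

    def test_nonnegative_on_random_inputs(self, rng):
        maps = render_targets([Box(cx=10, cy=10, w=6, h=6)], (8, 8))
        raw = {
            "heatmap": Tensor(rng.normal(size=(1, 1, 8, 8))),
            "size": Tensor(rng.normal(size=(1, 2, 8, 8))),
            "offset": Tensor(rng.normal(size=(1, 2, 8, 8))),
        }
        loss, parts = detection_loss(raw, [maps])
        assert float(loss.data) >= 0.0
        assert parts["focal"] >= 0.0

    def test_focal_term_matches_scalar_arithmetic(self):
        """Single-cell toy map: the focal value equals the hand-computed
        penalty-reduced focal formula with alpha=2, beta=4."""
        maps = render_targets([Box(cx=2, cy=2, w=4, h=4)], (1, 1))
        # one cell, which is the peak: pure positive term
        logit = 0.7
        p = 1 / (1 + np.exp(-logit))
        raw = {
            "heatmap": Tensor(np.full((1, 1, 1, 1), logit)),
            "size": Tensor(maps.size_map[None]),
            "offset": Tensor(maps.offset_map[None]),
        }
        _, parts = detection_loss(raw, [maps])
        expected = -((1 - p) ** 2) * np.log(p)  # n_pos = 1
        assert parts["focal"] == pytest.approx(expected, rel=1e-9)

    def test_background_only_frame_contributes_negative_term(self):
        maps = render_targets([], (4, 4))
        logit = -1.3
        p = 1 / (1 + np.exp(-logit))
        raw = {
            "heatmap": Tensor(np.full((1, 1, 4, 4), logit)),
            "size": Tensor(np.zeros((1, 2, 4, 4))),
            "offset": Tensor(np.zeros((1, 2, 4, 4))),
        }
        _, parts = detection_loss(raw, [maps])
        expected = -16 * (p**2) * np.log(1 - p)  # beta-weight is 1 off-peak
        assert parts["focal"] == pytest.approx(expected, rel=1e-9)
        assert parts["size_l1"] == 0.0

    def test_shape_mismatch_raises(self):
        maps = render_targets([], (4, 4))
        raw = {
            "heatmap": Tensor(np.zeros((1, 1, 8, 8))),
            "size": Tensor(np.zeros((1, 2, 8, 8))),
            "offset": Tensor(np.zeros((1, 2, 8, 8))),
        }
        with pytest.raises(ValueError):
            detection_loss(raw, [maps])

    def test_one_gradient_step_reduces_loss(self, rng):
        head = CenterHead(6, HeadConfig(hidden_channels=8), rng)
        features = Tensor(rng.normal(size=(1, 6, 8, 8)))
        maps = render_targets([Box(cx=12, cy=12, w=8, h=8)], (8, 8))
        opt = Adam(head.parameters(), lr=1e-2)
        raw = head.raw(features)
        loss0, _ = detection_loss(raw, [maps])
        loss0.backward()
        opt.step()
        loss1, _ = detection_loss(head.raw(features), [maps])
        assert float(loss1.data) < float(loss0.data)


def _decode_oracle(heat, score_min, k_max):
    """Exhaustive scan for 3x3-maximal cells, sorted by score."""
    h, w = heat.shape
    peaks = []
    for y in range(h):
        for x in range(w):
            v = heat[y, x]
            if v < score_min:
                continue
            neigh = heat[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
            if v >= neigh.max():
                peaks.append((y, x, v))
    peaks.sort(key=lambda p: (-p[2], p[0], p[1]))
    return peaks[:k_max]


class TestDecode:
    @staticmethod
    def _output(heat, size=None, offset=None):
        h, w = heat.shape
        return HeadOutput(
            heatmap=heat[None, None],
            size_map=np.zeros((1, 2, h, w)) if size is None else size[None],
            offset_map=np.zeros((1, 2, h, w)) if offset is None else offset[None],
        )

    def test_single_peak_arithmetic(self):
        heat = np.zeros((16, 16))
        heat[5, 4] = 1.0  # (py=5, px=4)
        size = np.zeros((2, 16, 16))
        size[0], size[1] = 8.0, 12.0
        det = decode(self._output(heat, size=size))
        assert len(det) == 1
        b = det.boxes[0]
        assert (b.cx, b.cy, b.w, b.h, b.p) == (16.0, 20.0, 8.0, 12.0, 1.0)

    def test_all_zero_heatmap_empty(self):
        det = decode(self._output(np.zeros((8, 8))))
        assert len(det) == 0

    def test_offset_moves_subpixel(self):
        heat = np.zeros((8, 8))
        heat[2, 3] = 0.9
        size = np.full((2, 8, 8), 6.0)
        offset = np.zeros((2, 8, 8))
        offset[0, 2, 3] = 0.25
        offset[1, 2, 3] = -0.5
        b = decode(self._output(heat, size=size, offset=offset)).boxes[0]
        assert (b.cx, b.cy) == (4 * 3.25, 4 * 1.5)

    def test_matches_exhaustive_peak_scan(self, rng):
        cfg = HeadConfig(score_min=0.3, k_max=10)
        for _ in range(25):
            heat = rng.uniform(size=(12, 12))
            size = np.full((2, 12, 12), 5.0)
            det = decode(self._output(heat, size=size), config=cfg)
            oracle = _decode_oracle(heat, cfg.score_min, cfg.k_max)
            assert len(det) == len(oracle)
            got = {(round(b.cy / 4 - 0.0, 6), round(b.cx / 4, 6)) for b in det.boxes}
            assert got == {(float(y), float(x)) for y, x, _ in oracle}

    def test_respects_k_max_and_score_min(self, rng):
        heat = rng.uniform(0.5, 1.0, size=(12, 12))
        size = np.full((2, 12, 12), 5.0)
        det = decode(self._output(heat, size=size), k_max=3, score_min=0.6)
        assert len(det) <= 3
        assert all(b.p >= 0.6 for b in det.boxes)


class TestRenderDecodeConsistency:
    def test_recovers_annotations_on_random_frames(self, rng):
        """Decoding rendered targets recovers every box: center error
        <= 0.5 px and exact sizes, across 50 random frames."""
        for _ in range(50):
            n = int(rng.integers(1, 4))
            boxes = []
            for _ in range(n):
                cand = Box(
                    cx=float(rng.uniform(8, 56)),
                    cy=float(rng.uniform(8, 56)),
                    w=float(rng.uniform(5, 14)),
                    h=float(rng.uniform(5, 14)),
                )
                # keep peak cells distinct so recoveries are unambiguous
                if all(
                    (int(cand.cx / 4) - int(b.cx / 4)) ** 2
                    + (int(cand.cy / 4) - int(b.cy / 4)) ** 2
                    > 2
                    for b in boxes
                ):
                    boxes.append(cand)
            maps = render_targets(boxes, (16, 16))
            pred = HeadOutput(
                heatmap=maps.heatmap[None],
                size_map=maps.size_map[None],
                offset_map=maps.offset_map[None],
            )
            det = decode(pred, score_min=0.99, k_max=10)
            assert len(det) == len(boxes)
            for b in boxes:
                best = min(
                    det.boxes,
                    key=lambda d: (d.cx - b.cx) ** 2 + (d.cy - b.cy) ** 2,
                )
                assert abs(best.cx - b.cx) <= 0.5
                assert abs(best.cy - b.cy) <= 0.5
                assert best.w == b.w and best.h == b.h
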