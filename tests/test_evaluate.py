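"""2D and 4D detection metrics."""

from dataclasses import replace

import pytest

from mitodet.evaluate import composite_score, evaluate_2d, evaluate_4d
from mitodet.geometry import Box


def _plane(boxes, t=0, s=0, **kw):
    return [replace(b, t=t, s=s, **kw) for b in boxes]


class TestEvaluate2D:
    def test_perfect_detections(self):
        anns = [
            Box(cx=10, cy=10, w=6, h=6, t=0, s=0, event_id=0),
            Box(cx=30, cy=30, w=8, h=8, t=0, s=1, event_id=0),
        ]
        dets = [replace(b, event_id=None, p=0.9) for b in anns]
        r = evaluate_2d(dets, anns)
        assert (r.tp, r.fp, r.fn) == (2, 0, 0)
        assert r.precision == r.recall == r.score_mean == 1.0

    def test_no_detections_degenerate_convention(self):
        anns = [Box(cx=10, cy=10, w=6, h=6)]
        r = evaluate_2d([], anns)
        assert (r.precision, r.recall) == (0.0, 0.0)
        assert r.score_harmonic == 0.0

    def test_hand_built_confusion_counts(self):
        # 2 TP, 1 FP, 1 FN by construction
        anns = [
            Box(cx=10, cy=10, w=6, h=6),
            Box(cx=30, cy=30, w=6, h=6),
            Box(cx=50, cy=50, w=6, h=6),  # missed
        ]
        dets = [
            Box(cx=10, cy=10, w=6, h=6, p=0.9),
            Box(cx=30.5, cy=30, w=6, h=6, p=0.8),  # IoU ~ 0.85 > 0.6
            Box(cx=70, cy=10, w=6, h=6, p=0.7),  # spurious
        ]
        r = evaluate_2d(dets, anns)
        assert (r.tp, r.fp, r.fn) == (2, 1, 1)
        assert r.precision == pytest.approx(2 / 3)
        assert r.recall == pytest.approx(2 / 3)
        assert r.score_mean == pytest.approx(2 / 3)

    def test_threshold_is_strict(self):
        ann = [Box(cx=10, cy=10, w=10, h=10)]
        # shifted so IoU is exactly 0.6: inter 75x10... construct IoU = 0.6
        # boxes 10x10, shift x by 2.5: inter = 7.5*10 = 75, union 125, IoU 0.6
        det = [Box(cx=12.5, cy=10, w=10, h=10, p=0.9)]
        r = evaluate_2d(det, ann, iou_min=0.6)
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)  # "exceeds" means strictly

    def test_counts_partition_inputs(self, rng):
        anns = [
            Box(cx=float(rng.uniform(5, 60)), cy=float(rng.uniform(5, 60)),
                w=6, h=6, t=int(rng.integers(2)), s=int(rng.integers(2)))
            for _ in range(10)
        ]
        dets = [
            Box(cx=float(rng.uniform(5, 60)), cy=float(rng.uniform(5, 60)),
                w=6, h=6, t=int(rng.integers(2)), s=int(rng.integers(2)),
                p=float(rng.uniform(0.1, 1)))
            for _ in range(12)
        ]
        r = evaluate_2d(dets, anns)
        assert r.tp + r.fp == len(dets)
        assert r.tp + r.fn == len(anns)

    def test_matching_is_per_plane(self):
        ann = [Box(cx=10, cy=10, w=6, h=6, t=0, s=0)]
        det = [Box(cx=10, cy=10, w=6, h=6, t=0, s=1, p=0.9)]  # wrong slice
        r = evaluate_2d(det, ann)
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)


class TestCompositeScore:
    @pytest.mark.parametrize(
        "p,r,expected",
        [
            (0.0411, 0.7221, 0.3816),
            (0.7883, 0.7751, 0.7817),
            (0.8356, 0.8442, 0.8399),
        ],
    )
    def test_mean_convention_reproduces_reported_rows(self, p, r, expected):
        assert round(composite_score(p, r, "mean"), 4) == expected

    def test_harmonic_differs_for_unbalanced_rows(self):
        # P=0.0715, R=0.8933: the mean is ~0.4824 but harmonic F1 ~ 0.132
        mean = composite_score(0.0715, 0.8933, "mean")
        harm = composite_score(0.0715, 0.8933, "harmonic")
        assert round(mean, 4) == 0.4824
        assert harm == pytest.approx(0.1324, abs=5e-4)

    def test_symmetric_point(self):
        for conv in ("mean", "harmonic"):
            assert composite_score(0.7, 0.7, conv) == pytest.approx(0.7)

    def test_degenerate_harmonic(self):
        assert composite_score(0.0, 0.0, "harmonic") == 0.0


def _event(slices, t=0, cx=20.0, cy=20.0, w=8.0, h=8.0, event_id=0):
    return [
        Box(cx=cx, cy=cy, w=w, h=h, t=t, s=s, event_id=event_id) for s in slices
    ]


class TestEvaluate4D:
    def test_perfect_six_slice_event(self):
        anns = _event(range(6))
        dets = [replace(b, event_id=None, p=0.9) for b in anns]
        r = evaluate_4d(dets, anns)
        assert (r.tp, r.fn, r.fp) == (1, 0, 0)

    def test_three_slice_event_cannot_be_credited(self):
        anns = _event(range(3))
        dets = [replace(b, event_id=None, p=0.9) for b in anns]
        r = evaluate_4d(dets, anns)
        assert (r.tp, r.fn, r.fp) == (0, 1, 0)
        assert r.short_events == [0]

    def test_alternating_iou_event_plus_spurious_stack(self):
        """7-slice event detected with per-slice IoU alternating ~0.8/~0.6
        (mean > 0.5 on every 5-window) -> TP; an unrelated self-consistent
        5-slice stack -> FP."""
        anns = _event(range(7))
        dets = []
        for k, b in enumerate(anns):
            # shift alternately: 10x... box 8x8; shift dx chosen for IoU about
            # 0.8 (dx~0.888) and 0.6 (dx=2)
            dx = 0.89 if k % 2 == 0 else 2.0
            dets.append(Box(cx=b.cx + dx, cy=b.cy, w=8, h=8, t=0, s=b.s, p=0.9))
        # spurious far-away stack of 5 identical boxes
        dets += [Box(cx=50, cy=50, w=8, h=8, t=0, s=s, p=0.9) for s in range(5)]
        r = evaluate_4d(dets, anns)
        assert (r.tp, r.fn, r.fp) == (1, 0, 1)

    def test_low_overlap_everywhere_is_fn_not_fp(self):
        anns = _event(range(6))
        # detections overlap the truth a little, so the stack is not "free"
        # of ground truth, but the mean IoU never clears 0.5
        dets = [Box(cx=b.cx + 5, cy=b.cy, w=8, h=8, t=0, s=b.s, p=0.9)
                for b in anns]
        r = evaluate_4d(dets, anns)
        assert (r.tp, r.fn, r.fp) == (0, 1, 0)

    def test_order_and_frame_relabel_invariance(self):
        anns = _event(range(6), t=3) + _event(range(2, 9), t=5, cx=40, cy=40,
                                              event_id=1)
        dets = [replace(b, event_id=None, p=0.9) for b in anns]
        r_fwd = evaluate_4d(dets, anns)
        r_rev = evaluate_4d(list(reversed(dets)), anns)
        assert (r_fwd.tp, r_fwd.fn, r_fwd.fp) == (r_rev.tp, r_rev.fn, r_rev.fp) == (
            2, 0, 0
        )
        shifted_anns = [replace(b, t=b.t + 4) for b in anns]
        shifted_dets = [replace(b, t=b.t + 4) for b in dets]
        r_shift = evaluate_4d(shifted_dets, shifted_anns)
        assert (r_shift.tp, r_shift.fn, r_shift.fp) == (2, 0, 0)

    def test_requires_event_ids(self):
        with pytest.raises(ValueError):
            evaluate_4d([], [Box(cx=1, cy=1, w=2, h=2)])
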