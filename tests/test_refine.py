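"""Spatio-temporal confidence refinement: weights, agreement, filtering."""

import math
from dataclasses import replace

import numpy as np
import pytest

from mitodet.geometry import Box, DetectionSet
from mitodet.refine import (
    RefinementConfig,
    associate_neighbours,
    binarize,
    neighbour_weight,
    refine,
    refine_score,
)

CFG = RefinementConfig()  # N=4, T=6


def brute_force_refined(contributions, N, T):
    """Independent two-loop weighted mean with the distance-weight formula."""
    num = den = 0.0
    for j in range(-N, N + 1):
        for k in range(-T, T + 1):
            if (j, k) not in contributions:
                continue
            w = 1.0 - math.sqrt(j * j + k * k) / math.sqrt(N * N + T * T)
            num += w * contributions[(j, k)]
            den += w
    return num / den if den else contributions[(0, 0)]


class TestBinarize:
    @pytest.mark.parametrize("p,expected", [(0.5, 1), (0.49, 0), (1.0, 1), (0.0, 0)])
    def test_inclusive_threshold(self, p, expected):
        assert binarize(p, 0.5) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            binarize(1.2)


class TestNeighbourWeight:
    def test_center_and_corner(self):
        assert neighbour_weight(0, 0, 4, 6) == 1.0
        assert neighbour_weight(4, 6, 4, 6) == pytest.approx(0.0)

    def test_worked_value(self):
        assert neighbour_weight(3, 4, 4, 6) == pytest.approx(
            1 - 5 / math.sqrt(52), abs=1e-6
        )
        assert neighbour_weight(3, 4, 4, 6) == pytest.approx(0.306625, abs=1e-5)

    def test_symmetry_and_monotonicity_full_grid(self):
        for j in range(-4, 5):
            for k in range(-6, 7):
                w = neighbour_weight(j, k, 4, 6)
                assert 0.0 <= w <= 1.0 + 1e-12
                assert w == neighbour_weight(-j, k, 4, 6)
                assert w == neighbour_weight(j, -k, 4, 6)
                if j >= 0 and j < 4:
                    assert neighbour_weight(j + 1, k, 4, 6) <= w
                if k >= 0 and k < 6:
                    assert neighbour_weight(j, k + 1, 4, 6) <= w

    def test_out_of_window_raises(self):
        with pytest.raises(ValueError):
            neighbour_weight(5, 0, 4, 6)


class TestRefineScore:
    def test_all_ones_and_all_zeros(self):
        full = {
            (j, k): 1 for j in range(-4, 5) for k in range(-6, 7)
        }
        assert refine_score(full, CFG) == pytest.approx(1.0)
        zeros = {key: 0 for key in full}
        assert refine_score(zeros, CFG) == 0.0

    def test_toy_grid_matches_double_sum_oracle(self):
        cfg = RefinementConfig(N=1, T=1)
        grid = {
            (-1, -1): 1, (-1, 0): 1, (-1, 1): 0,
            (0, -1): 1, (0, 0): 1, (0, 1): 0,
            (1, -1): 0, (1, 0): 0, (1, 1): 0,
        }
        assert refine_score(grid, cfg) == pytest.approx(
            brute_force_refined(grid, 1, 1), rel=1e-12
        )

    def test_random_maps_match_oracle(self, rng):
        """>=100 random truncated contribution maps agree with the
        brute-force double sum to 1e-12 relative error."""
        for _ in range(120):
            contributions = {(0, 0): int(rng.integers(0, 2))}
            for j in range(-4, 5):
                for k in range(-6, 7):
                    if (j, k) != (0, 0) and rng.random() < 0.6:
                        contributions[(j, k)] = int(rng.integers(0, 2))
            got = refine_score(contributions, CFG)
            want = brute_force_refined(contributions, 4, 6)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)
            assert 0.0 <= got <= 1.0

    def test_monotone_in_agreeing_neighbours(self, rng):
        contributions = {(0, 0): 1, (1, 0): 0, (0, 1): 0, (2, 3): 0}
        base = refine_score(contributions, CFG)
        for key in [(1, 0), (0, 1), (2, 3)]:
            upgraded = dict(contributions)
            upgraded[key] = 1
            assert refine_score(upgraded, CFG) >= base

    def test_requires_center_cell(self):
        with pytest.raises(ValueError):
            refine_score({(1, 0): 1}, CFG)

    def test_degenerate_corner_only_map(self):
        cfg = RefinementConfig(N=1, T=0)
        # only the zero-weight corner besides nothing: falls back to own p-hat
        assert refine_score({(0, 0): 1}, RefinementConfig(N=4, T=6)) == 1.0


def _copies(box, offsets):
    out = []
    for j, k in offsets:
        out.append(replace(box, s=box.s + j, t=box.t + k))
    return out


class TestAssociateNeighbours:
    def test_identical_copies_everywhere_agree(self):
        target = Box(cx=20, cy=20, w=8, h=8, s=4, t=6, p=0.9)
        cfg = RefinementConfig(N=1, T=1)
        dets = DetectionSet(boxes=_copies(target, [(j, k) for j in (-1, 0, 1)
                                                   for k in (-1, 0, 1)]))
        contributions = associate_neighbours(target, dets, cfg)
        assert set(contributions) == {(j, k) for j in (-1, 0, 1) for k in (-1, 0, 1)}
        assert all(v == 1 for v in contributions.values())

    def test_isolated_target_all_zero_but_center(self):
        target = Box(cx=20, cy=20, w=8, h=8, s=4, t=6, p=0.9)
        dets = DetectionSet(boxes=[target])
        contributions = associate_neighbours(target, dets, CFG,
                                             n_slices=9, n_frames=13)
        assert contributions[(0, 0)] == 1
        assert sum(contributions.values()) == 1
        assert len(contributions) == 9 * 13

    def test_volume_boundary_truncates_window(self):
        target = Box(cx=20, cy=20, w=8, h=8, s=0, t=0, p=0.9)
        contributions = associate_neighbours(
            target, DetectionSet(boxes=[target]), CFG, n_slices=3, n_frames=4
        )
        assert set(contributions) == {
            (j, k) for j in range(0, 3) for k in range(0, 4)
        }

    def test_planted_toy_matches_hand_enumeration(self):
        """3-slice, 3-frame toy with hand-placed matches and a low-confidence
        neighbour; contribution table enumerated by hand."""
        cfg = RefinementConfig(N=1, T=1)
        target = Box(cx=10, cy=10, w=6, h=6, s=1, t=1, p=0.8)
        neighbours = [
            replace(target, s=0, t=1, p=0.9),  # match above, confident
            replace(target, s=2, t=1, p=0.3),  # match below, binarizes to 0
            replace(target, s=1, t=0, p=0.6),  # previous frame, confident
            Box(cx=40, cy=40, w=6, h=6, s=1, t=2, p=0.95),  # far: no match
        ]
        dets = DetectionSet(boxes=[target] + neighbours)
        contributions = associate_neighbours(target, dets, cfg,
                                             n_slices=3, n_frames=3)
        expected = {
            (0, 0): 1,
            (-1, 0): 1, (1, 0): 0, (0, -1): 1, (0, 1): 0,
            (-1, -1): 0, (-1, 1): 0, (1, -1): 0, (1, 1): 0,
        }
        assert contributions == expected


class TestRefine:
    def test_empty_input(self):
        kept, records = refine(DetectionSet(), CFG)
        assert len(kept) == 0 and records == []

    def test_persistent_detection_kept_at_full_score(self):
        base = Box(cx=20, cy=20, w=8, h=8, s=4, t=6, p=0.9)
        offsets = [(j, k) for j in range(-4, 5) for k in range(-6, 7)]
        dets = DetectionSet(boxes=_copies(base, offsets))
        kept, records = refine(dets, CFG, n_slices=9, n_frames=13)
        center = next(r for r in records if r.box == base)
        assert center.p_refined == pytest.approx(1.0)
        assert any(b.cx == base.cx for b in kept)

    def test_isolated_false_positive_removed(self):
        """A single-plane response has refined score W(0,0)/sum(W) << 0.5
        under the default window and is filtered out."""
        lone = Box(cx=20, cy=20, w=8, h=8, s=4, t=6, p=0.95)
        kept, records = refine(DetectionSet(boxes=[lone]), CFG,
                               n_slices=9, n_frames=13)
        weights = [
            neighbour_weight(j, k, 4, 6)
            for j in range(-4, 5)
            for k in range(-6, 7)
        ]
        expected = neighbour_weight(0, 0, 4, 6) / sum(weights)
        assert records[0].p_refined == pytest.approx(expected)
        assert expected < CFG.keep_threshold
        assert len(kept) == 0

    def test_geometry_unchanged_and_scores_bounded(self, rng):
        boxes = [
            Box(cx=float(rng.uniform(10, 50)), cy=float(rng.uniform(10, 50)),
                w=6, h=6, s=int(rng.integers(0, 6)), t=int(rng.integers(0, 10)),
                p=float(rng.uniform(0, 1)))
            for _ in range(40)
        ]
        dets = DetectionSet(boxes=boxes)
        kept, records = refine(dets, CFG, n_slices=6, n_frames=10, keep_all=True)
        assert len(kept) == len(boxes)
        for rec, out in zip(records, kept):
            assert 0.0 <= rec.p_refined <= 1.0
            assert (out.cx, out.cy, out.w, out.h) == (
                rec.box.cx, rec.box.cy, rec.box.w, rec.box.h
            )
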