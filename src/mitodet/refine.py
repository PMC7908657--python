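"""Spatio-temporal refinement of per-slice detection confidences.

A mitotic event is visible, with nearly the same planar extent, in several
neighbouring z-slices and time frames; an isolated single-plane response is
almost always noise.  The refinement re-scores each detected box by the
distance-weighted agreement of binarized detections in a (2N+1) x (2T+1)
neighbourhood of slice offsets ``j`` and frame offsets ``k``:

* each confidence is binarized at 0.5 (inclusive);
* a neighbour at offset ``(j, k)`` carries weight
  ``W = 1 - sqrt(j^2 + k^2) / sqrt(N^2 + T^2)``;
* the refined score is the weighted mean of the binarized agreements over
  all in-volume offsets, missing neighbours contributing 0 with their weight
  retained; offsets falling outside the volume are dropped from both sums.

Defaults N=4 slices, T=6 frames; boxes whose refined score falls below
``keep_threshold`` (default 0.5) are removed, geometry untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .geometry import Box, DetectionSet, greedy_match, iou

__all__ = [
    "RefinementConfig",
    "RefinedBox",
    "binarize",
    "neighbour_weight",
    "associate_neighbours",
    "refine_score",
    "refine",
]


@dataclass(frozen=True)
class RefinementConfig:
    N: int = 4  # spatial neighbour radius, slices
    T: int = 6  # temporal neighbour radius, frames
    binarize_threshold: float = 0.5
    associate_iou: float = 0.3
    keep_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.N < 0 or self.T < 0 or (self.N == 0 and self.T == 0):
            raise ValueError("need N >= 0, T >= 0 and not both zero")
        for name in ("binarize_threshold", "associate_iou", "keep_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class RefinedBox:
    box: Box
    p_hat: int  # binarized own confidence
    p_refined: float  # weighted neighbourhood agreement


def binarize(p: float, threshold: float = 0.5) -> int:
    """1 iff the confidence reaches the threshold (inclusive)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"confidence must lie in [0, 1], got {p}")
    return 1 if p >= threshold else 0


def neighbour_weight(j: int, k: int, N: int, T: int) -> float:
    """Distance weight of slice offset j, frame offset k (1 at the center,
    0 at the (N, T) corner)."""
    if abs(j) > N or abs(k) > T:
        raise ValueError(f"offset ({j}, {k}) outside the (N={N}, T={T}) window")
    return 1.0 - math.sqrt(j * j + k * k) / math.sqrt(N * N + T * T)


def associate_neighbours(
    target: Box,
    detections: DetectionSet,
    config: RefinementConfig,
    n_slices: Optional[int] = None,
    n_frames: Optional[int] = None,
    _grouped: Optional[dict] = None,
) -> dict[tuple[int, int], int]:
    """Binarized agreement of each in-volume neighbourhood cell with the target.

    For every offset ``(j, k)`` whose plane ``(s+j, t+k)`` exists, the
    neighbour box with the highest IoU >= ``associate_iou`` against the
    target's extent contributes its binarized confidence; planes with no
    matching box contribute 0.  Offsets outside the volume are omitted
    entirely (truncated window).
    """
    grouped = detections.grouped() if _grouped is None else _grouped
    contributions: dict[tuple[int, int], int] = {}
    for j in range(-config.N, config.N + 1):
        s = target.s + j
        if s < 0 or (n_slices is not None and s >= n_slices):
            continue
        for k in range(-config.T, config.T + 1):
            t = target.t + k
            if t < 0 or (n_frames is not None and t >= n_frames):
                continue
            if j == 0 and k == 0:
                contributions[(0, 0)] = binarize(target.p, config.binarize_threshold)
                continue
            plane = grouped.get((t, s), [])
            pairing = greedy_match([target], plane, config.associate_iou)
            if 0 in pairing:
                matched = plane[pairing[0]]
                contributions[(j, k)] = binarize(matched.p, config.binarize_threshold)
            else:
                contributions[(j, k)] = 0
    return contributions


def refine_score(
    contributions: dict[tuple[int, int], int], config: RefinementConfig
) -> float:
    """Weighted mean of binarized agreements over the contribution map."""
    if (0, 0) not in contributions:
        raise ValueError("contribution map must contain the target cell (0, 0)")
    num = 0.0
    den = 0.0
    for (j, k), p_hat in contributions.items():
        w = neighbour_weight(j, k, config.N, config.T)
        num += w * p_hat
        den += w
    if den == 0.0:  # only reachable if the map is exactly the zero-weight corner
        return float(contributions[(0, 0)])
    return num / den


def refine(
    detections: DetectionSet,
    config: RefinementConfig = RefinementConfig(),
    n_slices: Optional[int] = None,
    n_frames: Optional[int] = None,
    keep_all: bool = False,
) -> tuple[DetectionSet, list[RefinedBox]]:
    """Re-score every box and drop those below ``keep_threshold``.

    Returns the filtered :class:`DetectionSet` (each kept box's ``p`` replaced
    by its refined score) and the full list of :class:`RefinedBox` records,
    including removed ones, for inspection.  ``keep_all=True`` skips the
    filtering in the returned set.
    """
    grouped = detections.grouped()
    refined: list[RefinedBox] = []
    kept = DetectionSet(source={**detections.source, "refined": True})
    for box in detections:
        contributions = associate_neighbours(
            box, detections, config, n_slices=n_slices, n_frames=n_frames,
            _grouped=grouped,
        )
        score = refine_score(contributions, config)
        record = RefinedBox(
            box=box,
            p_hat=binarize(box.p, config.binarize_threshold),
            p_refined=score,
        )
        refined.append(record)
        if keep_all or score >= config.keep_threshold:
            kept.add(replace(box, p=score))
    return kept, refined
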