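"""Detection evaluation: per-plane 2D metrics and the event-level 4D protocol.

2D protocol: detections and ground truth are matched greedily per (t, s)
plane; a detection is a true positive when its IoU with a ground-truth box
strictly exceeds the threshold (default 0.6).  Precision, recall and two
composite scores are reported: the arithmetic mean (P+R)/2 — the convention
the reference results tables use under the name "F1 score" — and the
standard harmonic-mean F1.

4D protocol: detections within one frame are linked across adjacent slices
into regions; a ground-truth mitotic event counts as a true positive when
some region overlapping it contains 5 continuous slices whose mean per-slice
IoU against the event's boxes exceeds 0.5.  A region with 5 continuous
slices of mean slice-to-slice self-consistency IoU above 0.5 that matches no
event counts as a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .geometry import Box, DetectionSet, greedy_match, iou

__all__ = [
    "EvalReport2D",
    "EvalReport4D",
    "evaluate_2d",
    "composite_score",
    "evaluate_4d",
]


@dataclass
class EvalReport2D:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def score_mean(self) -> float:
        return composite_score(self.precision, self.recall, "mean")

    @property
    def score_harmonic(self) -> float:
        return composite_score(self.precision, self.recall, "harmonic")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "score_mean": round(self.score_mean, 4),
            "score_harmonic": round(self.score_harmonic, 4),
        }


def composite_score(precision: float, recall: float, convention: str = "mean") -> float:
    """Combine precision and recall.

    ``mean``: (P+R)/2, the convention matching the reference tables;
    ``harmonic``: 2PR/(P+R), the standard F1 (0 when P+R = 0).
    """
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if convention == "mean":
        return (precision + recall) / 2.0
    if convention == "harmonic":
        denom = precision + recall
        return 2.0 * precision * recall / denom if denom else 0.0
    raise ValueError(f"unknown convention {convention!r}; use 'mean' or 'harmonic'")


def evaluate_2d(
    detections: Iterable[Box] | DetectionSet,
    annotations: Iterable[Box],
    iou_min: float = 0.6,
) -> EvalReport2D:
    """Per-plane greedy matching at strictly-greater-than ``iou_min``."""
    det_groups: dict[tuple[int, int], list[Box]] = {}
    for b in detections:
        det_groups.setdefault((b.t, b.s), []).append(b)
    ann_groups: dict[tuple[int, int], list[Box]] = {}
    for b in annotations:
        ann_groups.setdefault((b.t, b.s), []).append(b)

    tp = fp = fn = 0
    for key in sorted(set(det_groups) | set(ann_groups)):
        dets = det_groups.get(key, [])
        anns = ann_groups.get(key, [])
        # strict inequality: bump the threshold by an epsilon-free filter
        pairing = greedy_match(dets, anns, iou_min)
        strict = {
            ci: rj for ci, rj in pairing.items() if iou(dets[ci], anns[rj]) > iou_min
        }
        tp += len(strict)
        fp += len(dets) - len(strict)
        fn += len(anns) - len(strict)
    return EvalReport2D(tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# 4D protocol
# ---------------------------------------------------------------------------

@dataclass
class Region:
    """A chain of slice-adjacent detections within one frame."""

    t: int
    boxes: list[Box] = field(default_factory=list)  # ordered by slice

    @property
    def slices(self) -> list[int]:
        return [b.s for b in self.boxes]


@dataclass
class EvalReport4D:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    short_events: list[int] = field(default_factory=list)  # events that can never
    # reach the run-length requirement (span < run_length slices in every frame)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp,
                "short_events": list(self.short_events)}


def _link_regions(
    detections: Sequence[Box], associate_iou: float
) -> list[Region]:
    """Greedy slice-adjacent linking of one frame's detections into regions."""
    by_slice: dict[int, list[Box]] = {}
    for b in detections:
        by_slice.setdefault(b.s, []).append(b)
    regions: list[Region] = []
    open_regions: list[Region] = []
    for s in sorted(by_slice):
        boxes = by_slice[s]
        # regions whose last slice is s-1 may continue into s
        continuing = [r for r in open_regions if r.boxes[-1].s == s - 1]
        tails = [r.boxes[-1] for r in continuing]
        pairing = greedy_match(boxes, tails, associate_iou)
        taken = set()
        for ci, rj in pairing.items():
            continuing[rj].boxes.append(boxes[ci])
            taken.add(ci)
        for ci, b in enumerate(boxes):
            if ci not in taken:
                r = Region(t=b.t, boxes=[b])
                open_regions.append(r)
                regions.append(r)
    return regions


def _best_run_mean(values: list[float], run_length: int) -> float:
    """Maximum mean over any contiguous window of ``run_length`` values."""
    if len(values) < run_length:
        return 0.0
    best = 0.0
    for i in range(len(values) - run_length + 1):
        window = values[i : i + run_length]
        best = max(best, sum(window) / run_length)
    return best


def evaluate_4d(
    detections: Iterable[Box] | DetectionSet,
    annotations: Iterable[Box],
    iou_min: float = 0.5,
    run_length: int = 5,
    associate_iou: float = 0.3,
) -> EvalReport4D:
    """Event-level evaluation via 5-continuous-slice average IoU.

    ``annotations`` must carry ``event_id``; an event is credited (TP) when in
    at least one of its frames a linked detection region achieves a
    ``run_length``-slice window with mean IoU against the event's boxes
    strictly above ``iou_min``.  Regions that are self-consistent over such a
    window but credit no event count one FP each.
    """
    det_list = list(detections)
    ann_by_event: dict[int, list[Box]] = {}
    for b in annotations:
        if b.event_id is None:
            raise ValueError("4D evaluation requires event-linked annotations")
        ann_by_event.setdefault(b.event_id, []).append(b)

    frames = sorted({b.t for b in det_list})
    regions: list[Region] = []
    for t in frames:
        regions.extend(_link_regions([b for b in det_list if b.t == t], associate_iou))

    report = EvalReport4D()
    region_credits: dict[int, bool] = {i: False for i in range(len(regions))}

    for event_id in sorted(ann_by_event):
        ev_boxes = ann_by_event[event_id]
        ev_by_plane = {(b.t, b.s): b for b in ev_boxes}
        # maximal slice span of the event in any one frame
        span_by_frame: dict[int, int] = {}
        for b in ev_boxes:
            span_by_frame[b.t] = span_by_frame.get(b.t, 0) + 1
        if max(span_by_frame.values(), default=0) < run_length:
            report.short_events.append(event_id)
        detected = False
        for ri, region in enumerate(regions):
            ious = [
                iou(b, ev_by_plane[(region.t, b.s)])
                if (region.t, b.s) in ev_by_plane
                else 0.0
                for b in region.boxes
            ]
            if any(v > 0 for v in ious):
                region_credits[ri] = True  # overlaps ground truth: never an FP
            if _best_run_mean(ious, run_length) > iou_min:
                detected = True
        if detected:
            report.tp += 1
        else:
            report.fn += 1

    for ri, region in enumerate(regions):
        if region_credits[ri]:
            continue
        # self-consistency: IoU between successive boxes along the chain
        if len(region.boxes) < run_length:
            continue
        self_ious = [
            iou(a, b) for a, b in zip(region.boxes[:-1], region.boxes[1:])
        ]
        # a window of run_length slices has run_length - 1 adjacent pairs
        if _best_run_mean(self_ious, run_length - 1) > iou_min:
            report.fp += 1
    return report
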