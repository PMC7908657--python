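"""Bounding-box geometry shared by the detection head, refinement and evaluation.

Boxes live in a single slice ``s`` of a single time frame ``t`` of a 4D
microscopy volume.  Coordinates are center-based continuous pixels, 0-based,
x rightward and y downward; extents are half-open intervals
``[cx - w/2, cx + w/2)``.  Overlap (IoU) is always planar — cross-slice and
cross-frame reasoning is the job of the refinement and 4D evaluation stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "Box",
    "DetectionSet",
    "to_corners",
    "from_corners",
    "iou",
    "greedy_match",
    "read_boxes",
    "write_boxes",
]

#: CSV column order used by every reader/writer in the package.
BOX_COLUMNS = ["t", "s", "cx", "cy", "w", "h", "p", "event_id"]


@dataclass(frozen=True)
class Box:
    """One candidate or ground-truth bounding box bound to slice ``s``, frame ``t``.

    ``p`` is the detection confidence (1.0 for ground truth); ``event_id``
    links the boxes of one mitotic event across slices and frames and is only
    populated for ground truth.
    """

    cx: float
    cy: float
    w: float
    h: float
    s: int = 0
    t: int = 0
    p: float = 1.0
    event_id: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.p}")
        if self.s < 0 or self.t < 0:
            raise ValueError("slice and frame indices must be non-negative")

    @property
    def area(self) -> float:
        return self.w * self.h

    def sort_key(self) -> tuple:
        """Deterministic tie-break order: descending p, then geometry."""
        return (-self.p, self.cx, self.cy, self.w, self.h)


def to_corners(box: Box) -> tuple[float, float, float, float]:
    """Return ``(x1, y1, x2, y2)`` corner coordinates (half-open extents)."""
    return (
        box.cx - box.w / 2.0,
        box.cy - box.h / 2.0,
        box.cx + box.w / 2.0,
        box.cy + box.h / 2.0,
    )


def from_corners(
    x1: float, y1: float, x2: float, y2: float, **kwargs
) -> Box:
    """Inverse of :func:`to_corners`; extra fields pass through to :class:`Box`."""
    return Box(cx=(x1 + x2) / 2.0, cy=(y1 + y2) / 2.0, w=x2 - x1, h=y2 - y1, **kwargs)


def iou(a: Box, b: Box) -> float:
    """Planar intersection-over-union of two boxes; ``s`` and ``t`` are ignored."""
    ax1, ay1, ax2, ay2 = to_corners(a)
    bx1, by1, bx2, by2 = to_corners(b)
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return min(inter / union, 1.0)  # guard rounding on near-identical extents


def greedy_match(
    candidates: Sequence[Box],
    references: Sequence[Box],
    iou_min: float,
) -> dict[int, int]:
    """Greedy one-to-one assignment of candidates to references.

    Candidates are visited in descending confidence (ties broken by
    ``(cx, cy, w, h)``); each claims the still-unclaimed reference with the
    highest IoU, provided that IoU reaches ``iou_min``.  Returns a mapping
    ``candidate index -> reference index`` (indices into the input sequences);
    unmatched candidates are absent from the mapping.
    """
    order = sorted(range(len(candidates)), key=lambda i: candidates[i].sort_key())
    ref_order = sorted(range(len(references)), key=lambda j: references[j].sort_key())
    claimed: set[int] = set()
    pairing: dict[int, int] = {}
    for ci in order:
        best_j, best_iou = -1, 0.0
        for rj in ref_order:
            if rj in claimed:
                continue
            v = iou(candidates[ci], references[rj])
            if v > best_iou:
                best_j, best_iou = rj, v
        if best_j >= 0 and best_iou >= iou_min:
            pairing[ci] = best_j
            claimed.add(best_j)
    return pairing


@dataclass
class DetectionSet:
    """Boxes grouped by ``(t, s)`` plus provenance metadata."""

    boxes: list[Box] = field(default_factory=list)
    source: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self) -> Iterator[Box]:
        return iter(self.boxes)

    def add(self, box: Box) -> None:
        self.boxes.append(box)

    def at(self, t: int, s: int) -> list[Box]:
        return [b for b in self.boxes if b.t == t and b.s == s]

    def grouped(self) -> dict[tuple[int, int], list[Box]]:
        groups: dict[tuple[int, int], list[Box]] = {}
        for b in self.boxes:
            groups.setdefault((b.t, b.s), []).append(b)
        return groups

    def filtered(self, p_min: float) -> "DetectionSet":
        return DetectionSet(
            boxes=[b for b in self.boxes if b.p >= p_min],
            source=dict(self.source),
        )


# ---------------------------------------------------------------------------
# serialization: CSV with header t,s,cx,cy,w,h,p,event_id and equivalent JSON
# ---------------------------------------------------------------------------

def _boxes_to_frame(boxes: Iterable[Box]) -> pd.DataFrame:
    rows = [
        {
            "t": b.t,
            "s": b.s,
            "cx": b.cx,
            "cy": b.cy,
            "w": b.w,
            "h": b.h,
            "p": b.p,
            "event_id": b.event_id,
        }
        for b in boxes
    ]
    return pd.DataFrame(rows, columns=BOX_COLUMNS)


def _frame_to_boxes(df: pd.DataFrame, path: Path) -> list[Box]:
    missing = [c for c in BOX_COLUMNS if c not in df.columns and c != "event_id"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    boxes = []
    for row in df.itertuples(index=False):
        eid = getattr(row, "event_id", None)
        if eid is None or (isinstance(eid, float) and pd.isna(eid)):
            eid = None
        else:
            eid = int(eid)
        boxes.append(
            Box(
                t=int(row.t),
                s=int(row.s),
                cx=float(row.cx),
                cy=float(row.cy),
                w=float(row.w),
                h=float(row.h),
                p=float(row.p),
                event_id=eid,
            )
        )
    return boxes


def write_boxes(boxes: Iterable[Box], path: str | Path) -> None:
    """Write boxes as CSV (``.csv``) or a JSON array (``.json``)."""
    path = Path(path)
    df = _boxes_to_frame(boxes)
    if path.suffix == ".json":
        records = df.to_dict(orient="records")
        for r in records:
            if r["event_id"] is None or pd.isna(r["event_id"]):
                r["event_id"] = None
            else:
                r["event_id"] = int(r["event_id"])
        path.write_text(json.dumps(records, indent=1))
    else:
        df.to_csv(path, index=False)


def read_boxes(path: str | Path) -> list[Box]:
    """Read boxes from the CSV or JSON layout produced by :func:`write_boxes`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation/detection file not found: {path}")
    try:
        if path.suffix == ".json":
            df = pd.DataFrame(json.loads(path.read_text()), columns=BOX_COLUMNS)
        else:
            df = pd.read_csv(path)
    except (json.JSONDecodeError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise ValueError(f"malformed box file {path}: {e}") from e
    if df.empty:
        return []
    return _frame_to_boxes(df, path)


def shifted(box: Box, **changes) -> Box:
    """Functional update helper (frozen dataclass)."""
    return replace(box, **changes)
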