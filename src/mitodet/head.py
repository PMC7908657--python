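"""Anchor-free center-point detection head.

Objects are detected as peaks of a single-class center heatmap at 1/4 input
resolution; width/height are regressed densely and read at the peaks, and a
2-channel sub-pixel offset head undoes the 4x stride quantization of the
center coordinate.  Targets follow the standard center-point recipe: one
Gaussian splat per ground-truth box (radius from the min-overlap-0.7 rule),
overlapping splats combined by elementwise max.  The loss is the
penalty-reduced focal loss (alpha=2, beta=4) on the heatmap plus L1 terms on
size and offset evaluated at peak cells only.

The head is deliberately decoupled from the backbone: anything producing a
``(B, C, H/4, W/4)`` feature tensor can drive it, and alternative anchor-free
heads can be swapped in behind the same render/loss/decode surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import Box, DetectionSet
from .nn import Tensor, Module, Conv2d

__all__ = [
    "HeadConfig",
    "HeadOutput",
    "TargetMaps",
    "CenterHead",
    "gaussian_radius",
    "render_targets",
    "detection_loss",
    "decode",
]

logger = logging.getLogger(__name__)

STRIDE = 4  # head operates at 1/4 input resolution


@dataclass(frozen=True)
class HeadConfig:
    hidden_channels: int = 32
    weight_heatmap: float = 1.0
    weight_size: float = 0.1
    weight_offset: float = 1.0
    focal_alpha: float = 2.0
    focal_beta: float = 4.0
    min_overlap: float = 0.7  # Gaussian radius rule
    score_min: float = 0.3  # raw decode threshold; refinement applies 0.5 later
    k_max: int = 20


@dataclass
class HeadOutput:
    """Activated head predictions at 1/4 resolution (batch dimension kept)."""

    heatmap: np.ndarray  # (B, 1, h, w), sigmoid-activated
    size_map: np.ndarray  # (B, 2, h, w): (w, h) in input pixels
    offset_map: np.ndarray  # (B, 2, h, w): (dx, dy) in map cells


@dataclass
class TargetMaps:
    heatmap: np.ndarray  # (1, h, w)
    size_map: np.ndarray  # (2, h, w)
    offset_map: np.ndarray  # (2, h, w)
    center_mask: np.ndarray  # (1, h, w) bool, peak cells
    n_skipped: int = 0  # boxes whose center fell outside the map


def gaussian_radius(box_h: float, box_w: float, min_overlap: float = 0.7) -> float:
    """Largest center displacement keeping IoU >= min_overlap (three-case rule)."""
    a1 = 1.0
    b1 = box_h + box_w
    c1 = box_w * box_h * (1 - min_overlap) / (1 + min_overlap)
    r1 = (b1 - np.sqrt(b1**2 - 4 * a1 * c1)) / (2 * a1)

    a2 = 4.0
    b2 = 2 * (box_h + box_w)
    c2 = (1 - min_overlap) * box_w * box_h
    r2 = (b2 - np.sqrt(b2**2 - 4 * a2 * c2)) / (2 * a2)

    a3 = 4.0 * min_overlap
    b3 = -2 * min_overlap * (box_h + box_w)
    c3 = (min_overlap - 1) * box_w * box_h
    r3 = (-b3 + np.sqrt(b3**2 - 4 * a3 * c3)) / (2 * a3)
    return max(min(r1, r2, r3), 0.0)


def _splat(heatmap: np.ndarray, px: int, py: int, radius: int) -> None:
    """Draw a peak-normalized Gaussian at integer cell (px, py), max-combined."""
    sigma = max(radius / 3.0, 1e-6)
    h, w = heatmap.shape
    x0, x1 = max(px - radius, 0), min(px + radius + 1, w)
    y0, y1 = max(py - radius, 0), min(py + radius + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-((xs - px) ** 2 + (ys - py) ** 2) / (2 * sigma**2))
    np.maximum(heatmap[y0:y1, x0:x1], g, out=heatmap[y0:y1, x0:x1])


def render_targets(annotations: list[Box], map_shape: tuple[int, int]) -> TargetMaps:
    """Render center/size/offset targets for the boxes of one (t, s) plane."""
    h, w = map_shape
    heat = np.zeros((1, h, w))
    size = np.zeros((2, h, w))
    offset = np.zeros((2, h, w))
    mask = np.zeros((1, h, w), dtype=bool)
    skipped = 0
    for box in annotations:
        mx, my = box.cx / STRIDE, box.cy / STRIDE
        px, py = int(mx), int(my)
        if not (0 <= px < w and 0 <= py < h):
            skipped += 1
            continue
        radius = max(int(gaussian_radius(box.h / STRIDE, box.w / STRIDE)), 1)
        _splat(heat[0], px, py, radius)
        heat[0, py, px] = 1.0
        size[:, py, px] = (box.w, box.h)
        offset[:, py, px] = (mx - px, my - py)
        mask[0, py, px] = True
    if skipped:
        logger.warning("render_targets: skipped %d boxes with centers off-map", skipped)
    return TargetMaps(heatmap=heat, size_map=size, offset_map=offset,
                      center_mask=mask, n_skipped=skipped)


class CenterHead(Module):
    """3x3 -> 1x1 convolution branches for heatmap, size and offset."""

    def __init__(self, in_channels: int, config: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        hc = config.hidden_channels
        for branch, out_ch in (("heatmap", 1), ("size", 2), ("offset", 2)):
            self.register(f"{branch}_conv", Conv2d(in_channels, hc, 3, rng))
            self.register(f"{branch}_out", Conv2d(hc, out_ch, 1, rng, padding=0))
        # bias the heatmap toward background so early training is stable
        self.heatmap_out.bias.data[:] = -2.19  # sigmoid ~= 0.1

    def raw(self, features: Tensor) -> dict[str, Tensor]:
        out = {}
        for branch in ("heatmap", "size", "offset"):
            hid = getattr(self, f"{branch}_conv")(features).relu()
            out[branch] = getattr(self, f"{branch}_out")(hid)
        return out

    def __call__(self, features: Tensor) -> HeadOutput:
        raw = self.raw(features)
        return HeadOutput(
            heatmap=1.0 / (1.0 + np.exp(-np.clip(raw["heatmap"].data, -60, 60))),
            size_map=raw["size"].data,
            offset_map=raw["offset"].data,
        )


def detection_loss(
    raw: dict[str, Tensor],
    targets: list[TargetMaps],
    config: HeadConfig = HeadConfig(),
) -> tuple[Tensor, dict[str, float]]:
    """Penalty-reduced focal + masked L1 loss over a batch of target maps.

    ``raw`` holds unactivated head branches; returns the scalar loss tensor
    and a float breakdown for logging.
    """
    B = raw["heatmap"].data.shape[0]
    if len(targets) != B:
        raise ValueError(f"batch mismatch: {B} predictions vs {len(targets)} targets")
    if raw["heatmap"].data.shape[2:] != targets[0].heatmap.shape[1:]:
        raise ValueError(
            f"map shape mismatch: pred {raw['heatmap'].data.shape[2:]} vs "
            f"target {targets[0].heatmap.shape[1:]}"
        )
    heat_t = np.stack([t.heatmap for t in targets])
    size_t = np.stack([t.size_map for t in targets])
    off_t = np.stack([t.offset_map for t in targets])
    peak = np.stack([t.center_mask for t in targets]).astype(np.float64)
    n_pos = max(peak.sum(), 1.0)

    p = raw["heatmap"].sigmoid().clip(1e-6, 1.0 - 1e-6)
    alpha, beta = config.focal_alpha, config.focal_beta
    pos_term = (1.0 - p).pow(alpha) * p.log() * peak
    neg_weight = (1.0 - heat_t) ** beta * (1.0 - peak)
    neg_term = p.pow(alpha) * (1.0 - p).log() * neg_weight
    focal = -(1.0 / n_pos) * (pos_term.sum() + neg_term.sum())

    peak2 = np.repeat(peak, 2, axis=1)
    size_l1 = (1.0 / n_pos) * ((raw["size"] - size_t).abs() * peak2).sum()
    off_l1 = (1.0 / n_pos) * ((raw["offset"] - off_t).abs() * peak2).sum()

    total = (
        config.weight_heatmap * focal
        + config.weight_size * size_l1
        + config.weight_offset * off_l1
    )
    parts = {
        "focal": float(focal.data),
        "size_l1": float(size_l1.data),
        "offset_l1": float(off_l1.data),
        "total": float(total.data),
    }
    return total, parts


def _local_maxima(heat: np.ndarray) -> np.ndarray:
    """Boolean mask of 3x3-neighborhood maxima (plateaus kept)."""
    h, w = heat.shape
    padded = np.pad(heat, 1, constant_values=-np.inf)
    neighborhood = np.max(
        [padded[a : a + h, b : b + w] for a in range(3) for b in range(3)], axis=0
    )
    return heat >= neighborhood


def decode(
    pred: HeadOutput,
    t: int = 0,
    s: int = 0,
    k_max: int | None = None,
    score_min: float | None = None,
    config: HeadConfig = HeadConfig(),
) -> DetectionSet:
    """Decode one plane's head output into boxes in input-pixel coordinates."""
    k_max = config.k_max if k_max is None else k_max
    score_min = config.score_min if score_min is None else score_min
    heat = pred.heatmap[0, 0] if pred.heatmap.ndim == 4 else pred.heatmap[0]
    size = pred.size_map[0] if pred.size_map.ndim == 4 else pred.size_map
    offset = pred.offset_map[0] if pred.offset_map.ndim == 4 else pred.offset_map

    peaks = _local_maxima(heat)
    ys, xs = np.nonzero(peaks & (heat >= score_min))
    scores = heat[ys, xs]
    order = np.lexsort((xs, ys, -scores))[:k_max]

    det = DetectionSet(source={"decode_threshold": score_min})
    for idx in order:
        py, px = int(ys[idx]), int(xs[idx])
        bw, bh = size[0, py, px], size[1, py, px]
        if bw <= 0 or bh <= 0:
            continue
        det.add(
            Box(
                cx=STRIDE * (px + offset[0, py, px]),
                cy=STRIDE * (py + offset[1, py, px]),
                w=float(bw),
                h=float(bh),
                s=s,
                t=t,
                p=float(min(max(heat[py, px], 0.0), 1.0)),
            )
        )
    return det
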