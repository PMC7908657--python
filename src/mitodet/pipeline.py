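"""Training, augmentation, volume-wide inference and checkpointing.

The training loop samples temporal windows around annotated planes
(positives) and annotation-free planes (negatives) of one or more synthetic
or real volumes, applies a shared affine augmentation to the whole window,
renders center-point targets for the window's central plane, and minimizes
the detection loss with Adam under a two-stage learning-rate schedule.
Checkpoints are single ``.npz`` files carrying model weights, optimizer
state, the full configuration, and the sampler's RNG state, so training can
resume bit-exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import affine_transform

from .config import AugmentSpec, PipelineConfig
from .geometry import Box, DetectionSet
from .head import CenterHead, HeadOutput, STRIDE, decode, detection_loss, render_targets
from .nn import Adam, Module, Tensor
from .simulate import Volume4D
from .temporal import RDLApp, extract_window

__all__ = [
    "AugmentDraw",
    "augment",
    "MitosisDetector",
    "TrainResult",
    "train",
    "detect_volume",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentDraw:
    """One sampled augmentation: rotation, isotropic scale, flips, shift."""

    angle_deg: float = 0.0
    scale: float = 1.0
    flip_h: bool = False
    flip_v: bool = False
    shift_x: float = 0.0
    shift_y: float = 0.0

    @property
    def is_identity(self) -> bool:
        return (
            self.angle_deg == 0.0
            and self.scale == 1.0
            and not self.flip_h
            and not self.flip_v
            and self.shift_x == 0.0
            and self.shift_y == 0.0
        )

    @staticmethod
    def sample(spec: AugmentSpec, rng: np.random.Generator) -> "AugmentDraw":
        jitter = (1.0 - spec.crop_fraction) / 2.0
        return AugmentDraw(
            angle_deg=float(rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg)),
            scale=float(rng.uniform(*spec.scale_range)),
            flip_h=bool(spec.flip_horizontal and rng.random() < 0.5),
            flip_v=bool(spec.flip_vertical and rng.random() < 0.5),
            shift_x=float(rng.uniform(-jitter, jitter)),
            shift_y=float(rng.uniform(-jitter, jitter)),
        )

    def matrix(self, height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
        """Forward affine p' = A (p - c) + c + shift, in (x, y) coordinates."""
        th = math.radians(self.angle_deg)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        F = np.diag([-1.0 if self.flip_h else 1.0, -1.0 if self.flip_v else 1.0])
        A = F @ R * self.scale
        c = np.array([width / 2.0, height / 2.0])
        shift = np.array([self.shift_x * width, self.shift_y * height])
        return A, c + shift - A @ c  # p' = A p + offset


def augment(
    stack: np.ndarray,
    boxes: Sequence[Box],
    spec: AugmentSpec,
    draw: AugmentDraw,
) -> tuple[np.ndarray, list[Box]]:
    """Apply one augmentation draw to an image stack and its boxes.

    ``stack`` may have any number of leading dimensions over a trailing
    (H, W) plane (a 2.5D stack, or a whole temporal window); all planes get
    the same affine map.  Boxes are mapped through the affine and re-tightened
    to axis-aligned extents; boxes whose center leaves the image are dropped.
    """
    if draw.is_identity:
        return stack, list(boxes)
    h, w = stack.shape[-2:]
    A, offset = draw.matrix(h, w)
    # scipy maps output coords through (matrix, offset) to input coords:
    # invert the forward map and express it in (row, col) = (y, x) order.
    Ainv = np.linalg.inv(A)
    # box coordinates are continuous (pixel i spans [i, i+1)); scipy indexes
    # pixel centers at integers, i.e. continuous coordinate minus 0.5
    off_in = Ainv @ (np.array([0.5, 0.5]) - offset) - 0.5
    M_yx = Ainv[::-1, ::-1].copy()
    off_yx = off_in[::-1].copy()

    flat = stack.reshape(-1, h, w)
    out = np.empty_like(flat)
    for k in range(flat.shape[0]):
        out[k] = affine_transform(
            flat[k], M_yx, offset=off_yx, order=1, mode="nearest"
        )
    out = out.reshape(stack.shape)

    cos_a, sin_a = abs(math.cos(math.radians(draw.angle_deg))), abs(
        math.sin(math.radians(draw.angle_deg))
    )
    new_boxes: list[Box] = []
    dropped = 0
    for b in boxes:
        cx, cy = A @ np.array([b.cx, b.cy]) + offset
        if not (0 <= cx < w and 0 <= cy < h):
            dropped += 1
            continue
        bw = draw.scale * (b.w * cos_a + b.h * sin_a)
        bh = draw.scale * (b.w * sin_a + b.h * cos_a)
        new_boxes.append(replace(b, cx=float(cx), cy=float(cy), w=bw, h=bh))
    if dropped:
        logger.debug("augment: dropped %d boxes leaving the crop", dropped)
    return out, new_boxes


# ---------------------------------------------------------------------------
# full detector model
# ---------------------------------------------------------------------------

class MitosisDetector(Module):
    """RDLA++ feature extractor plus the anchor-free center-point head."""

    def __init__(self, config: PipelineConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.register("rdla", RDLApp(config.backbone, config.temporal, rng))
        self.register(
            "head", CenterHead(self.rdla.fused_channels_total, config.head, rng)
        )

    def raw(self, windows: Tensor) -> dict[str, Tensor]:
        return self.head.raw(self.rdla(windows))

    def predict(self, windows: np.ndarray) -> HeadOutput:
        raw = self.raw(Tensor(windows))
        return HeadOutput(
            heatmap=1.0 / (1.0 + np.exp(-np.clip(raw["heatmap"].data, -60, 60))),
            size_map=raw["size"].data,
            offset_map=raw["offset"].data,
        )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    model: MitosisDetector,
    optimizer: Adam | None = None,
    iteration: int = 0,
    rng_state: dict | None = None,
) -> None:
    payload: dict[str, np.ndarray] = {
        f"model/{k}": v for k, v in model.state_dict().items()
    }
    meta = {
        "config": model.config.to_dict(),
        "iteration": iteration,
        "rng_state": rng_state,
    }
    if optimizer is not None:
        st = optimizer.state()
        meta["adam"] = {"t": st["t"], "lr": st["lr"]}
        for k, (m, v) in enumerate(zip(st["m"], st["v"])):
            payload[f"adam_m/{k}"] = m
            payload[f"adam_v/{k}"] = v
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta, default=int).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path: str | Path):
    """Return (model, meta dict with 'iteration', 'rng_state', 'adam', 'config')."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        config = PipelineConfig.from_dict(meta["config"])
        model = MitosisDetector(config, np.random.default_rng(0))
        state = {
            k[len("model/"):]: z[k] for k in z.files if k.startswith("model/")
        }
        model.load_state_dict(state)
        n_adam = sum(1 for k in z.files if k.startswith("adam_m/"))
        if n_adam:
            meta["adam_m"] = [z[f"adam_m/{k}"] for k in range(n_adam)]
            meta["adam_v"] = [z[f"adam_v/{k}"] for k in range(n_adam)]
    return model, meta


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: MitosisDetector
    losses: list[float] = field(default_factory=list)
    iterations_run: int = 0


def _annotation_planes(annotations: Sequence[Box]) -> list[tuple[int, int]]:
    return sorted({(b.t, b.s) for b in annotations})




def _sample_batch(
    volumes: Sequence[Volume4D],
    annotations: Sequence[Sequence[Box]],
    config: PipelineConfig,
    rng: np.random.Generator,
    plane_cache: dict | None = None,
):
    """One training batch: positive and negative windows with targets."""
    windows = []
    targets = []
    for b in range(config.train.batch_size):
        vi = int(rng.integers(len(volumes)))
        vol, anns = volumes[vi], annotations[vi]
        if plane_cache is not None and vi in plane_cache:
            planes = plane_cache[vi]
        else:
            planes = _annotation_planes(anns)
            if plane_cache is not None:
                plane_cache[vi] = planes
        # deterministic batch composition: the first ceil(B/(1+ratio)) windows
        # are positive, the rest negative (1:1 at the defaults)
        n_pos = max(int(np.ceil(config.train.batch_size
                                / (1.0 + config.train.negative_ratio))), 1)
        positive = bool(planes) and b < n_pos
        if positive:
            t, s = planes[int(rng.integers(len(planes)))]
        else:
            occupied = set(planes)
            for _ in range(50):
                t = int(rng.integers(vol.n_frames))
                s = int(rng.integers(vol.n_slices))
                if (t, s) not in occupied:
                    break
        win = extract_window(vol, t, s, config.temporal)
        boxes = [bx for bx in anns if bx.t == t and bx.s == s]
        draw = AugmentDraw.sample(config.augment, rng)
        frames, boxes = augment(win.frames, boxes, config.augment, draw)
        h, w = frames.shape[-2:]
        windows.append(frames)
        targets.append(render_targets(boxes, (h // STRIDE, w // STRIDE)))
    return np.stack(windows), targets


def train(
    volumes: Sequence[Volume4D],
    annotations: Sequence[Sequence[Box]],
    config: PipelineConfig,
    checkpoint_path: str | Path | None = None,
    resume_from: str | Path | None = None,
) -> TrainResult:
    """Minimize the detection loss over augmented temporal windows.

    ``volumes`` and ``annotations`` are parallel sequences; pass
    ``resume_from`` to continue bit-exactly from a saved checkpoint.
    """
    if not volumes:
        raise ValueError("need at least one annotated volume")
    if len(volumes) != len(annotations):
        raise ValueError("volumes and annotations must be parallel sequences")

    tcfg = config.train
    if resume_from is not None:
        model, meta = load_checkpoint(resume_from)
        config = model.config
        tcfg = config.train
        rng = np.random.default_rng()
        rng.bit_generator.state = meta["rng_state"]
        start_iter = int(meta["iteration"])
        optimizer = Adam(model.parameters(), lr=tcfg.lr_at(start_iter))
        optimizer.load({"t": meta["adam"]["t"], "m": meta["adam_m"],
                        "v": meta["adam_v"], "lr": meta["adam"]["lr"]})
    else:
        rng = np.random.default_rng(tcfg.seed)
        model = MitosisDetector(config, rng)
        optimizer = Adam(model.parameters(), lr=tcfg.lr_initial)
        start_iter = 0

    cfg_hash = hash(json.dumps(config.to_dict(), sort_keys=True)) & 0xFFFFFFFF
    logger.info(
        "training start: profile=%s seed=%d iterations=%d config_hash=%08x",
        tcfg.profile, tcfg.seed, tcfg.iterations, cfg_hash,
    )

    losses: list[float] = []
    plane_cache: dict = {}
    for iteration in range(start_iter, tcfg.iterations):
        optimizer.lr = tcfg.lr_at(iteration)
        batch, targets = _sample_batch(volumes, annotations, config, rng,
                                       plane_cache)
        raw = model.raw(Tensor(batch))
        loss, parts = detection_loss(raw, targets, config.head)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss at iteration {iteration}: {parts}"
            )
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        losses.append(parts["total"])
        if (iteration + 1) % tcfg.log_every == 0:
            recent = np.mean(losses[-tcfg.log_every:])
            logger.info("iter %d/%d loss=%.4f", iteration + 1, tcfg.iterations, recent)

    if checkpoint_path is not None:
        save_checkpoint(
            checkpoint_path, model, optimizer, iteration=tcfg.iterations,
            rng_state=rng.bit_generator.state,
        )
    return TrainResult(model=model, losses=losses, iterations_run=len(losses))


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _pad_to_multiple(frames: np.ndarray, multiple: int) -> tuple[np.ndarray, int, int]:
    h, w = frames.shape[-2:]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return frames, 0, 0
    pad = [(0, 0)] * (frames.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(frames, pad, mode="reflect"), ph, pw


def detect_volume(
    volume: Volume4D,
    model: MitosisDetector,
    score_min: float | None = None,
    batch_windows: int = 8,
) -> DetectionSet:
    """Decode raw detections for every (t, s) plane of a volume."""
    config = model.config
    out = DetectionSet(source={"model": "mitodet", "decode_threshold":
                               score_min if score_min is not None
                               else config.head.score_min})
    coords = [(t, s) for t in range(volume.n_frames) for s in range(volume.n_slices)]
    n_windows = 0
    for start in range(0, len(coords), batch_windows):
        chunk = coords[start : start + batch_windows]
        frames = []
        for t, s in chunk:
            win = extract_window(volume, t, s, config.temporal)
            f, ph, pw = _pad_to_multiple(win.frames, config.backbone.max_scale)
            frames.append(f)
        pred = model.predict(np.stack(frames))
        for bi, (t, s) in enumerate(chunk):
            plane = HeadOutput(
                heatmap=pred.heatmap[bi : bi + 1],
                size_map=pred.size_map[bi : bi + 1],
                offset_map=pred.offset_map[bi : bi + 1],
            )
            dets = decode(plane, t=t, s=s, score_min=score_min, config=config.head)
            h, w = volume.data.shape[-2:]
            for b in dets:
                if b.cx < w and b.cy < h:  # discard boxes in the padding margin
                    out.add(b)
        n_windows += len(chunk)
    logger.info("detect_volume: %d windows, %d raw boxes", n_windows, len(out))
    return out
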