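"""Synthetic 4D microscopy scenes with planted mitotic events.

The generator emulates the structure of two-photon time-lapse stacks of
epidermal tissue: sparse bright blob-like cells over a weakly textured
background, with one to a few mitotic events per dataset.  A mitotic event is
rendered as a 3D Gaussian blob that elongates along a random 3D orientation,
pinches, and splits into two daughter blobs over a configurable number of
frames.  Exact per-slice bounding-box annotations are derived from each
event's own (noise-free) intensity field, so ground truth is independent of
background texture and noise settings.

All randomness flows from a single ``numpy.random.Generator`` seeded by
``SceneSpec.seed``; two calls with the same spec produce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .geometry import Box, read_boxes, write_boxes

__all__ = ["SceneSpec", "Volume4D", "generate_scene", "write_fixture", "read_fixture"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic 4D scene.

    Defaults are a desk-scale rendition of a contest-style dataset: a small
    field of view, a handful of interphase cells and two mitotic events whose
    full temporal span fits inside the sequence.
    """

    height: int = 64
    width: int = 64
    n_slices: int = 8
    n_frames: int = 16
    n_normal_cells: int = 6
    n_mitotic_events: int = 2
    cell_radius_range: tuple[float, float] = (2.5, 4.0)
    mitosis_duration: int = 6
    blur_sigma: float = 0.6
    noise_sd: float = 0.02
    background_level: float = 0.10
    texture_amplitude: float = 0.03
    # slice spacing in pixel units; chosen so a typical event's half-maximum
    # footprint spans >= 5 consecutive slices, the run the 4D protocol scores
    z_spacing: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.n_slices, self.n_frames) <= 0:
            raise ValueError("volume dimensions must be positive")
        if self.n_normal_cells < 0 or self.n_mitotic_events < 0:
            raise ValueError("object counts must be non-negative")
        if self.mitosis_duration < 3:
            raise ValueError("mitosis_duration must be at least 3 frames")
        rmin, rmax = self.cell_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("cell_radius_range must satisfy 0 < min <= max")
        if self.n_mitotic_events > 0 and self.mitosis_duration > self.n_frames:
            raise ValueError(
                "mitosis_duration exceeds n_frames; the event cannot fit temporally"
            )
        # at division completion the two daughters sit 2*r apart, each of
        # roughly radius r: require ~4*rmax plus margin to fit laterally
        extent = 4.0 * rmax + 4.0
        if self.n_mitotic_events > 0 and extent > min(self.height, self.width):
            raise ValueError(
                f"event spatial extent ~{extent:.0f}px exceeds the "
                f"{self.height}x{self.width} volume"
            )


@dataclass
class Volume4D:
    """4D intensity data ordered ``(t, s, y, x)`` with values in [0, 1]."""

    data: np.ndarray
    spec: Optional[SceneSpec] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"expected a (t, s, y, x) array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _blob_slice(
    h: int,
    w: int,
    cx: float,
    cy: float,
    cz: float,
    s: int,
    r_xy: float,
    r_z: float,
    amplitude: float,
) -> np.ndarray:
    """Planar cut through an anisotropic 3D Gaussian blob at slice index s."""
    dz2 = ((s - cz) / r_z) ** 2
    if dz2 > 9.0:  # >3 sigma in z: negligible
        return np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = ((xx - cx) / r_xy) ** 2 + ((yy - cy) / r_xy) ** 2
    return amplitude * np.exp(-0.5 * (d2 + dz2))


@dataclass
class _Cell:
    cx: float
    cy: float
    cz: float
    r: float
    amplitude: float
    vx: float = 0.0
    vy: float = 0.0


@dataclass
class _Event:
    cx: float
    cy: float
    cz: float
    r: float
    amplitude: float
    t0: int
    duration: int
    orientation: np.ndarray  # 3D unit vector (x, y, z-in-slice-units)
    event_id: int


def _event_intensity(ev: _Event, spec: SceneSpec, t: int, s: int) -> np.ndarray:
    """Noise-free intensity contributed by one mitotic event to slice (t, s).

    Before onset the parent is a single round blob; during the event two lobes
    separate linearly in time along the 3D orientation vector (separation at
    completion = 2x the parent radius); afterwards the daughters persist.
    """
    h, w = spec.height, spec.width
    if t < ev.t0:
        return _blob_slice(h, w, ev.cx, ev.cy, ev.cz, s, ev.r, ev.r / spec.z_spacing,
                           ev.amplitude)
    tau = min((t - ev.t0 + 1) / ev.duration, 1.0)
    sep = 2.0 * ev.r * tau
    ux, uy, uz = ev.orientation
    out = np.zeros((h, w))
    # daughters shrink slightly toward ~0.8x the parent radius as they separate
    r_d = ev.r * (1.0 - 0.2 * tau)
    for sign in (+1.0, -1.0):
        out += _blob_slice(
            h, w,
            ev.cx + sign * ux * sep / 2.0,
            ev.cy + sign * uy * sep / 2.0,
            ev.cz + sign * uz * sep / (2.0 * spec.z_spacing),
            s, r_d, r_d / spec.z_spacing, ev.amplitude,
        )
    return np.minimum(out, ev.amplitude * 1.2)


def _tight_box(mask: np.ndarray) -> tuple[float, float, float, float]:
    """Center/size of the tight bounding box of a boolean mask (pixel extents)."""
    ys, xs = np.nonzero(mask)
    x1, x2 = xs.min(), xs.max() + 1
    y1, y2 = ys.min(), ys.max() + 1
    return ((x1 + x2) / 2.0, (y1 + y2) / 2.0, float(x2 - x1), float(y2 - y1))


def _place_objects(spec: SceneSpec, rng: np.random.Generator):
    """Draw non-overlapping cell and event positions inside safe margins."""
    rmin, rmax = spec.cell_radius_range
    margin = 2.5 * rmax + 2.0
    placed: list[tuple[float, float]] = []

    def draw_xy(min_sep: float) -> tuple[float, float]:
        for _ in range(200):
            x = rng.uniform(margin, spec.width - margin)
            y = rng.uniform(margin, spec.height - margin)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in placed):
                placed.append((x, y))
                return x, y
        raise ValueError("could not place objects without overlap; volume too crowded")

    events = []
    for k in range(spec.n_mitotic_events):
        r = rng.uniform(rmin, rmax)
        x, y = draw_xy(min_sep=4.5 * rmax)
        z = rng.uniform(1.5, spec.n_slices - 2.5) if spec.n_slices > 4 else spec.n_slices / 2
        t0 = int(rng.integers(0, spec.n_frames - spec.mitosis_duration + 1))
        u = rng.normal(size=3)
        u[2] *= 0.5  # divisions are biased toward the imaging plane
        u /= np.linalg.norm(u)
        events.append(
            _Event(cx=x, cy=y, cz=z, r=r, amplitude=rng.uniform(0.8, 1.0),
                   t0=t0, duration=spec.mitosis_duration, orientation=u, event_id=k)
        )
    cells = []
    for _ in range(spec.n_normal_cells):
        r = rng.uniform(rmin, rmax)
        x, y = draw_xy(min_sep=3.0 * rmax)
        z = rng.uniform(0.5, spec.n_slices - 1.5)
        cells.append(
            _Cell(cx=x, cy=y, cz=z, r=r, amplitude=rng.uniform(0.5, 0.8),
                  vx=rng.uniform(-0.15, 0.15), vy=rng.uniform(-0.15, 0.15))
        )
    return cells, events


def generate_scene(spec: SceneSpec) -> tuple[Volume4D, list[Box]]:
    """Render a synthetic scene and its exact per-slice annotations.

    Returns the volume and one :class:`Box` per (t, s) where an event's
    above-half-maximum mask covers at least 4 pixels, linked by ``event_id``.
    """
    rng = np.random.default_rng(spec.seed)
    cells, events = _place_objects(spec, rng)

    h, w = spec.height, spec.width
    texture = gaussian_filter(
        rng.normal(size=(spec.n_slices, h, w)), sigma=(0, 3.0, 3.0)
    )
    if spec.texture_amplitude > 0 and texture.std() > 0:
        texture = spec.texture_amplitude * texture / texture.std()
    else:
        texture = np.zeros_like(texture)

    data = np.zeros((spec.n_frames, spec.n_slices, h, w))
    annotations: list[Box] = []
    for t in range(spec.n_frames):
        for s in range(spec.n_slices):
            img = np.full((h, w), spec.background_level) + texture[s]
            for c in cells:
                img += _blob_slice(
                    h, w, c.cx + c.vx * t, c.cy + c.vy * t, c.cz, s,
                    c.r, c.r / spec.z_spacing, c.amplitude,
                )
            for ev in events:
                contrib = _event_intensity(ev, spec, t, s)
                img += contrib
                if ev.t0 <= t < ev.t0 + ev.duration:
                    peak = max(
                        _event_intensity(ev, spec, t, ss).max()
                        for ss in range(spec.n_slices)
                    )
                    mask = contrib >= 0.5 * peak
                    if mask.sum() >= 4:
                        cx, cy, bw, bh = _tight_box(mask)
                        annotations.append(
                            Box(cx=cx, cy=cy, w=bw, h=bh, s=s, t=t,
                                p=1.0, event_id=ev.event_id)
                        )
            if spec.blur_sigma > 0:
                img = gaussian_filter(img, spec.blur_sigma)
            if spec.noise_sd > 0:
                img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))
            data[t, s] = np.clip(img, 0.0, 1.0)

    return Volume4D(data=data, spec=spec), annotations


# ---------------------------------------------------------------------------
# fixtures on disk: one multi-page TIFF per frame + annotations.csv + spec
# ---------------------------------------------------------------------------

def write_fixture(volume: Volume4D, annotations: list[Box], dir_path: str | Path) -> None:
    """Persist a scene as per-frame multi-page TIFFs plus CSV annotations."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    quantized = np.round(volume.data * 65535.0).astype(np.uint16)
    for t in range(volume.n_frames):
        tifffile.imwrite(d / f"frame_{t:04d}.tif", quantized[t])
    write_boxes(annotations, d / "annotations.csv")
    if volume.spec is not None:
        spec_dict = asdict(volume.spec)
        spec_dict["cell_radius_range"] = list(spec_dict["cell_radius_range"])
        spec_dict = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in spec_dict.items()}
        (d / "scene_spec.json").write_text(json.dumps(spec_dict, indent=1))


def read_fixture(dir_path: str | Path) -> tuple[Volume4D, list[Box]]:
    """Load a scene written by :func:`write_fixture`.

    Accepts either per-frame ``frame_{t:04d}.tif`` multi-page TIFFs or a single
    4D TIFF named ``volume.tif`` in T-Z-Y-X order.
    """
    d = Path(dir_path)
    frame_files = sorted(d.glob("frame_*.tif"))
    single = d / "volume.tif"
    if frame_files:
        try:
            frames = [tifffile.imread(f) for f in frame_files]
        except (ValueError, OSError) as e:
            raise ValueError(f"malformed TIFF in fixture {d}: {e}") from e
        data = np.stack(frames, axis=0)
    elif single.exists():
        data = tifffile.imread(single)
        if data.ndim != 4:
            raise ValueError(f"{single}: expected a 4D (T, Z, Y, X) TIFF")
    else:
        raise FileNotFoundError(f"no frame_*.tif or volume.tif found in {d}")
    if data.dtype == np.uint16:
        data = data.astype(np.float64) / 65535.0
    elif data.dtype == np.uint8:
        data = data.astype(np.float64) / 255.0
    else:
        data = data.astype(np.float64)

    spec = None
    spec_file = d / "scene_spec.json"
    if spec_file.exists():
        raw = json.loads(spec_file.read_text())
        raw["cell_radius_range"] = tuple(raw["cell_radius_range"])
        spec = SceneSpec(**raw)

    ann_file = d / "annotations.csv"
    if not ann_file.exists():
        ann_file = d / "annotations.json"
    if not ann_file.exists():
        raise FileNotFoundError(f"no annotations.csv/json found in {d}")
    annotations = read_boxes(ann_file)
    return Volume4D(data=data, spec=spec), annotations
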