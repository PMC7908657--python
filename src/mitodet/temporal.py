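"""Recurrent temporal aggregation on top of the DLA++ backbone (RDLA++).

For a target location ``(t, s)`` of a 4D volume the detector looks at a
7-frame temporal window (three frames before and after the target, edges
replicated) of 2.5D stacks — the target slice plus its two z-neighbours as
the three input channels.  One shared-weight backbone maps every frame to
per-scale features; each scale is aggregated over time by an independent
bidirectional convolutional LSTM (center-step readout, forward and backward
states concatenated); finally the scales are fused coarsest-first by
bilinear upsampling to scale 4 plus a 1x1 convolution, with each fusion step
seeing all previously fused outputs, and the per-scale projections
concatenated into one head-ready map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import BackboneConfig, DLAppBackbone
from .nn import Tensor, Module, Conv2d, BidirectionalConvLSTM, concat, upsample_bilinear
from .simulate import Volume4D

__all__ = [
    "TemporalConfig",
    "TemporalWindow",
    "extract_window",
    "RDLApp",
]


@dataclass(frozen=True)
class TemporalConfig:
    n_frames_window: int = 7  # 3 forward + 3 backward around the center
    n_slices_stack: int = 3  # 2.5D input: (s-1, s, s+1)
    hidden_channels: int = 16  # per-direction CLSTM state channels, per scale
    fused_channels: int = 16  # per-scale projection width after fusion

    def __post_init__(self) -> None:
        if self.n_frames_window < 1 or self.n_frames_window % 2 == 0:
            raise ValueError("temporal window length must be odd and positive")
        if self.n_slices_stack < 1 or self.n_slices_stack % 2 == 0:
            raise ValueError("slice stack depth must be odd and positive")


@dataclass
class TemporalWindow:
    """Ordered 2.5D stacks for frames t-k .. t+k plus provenance."""

    frames: np.ndarray  # (n_frames_window, n_slices_stack, H, W)
    t: int
    s: int

    @property
    def center(self) -> int:
        return self.frames.shape[0] // 2


def extract_window(
    volume: Volume4D, t: int, s: int, config: TemporalConfig = TemporalConfig()
) -> TemporalWindow:
    """Cut the temporal window of 2.5D stacks at (t, s), replicating edges.

    Frame indices outside ``[0, T)`` are clamped to the nearest valid frame,
    and slice indices outside ``[0, S)`` to the nearest valid slice, so border
    windows see replicated (not fabricated dark) data.
    """
    T, S = volume.n_frames, volume.n_slices
    if not (0 <= t < T and 0 <= s < S):
        raise IndexError(f"(t={t}, s={s}) outside volume with T={T}, S={S}")
    half_t = config.n_frames_window // 2
    half_s = config.n_slices_stack // 2
    t_idx = np.clip(np.arange(t - half_t, t + half_t + 1), 0, T - 1)
    s_idx = np.clip(np.arange(s - half_s, s + half_s + 1), 0, S - 1)
    frames = volume.data[np.ix_(t_idx, s_idx)]
    return TemporalWindow(frames=frames, t=t, s=s)


class RDLApp(Module):
    """Backbone + per-scale bidirectional CLSTMs + full-scale fusion.

    ``forward`` accepts a batch of temporal windows shaped
    ``(B, n_frames_window, n_slices_stack, H, W)`` and returns the fused
    feature tensor at scale 4 with ``3 * fused_channels`` channels.
    """

    def __init__(
        self,
        backbone_config: BackboneConfig,
        temporal_config: TemporalConfig,
        rng: np.random.Generator,
    ):
        super().__init__()
        if len(backbone_config.output_scales) != 3:
            raise ValueError(
                "temporal fusion expects the three output scales {4, 8, 16}; "
                f"backbone provides {backbone_config.output_scales}"
            )
        self.tcfg = temporal_config
        self.register("backbone", DLAppBackbone(backbone_config, rng))
        ch = backbone_config.channels_per_level
        hidden = temporal_config.hidden_channels
        fused = temporal_config.fused_channels
        # coarsest-first fusion order; each step sees all previous projections
        self.fusion_order = (16, 8, 4)
        for scale in self.fusion_order:
            level = {4: 0, 8: 1, 16: 2}[scale]
            self.register(
                f"clstm_{scale}",
                BidirectionalConvLSTM(ch[level], hidden, rng),
            )
        for rank, scale in enumerate(self.fusion_order):
            in_ch = 2 * hidden + rank * fused
            self.register(f"fuse_{scale}", Conv2d(in_ch, fused, 1, rng, padding=0))

    @property
    def fused_channels_total(self) -> int:
        return 3 * self.tcfg.fused_channels

    def backbone_per_frame(self, windows: Tensor) -> list[dict[int, Tensor]]:
        """Run the shared backbone on each frame of the window batch."""
        B, F, C, H, W = windows.data.shape
        features = []
        for k in range(F):
            frame = Tensor(windows.data[:, k])  # inputs carry no gradient
            features.append(self.backbone(frame))
        return features

    def clstm_aggregate(self, per_frame: list[dict[int, Tensor]]) -> dict[int, Tensor]:
        """Bidirectional CLSTM over the frame sequence, per scale, center
        state readout (forward and backward halves concatenated)."""
        shapes = {s: f.data.shape for s, f in per_frame[0].items()}
        for fm in per_frame[1:]:
            for s, f in fm.items():
                if f.data.shape != shapes[s]:
                    raise ValueError("per-frame feature shapes disagree across the window")
        out: dict[int, Tensor] = {}
        for scale in self.fusion_order:
            sequence = [fm[scale] for fm in per_frame]
            out[scale] = getattr(self, f"clstm_{scale}")(sequence)
        return out

    def fuse_scales(self, temporal: dict[int, Tensor]) -> Tensor:
        """Coarsest-first fusion: upsample to scale 4, 1x1-project together
        with all previously fused outputs, then concatenate the projections."""
        for scale in self.fusion_order:
            if scale not in temporal:
                raise ValueError(f"missing temporal features for scale {scale}")
        fused: list[Tensor] = []
        for scale in self.fusion_order:
            x = temporal[scale]
            if scale != 4:
                x = upsample_bilinear(x, scale // 4)
            inp = x if not fused else concat([x] + fused, axis=1)
            fused.append(getattr(self, f"fuse_{scale}")(inp).relu())
        return concat(fused, axis=1)

    def forward(self, windows: Tensor) -> Tensor:
        per_frame = self.backbone_per_frame(windows)
        temporal = self.clstm_aggregate(per_frame)
        return self.fuse_scales(temporal)

    __call__ = forward
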