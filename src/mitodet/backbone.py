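"""Full-scale-connected deep layer aggregation backbone (DLA++).

The extractor is organised as ``I`` downsampling levels (level ``i`` carries
spatial scale ``4 * 2**i`` relative to the input after a two-convolution
stem).  Each level holds a row of aggregation nodes indexed by a dense
position ``j``; node wiring follows three cases:

* ``j = 0`` — a single input: the first node of the finer level below,
  entering through a stride-2 convolution (the downsampling spine);
* ``0 < j < J - (2i + 1)`` — the upsampled output of node ``(i+1, j-1)`` from
  the coarser level, concatenated with every earlier same-level output
  ``(i, 0) .. (i, j-1)`` (the dense skip connections);
* ``j = J - (2i + 1)`` (the last position of a level) — as above but the
  upsample input is node ``(i+1, j-2)``, which is exactly the coarser level's
  final, fully aggregated node.

``J`` bounds the dense positions: level ``i`` has ``J - 2i`` nodes, so the
coarsest level must reduce to a single node, which pins ``J = 2I - 1`` (7 for
the default ``I = 4``, giving the 7/5/3/1 node triangle).  The last node of
each of the three finest levels is exposed as ``Out 4 / Out 8 / Out 16``.

Every node applies a 3x3 convolution + ReLU to its concatenated inputs;
upsampling is bilinear x2 followed by a 1x1 channel projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, Module, Conv2d, concat, upsample_bilinear

__all__ = [
    "BackboneConfig",
    "NodeGraph",
    "node_inputs",
    "build_graph",
    "DLAppBackbone",
    "GraphError",
]

STEM = ("stem", 0)  # sentinel predecessor for node (0, 0)

ROLE_DOWN = "dense_conv_input"
ROLE_SKIP = "same_level_skip"
ROLE_UP = "upsample_input"


class GraphError(ValueError):
    """Structural wiring error, carrying the offending (i, j) when known."""

    def __init__(self, msg: str, node: tuple[int, int] | None = None):
        super().__init__(msg)
        self.node = node


@dataclass(frozen=True)
class BackboneConfig:
    I: int = 4
    J: int = 7
    channels_per_level: tuple[int, ...] = (16, 32, 64, 128)
    in_channels: int = 3
    use_deformable: bool = False

    def __post_init__(self) -> None:
        if self.I < 2:
            raise ValueError("need at least two levels (I >= 2)")
        if len(self.channels_per_level) != self.I:
            raise ValueError(
                f"channels_per_level must list {self.I} entries, got "
                f"{len(self.channels_per_level)}"
            )
        if self.n_positions(self.I - 1) < 1:
            raise ValueError(
                f"J={self.J} leaves level {self.I - 1} with no nodes; "
                f"need J >= {2 * self.I - 1}"
            )

    def n_positions(self, i: int) -> int:
        """Dense positions at level i: j = 0 .. J - (2i + 1), inclusive."""
        return self.J - 2 * i

    def scale(self, i: int) -> int:
        return 4 * 2**i

    @property
    def output_scales(self) -> tuple[int, ...]:
        return tuple(self.scale(i) for i in range(min(self.I, 3)))

    @property
    def max_scale(self) -> int:
        return self.scale(self.I - 1)


REFERENCE_CHANNELS = (64, 128, 256, 512)
TEST_CHANNELS = (16, 32, 64, 128)


def node_inputs(i: int, j: int, config: BackboneConfig) -> list[tuple[str, tuple]]:
    """Labeled predecessors of node (i, j) — a pure wiring function."""
    if not (0 <= i < config.I) or not (0 <= j < config.n_positions(i)):
        raise GraphError(f"({i}, {j}) is not a valid node", node=(i, j))
    if j == 0:
        src = STEM if i == 0 else (i - 1, 0)
        return [(ROLE_DOWN, src)]
    if i == config.I - 1:
        raise GraphError(
            f"node ({i}, {j}) at the coarsest level needs an upsample input "
            f"from a level above {config.I - 1}, which does not exist; "
            f"reduce J (J = 2I - 1 gives the valid triangle)",
            node=(i, j),
        )
    last = config.n_positions(i) - 1  # == J - (2i + 1)
    up_j = j - 1 if j < last else j - 2
    if up_j < 0 or up_j >= config.n_positions(i + 1):
        raise GraphError(
            f"node ({i}, {j}) requires upsample source ({i + 1}, {up_j}), "
            f"which is outside level {i + 1}",
            node=(i, j),
        )
    preds: list[tuple[str, tuple]] = [(ROLE_UP, (i + 1, up_j))]
    preds += [(ROLE_SKIP, (i, k)) for k in range(j)]
    return preds


@dataclass
class NodeGraph:
    config: BackboneConfig
    nodes: list[tuple[int, int]] = field(default_factory=list)
    edges: dict[tuple[int, int], list[tuple[str, tuple]]] = field(default_factory=dict)
    topo_order: list[tuple[int, int]] = field(default_factory=list)
    outputs: dict[int, tuple[int, int]] = field(default_factory=dict)  # scale -> node

    def to_dot(self) -> str:
        lines = ["digraph dlapp {", "  rankdir=BT;"]
        for (i, j) in self.nodes:
            lines.append(f'  "x{i}_{j}" [label="x^{i}_{j}\\nscale {self.config.scale(i)}"];')
        for node, preds in self.edges.items():
            for role, src in preds:
                sname = "stem" if src == STEM else f"x{src[0]}_{src[1]}"
                lines.append(f'  "{sname}" -> "x{node[0]}_{node[1]}" [label="{role}"];')
        lines.append("}")
        return "\n".join(lines)


def build_graph(config: BackboneConfig) -> NodeGraph:
    """Instantiate the wiring graph, validating every node against the
    three-case wiring rule and producing a topological evaluation order."""
    graph = NodeGraph(config=config)
    for i in range(config.I):
        for j in range(config.n_positions(i)):
            graph.nodes.append((i, j))
            graph.edges[(i, j)] = node_inputs(i, j, config)

    # topological order by Kahn's algorithm (deterministic: sorted frontier)
    indeg = {n: 0 for n in graph.nodes}
    dependents: dict[tuple, list] = {n: [] for n in graph.nodes}
    for node, preds in graph.edges.items():
        for _, src in preds:
            if src == STEM:
                continue
            indeg[node] += 1
            dependents[src].append(node)
    frontier = sorted(n for n, d in indeg.items() if d == 0)
    order: list[tuple[int, int]] = []
    while frontier:
        node = frontier.pop(0)
        order.append(node)
        for dep in dependents[node]:
            indeg[dep] -= 1
            if indeg[dep] == 0:
                frontier.append(dep)
        frontier.sort()
    if len(order) != len(graph.nodes):
        raise GraphError("wiring graph contains a cycle")
    graph.topo_order = order

    for i in range(min(config.I, 3)):
        graph.outputs[config.scale(i)] = (i, config.n_positions(i) - 1)
    return graph


class DLAppBackbone(Module):
    """Executable DLA++ network realizing a :class:`NodeGraph`.

    ``use_deformable`` is accepted for config compatibility; offsets-learned
    (deformable) convolutions are not implemented in the numpy engine, so the
    downsampling spine always uses standard stride-2 convolutions.
    """

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.graph = build_graph(config)
        ch = config.channels_per_level

        self.register("stem1", Conv2d(config.in_channels, ch[0], 3, rng, stride=2))
        self.register("stem2", Conv2d(ch[0], ch[0], 3, rng, stride=2))

        for (i, j) in self.graph.topo_order:
            preds = self.graph.edges[(i, j)]
            if j == 0:
                in_ch = ch[0] if i == 0 else ch[i - 1]
                stride = 1 if i == 0 else 2
                self.register(f"node_{i}_{j}", Conv2d(in_ch, ch[i], 3, rng,
                                                      stride=stride))
            else:
                # 1x1 projection after bilinear upsample, then the H conv
                self.register(f"proj_{i}_{j}", Conv2d(ch[i + 1], ch[i], 1, rng,
                                                      padding=0))
                n_inputs = 1 + sum(1 for r, _ in preds if r == ROLE_SKIP)
                self.register(f"node_{i}_{j}", Conv2d(n_inputs * ch[i], ch[i], 3, rng))
        self.realized_inputs: dict[tuple[int, int], list[tuple[str, tuple]]] = {}

    def forward(self, x: Tensor) -> dict[int, Tensor]:
        """Map a (N, in_channels, H, W) stack to per-scale feature tensors."""
        N, C, H, W = x.data.shape
        ms = self.config.max_scale
        if H % ms or W % ms:
            raise ValueError(
                f"input spatial size {H}x{W} must be divisible by {ms}; "
                f"pad the image (e.g. reflect-pad) before calling forward"
            )
        self.realized_inputs = {}
        stem = self.stem2(self.stem1(x).relu()).relu()
        values: dict[tuple, Tensor] = {STEM: stem}
        for (i, j) in self.graph.topo_order:
            preds = self.graph.edges[(i, j)]
            self.realized_inputs[(i, j)] = list(preds)
            if j == 0:
                inp = values[preds[0][1]]
                out = getattr(self, f"node_{i}_{j}")(inp).relu()
            else:
                parts: list[Tensor] = []
                for role, src in preds:
                    if role == ROLE_UP:
                        up = upsample_bilinear(values[src], 2)
                        parts.append(getattr(self, f"proj_{i}_{j}")(up))
                    else:
                        parts.append(values[src])
                out = getattr(self, f"node_{i}_{j}")(concat(parts, axis=1)).relu()
            values[(i, j)] = out
        return {scale: values[node] for scale, node in self.graph.outputs.items()}

    __call__ = forward
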