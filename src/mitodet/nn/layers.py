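"""Layers and optimizer built on the tensor core.

Modules hold named parameters in insertion order; ``state_dict`` /
``load_state_dict`` round-trip through plain numpy arrays so checkpoints are a
single ``.npz`` file.  Initialization is He-normal for convolutions feeding
ReLU and Glorot-uniform elsewhere, drawn from an explicit generator so every
model build is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv2d

__all__ = ["Module", "Conv2d", "ConvLSTMCell", "BidirectionalConvLSTM", "Adam"]


class Module:
    """Base class: parameter registry plus nested submodules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def register(self, name: str, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        else:
            raise TypeError(f"cannot register {type(value)!r}")
        object.__setattr__(self, name, value)
        return value

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(
                f"checkpoint/model mismatch; missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        for k, v in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {arr.shape} vs model "
                    f"{v.data.shape}"
                )
            v.data = arr.copy()

    def zero_all(self) -> None:
        """Set every parameter to zero (used by contract tests)."""
        for p in self.parameters():
            p.data[...] = 0.0


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, init: str = "he"):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        if init == "he":
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        else:
            limit = np.sqrt(6.0 / (fan_in + out_ch * kernel * kernel))
            w = rng.uniform(-limit, limit, size=(out_ch, in_ch, kernel, kernel))
        self.register("weight", Tensor(w, requires_grad=True))
        self.register("bias", Tensor(np.zeros(out_ch), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class ConvLSTMCell(Module):
    """Convolutional LSTM cell: gates from a 3x3 conv of [input, hidden]."""

    def __init__(self, in_ch: int, hidden_ch: int, rng: np.random.Generator,
                 kernel: int = 3):
        super().__init__()
        self.hidden_ch = hidden_ch
        self.register(
            "gates", Conv2d(in_ch + hidden_ch, 4 * hidden_ch, kernel, rng,
                            init="glorot")
        )
        # forget-gate bias starts at 1 so early training does not wash out state
        self.gates.bias.data[hidden_ch : 2 * hidden_ch] = 1.0

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = self.gates(concat([x, h], axis=1))
        n = self.hidden_ch
        i = z.channel_slice(0, n).sigmoid()
        f = z.channel_slice(n, 2 * n).sigmoid()
        g = z.channel_slice(2 * n, 3 * n).tanh()
        o = z.channel_slice(3 * n, 4 * n).sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def initial_state(self, n: int, hw: tuple[int, int]) -> tuple[Tensor, Tensor]:
        shape = (n, self.hidden_ch, hw[0], hw[1])
        return Tensor(np.zeros(shape)), Tensor(np.zeros(shape))


class BidirectionalConvLSTM(Module):
    """Runs a forward and a backward ConvLSTM over a short sequence and
    returns the concatenated hidden states at the center step."""

    def __init__(self, in_ch: int, hidden_ch: int, rng: np.random.Generator):
        super().__init__()
        self.register("fwd", ConvLSTMCell(in_ch, hidden_ch, rng))
        self.register("bwd", ConvLSTMCell(in_ch, hidden_ch, rng))

    def __call__(self, sequence: list[Tensor]) -> Tensor:
        n_steps = len(sequence)
        center = n_steps // 2
        n, _, H, W = sequence[0].data.shape
        h, c = self.fwd.initial_state(n, (H, W))
        h_center_fwd = None
        for k, x in enumerate(sequence):
            h, c = self.fwd.step(x, h, c)
            if k == center:
                h_center_fwd = h
        h, c = self.bwd.initial_state(n, (H, W))
        h_center_bwd = None
        for k, x in enumerate(reversed(sequence)):
            h, c = self.bwd.step(x, h, c)
            if k == n_steps - 1 - center:
                h_center_bwd = h
        return concat([h_center_fwd, h_center_bwd], axis=1)


class Adam:
    """Adam with optional global learning-rate reassignment (for schedules)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    def load(self, st: dict) -> None:
        self.t = int(st["t"])
        self.m = [np.asarray(a) for a in st["m"]]
        self.v = [np.asarray(a) for a in st["v"]]
        self.lr = float(st["lr"])
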