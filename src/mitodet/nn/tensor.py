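"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the package's tensor core: a small define-by-run graph supporting
exactly the operations the detector needs — elementwise arithmetic, the
standard activations, channel concatenation/slicing, 2D convolution (direct
shifted-slice contraction), and separable bilinear upsampling.  Gradients of
every primitive are verified against central finite differences in the test
suite.

Design notes: arrays are float64 throughout (CPU, determinism over speed);
broadcasting is supported in ``+`` and ``*`` with the usual sum-over-broadcast
backward; graphs are torn down after ``backward()`` by dropping closures.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample_bilinear"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph bookkeeping ---------------------------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free the closure
                if node is not self:
                    node.grad = None  # intermediate grads are not retained

    # -- basic arithmetic ----------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    # -- reductions ----------------------------------------------------------
    def sum(self):
        def backward(g):
            self._accum(np.broadcast_to(g, self.data.shape))

        return self._result(np.asarray(self.data.sum()), (self,), backward)

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accum(g * y * (1.0 - y))

        return self._result(y, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - y * y))

        return self._result(y, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._result(np.log(self.data), (self,), backward)

    def pow(self, exponent: float):
        y = self.data**exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._result(y, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return self._result(np.abs(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclamped."""
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accum(g * inside)

        return self._result(np.clip(self.data, lo, hi), (self,), backward)

    # -- shape ops -----------------------------------------------------------
    def channel_slice(self, start: int, stop: int):
        """Slice along axis 1 (channels) of an (N, C, H, W) tensor."""
        def backward(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            self._accum(full)

        return self._result(self.data[:, start:stop], (self,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._result(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution: direct contraction over kernel offsets (no im2col copies)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 1) -> Tensor:
    """2D convolution of (N, Cin, H, W) with (Cout, Cin, kh, kw) weights.

    im2col formulation: one strided-window gather plus a single matmul in
    each direction, which keeps both passes exact and fast on CPU for the
    small feature maps this package works with.
    """
    N, Cin, H, W = x.data.shape
    Cout, Cin_w, kh, kw = weight.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input has {Cin}, weight expects {Cin_w}")
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("convolution output would be empty; input too small")

    xpad = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(xpad, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, Cin, Ho, Wo, kh, kw)
    col = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, Cin * kh * kw
    )
    wmat = weight.data.reshape(Cout, Cin * kh * kw)
    out = (col @ wmat.T).reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, Cout)
        if weight.requires_grad:
            weight._accum((gmat.T @ col).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcol = (gmat @ wmat).reshape(N, Ho, Wo, Cin, kh, kw)
            gx_pad = np.zeros_like(xpad)
            for a in range(kh):
                for b in range(kw):
                    gx_pad[:, :, a : a + stride * Ho : stride,
                           b : b + stride * Wo : stride] += gcol[..., a, b].transpose(
                        0, 3, 1, 2
                    )
            if padding:
                gx = gx_pad[:, :, padding:-padding, padding:-padding]
            else:
                gx = gx_pad
            x._accum(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._result(out, parents, backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1D bilinear interpolation matrix (align_corners=False convention)."""
    M = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        M[i, lo_c] += 1.0 - frac
        M[i, hi_c] += frac
    return M


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = _interp_matrix(n_out, n_in)
    return _INTERP_CACHE[key]


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling of (N, C, H, W) by an integer factor."""
    N, C, H, W = x.data.shape
    Mh = _interp(H * factor, H)
    Mw = _interp(W * factor, W)
    out = Mh @ x.data @ Mw.T  # matmul broadcasts over (N, C)

    def backward(g):
        if x.requires_grad:
            x._accum(Mh.T @ g @ Mw)

    return Tensor._result(out, (x,), backward)
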