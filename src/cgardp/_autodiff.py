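"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the pair/path encoders need: broadcast
arithmetic, matmul, the sigmoid/tanh/ReLU nonlinearities, a numerically
stable softmax, valid 2-D convolution, non-overlapping max pooling, row
gather and concatenation.  Gradients are accumulated by a topological
backward sweep over the recorded graph.

All values are float64 ndarrays; gradient checks in the test suite compare
every operator against central finite differences.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "concatenate",
    "conv2d",
    "max_pool2d",
    "softmax",
    "clipped_log",
]

_LOG_FLOOR = 1e-12


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    # ---- graph traversal -------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.value)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.value.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.value, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(-g)

        out._backward = bwd
        return out

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other: float) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.value @ other.value, parents=(self, other))
        a, b = self.value, other.value

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                if b.ndim == 1:
                    self._accum(np.outer(g, b) if a.ndim == 2 else g * b)
                else:
                    self._accum(np.atleast_2d(g) @ b.T if a.ndim >= 2 else b @ g)
            if other.requires_grad:
                if a.ndim == 1:
                    other._accum(np.outer(a, g) if b.ndim == 2 else g * a)
                else:
                    other._accum(a.T @ np.atleast_2d(g) if b.ndim >= 2 else a.T @ g)

        out._backward = bwd
        return out

    # ---- shaping ---------------------------------------------------------

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.value.T, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g.T)

        out._backward = bwd
        return out

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.value.reshape(*shape), parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g.reshape(self.value.shape))

        out._backward = bwd
        return out

    def take(self, indices: Sequence[int] | np.ndarray) -> "Tensor":
        """Gather rows along axis 0 (repeated indices accumulate)."""
        idx = np.asarray(indices, dtype=np.intp)
        out = Tensor(self.value[idx], parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                acc = np.zeros_like(self.value)
                np.add.at(acc, idx, g)
                self._accum(acc)

        out._backward = bwd
        return out

    # ---- reductions ------------------------------------------------------

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape).copy())

        out._backward = bwd
        return out

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.value.size)

    # ---- nonlinearities --------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.value, 0.0), parents=(self,))
        mask = self.value > 0

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        s = _stable_sigmoid(self.value)
        out = Tensor(s, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.value)
        out = Tensor(t, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        out._backward = bwd
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.value)
        out = Tensor(e, parents=(self,))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * e)

        out._backward = bwd
        return out


def _as_tensor(x: "Tensor | float | np.ndarray") -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def constant(value: np.ndarray | float) -> Tensor:
    return Tensor(value, requires_grad=False)


def parameter(value: np.ndarray) -> Tensor:
    return Tensor(np.array(value, dtype=np.float64), requires_grad=True)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.value for t in tensors], axis=axis), parents=tuple(tensors)
    )
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max subtraction) as a primitive."""
    shifted = x.value - x.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = bwd
    return out


def clipped_log(x: Tensor, floor: float = _LOG_FLOOR) -> Tensor:
    """log with its argument clipped below at `floor` (guards log(0))."""
    clipped = np.maximum(x.value, floor)
    out = Tensor(np.log(clipped), parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * (x.value > floor) / clipped)

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 2-D convolution (cross-correlation, stride 1).

    x: (B, C, H, W); w: (F, C, kh, kw); b: (F,) -> (B, F, H-kh+1, W-kw+1).
    """
    B, C, H, W = x.value.shape
    F, Cw, kh, kw = w.value.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, filters {Cw}")
    if kh > H or kw > W:
        raise ValueError(f"filter ({kh},{kw}) larger than input ({H},{W})")
    patches = np.lib.stride_tricks.sliding_window_view(x.value, (kh, kw), axis=(2, 3))
    # patches: (B, C, Ho, Wo, kh, kw)
    y = np.einsum("bchwij,fcij->bfhw", patches, w.value, optimize=True)
    y += b.value[None, :, None, None]
    out = Tensor(y, parents=(x, w, b))

    def bwd(g: np.ndarray) -> None:
        if w.requires_grad:
            w._accum(np.einsum("bchwij,bfhw->fcij", patches, g, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros_like(x.value)
            Ho, Wo = g.shape[2], g.shape[3]
            for di in range(kh):
                for dj in range(kw):
                    gx[:, :, di : di + Ho, dj : dj + Wo] += np.einsum(
                        "bfhw,fc->bchw", g, w.value[:, :, di, dj], optimize=True
                    )
            x._accum(gx)

    out._backward = bwd
    return out


def max_pool2d(x: Tensor, window: tuple[int, int]) -> Tensor:
    """Non-overlapping max pooling; trailing partial windows are dropped.

    The window is clamped to the input extent so degenerate maps (e.g. a
    single row) still pool along the other axis.
    """
    B, C, H, W = x.value.shape
    ph, pw = min(window[0], H), min(window[1], W)
    Ho, Wo = H // ph, W // pw
    v = x.value[:, :, : Ho * ph, : Wo * pw]
    blocks = v.reshape(B, C, Ho, ph, Wo, pw).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(B, C, Ho, Wo, ph * pw)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        gflat = np.zeros((B, C, Ho, Wo, ph * pw))
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.value)
        gx[:, :, : Ho * ph, : Wo * pw] = (
            gflat.reshape(B, C, Ho, Wo, ph, pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, Ho * ph, Wo * pw)
        )
        x._accum(gx)

    out._backward = bwd
    return out
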