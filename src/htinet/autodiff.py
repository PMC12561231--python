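"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model here is small enough (whole-graph training at desk scale) that a
compact tape-based engine covers every operation the network needs:
broadcast arithmetic, (batched) matmul, the usual nonlinearities, gather /
scatter-add for per-edge message passing, and shape surgery. Gradients are
accumulated by topological traversal of the recorded graph. The engine is
deterministic: identical inputs produce bitwise-identical outputs and
gradients.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(grad.shape, shape)):
        if ss == 1 and gs != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward
        self.name = name

    # -- bookkeeping -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        tag = f" {self.name!r}" if self.name else ""
        return f"Tensor(shape={self.shape}{tag}, grad={'yes' if self.requires_grad else 'no'})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def back(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def back(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, True, (self, other))

        def back(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = back
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), True, (self, other))

        def back(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                # vector @ matrix
                if self.requires_grad or self._parents:
                    self._accumulate(np.matmul(g, np.swapaxes(b, -1, -2)))
                if other.requires_grad or other._parents:
                    other._accumulate(np.outer(a, g))
                return
            if b.ndim == 1:
                if self.requires_grad or self._parents:
                    self._accumulate(np.outer(g, b) if a.ndim == 2 else g[..., None] * b)
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g[..., None])[..., 0], b.shape))
                return
            if self.requires_grad or self._parents:
                self._accumulate(
                    _unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)), a.shape)
                )
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g), b.shape)
                )

        out._backward = back
        return out

    # -- shape surgery ---------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), True, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = axes or tuple(reversed(range(self.ndim)))
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), True, (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], True, (self,))

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = back
        return out

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def back(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities -------------------------------------------


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), True, (x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def leaky_relu(x: Tensor, negative_slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.where(x.data > 0, x.data, negative_slope * x.data), True, (x,))
    out._backward = lambda g: x._accumulate(
        g * np.where(x.data > 0, 1.0, negative_slope)
    )
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, True, (x,))
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(np.clip(x.data, -700, 700))
    out = Tensor(e, True, (x,))
    out._backward = lambda g: x._accumulate(g * e)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), True, (x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = np.sqrt(x.data)
    out = Tensor(s, True, (x,))
    out._backward = lambda g: x._accumulate(g * 0.5 / s)
    return out


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; gradients pass through only inside the open interval."""
    x = as_tensor(x)
    out = Tensor(np.clip(x.data, lo, hi), True, (x,))
    out._backward = lambda g: x._accumulate(g * ((x.data > lo) & (x.data < hi)))
    return out


# -- structural ops -------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out._backward = back
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), True, tuple(tensors))

    def back(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    out._backward = back
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]`` (first axis); backward scatter-adds."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], True, (x,))

    def back(g):
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        x._accumulate(full)

    out._backward = back
    return out


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given by ``segments``."""
    x = as_tensor(x)
    segments = np.asarray(segments, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segments, x.data)
    out = Tensor(data, True, (x,))
    out._backward = lambda g: x._accumulate(g[segments])
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max-shift is a constant)."""
    x = as_tensor(x)
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


def segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a 1-D score vector within each segment bucket."""
    scores = as_tensor(scores)
    segments = np.asarray(segments, dtype=np.intp)
    # per-segment max as a constant shift for stability
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segments, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    e = exp(scores - Tensor(seg_max[segments]))
    denom = segment_sum(e, segments, num_segments)
    return e / gather_rows(denom, segments)


# -- parameters and optimizer ---------------------------------------------


class Parameter(Tensor):
    """A named trainable tensor."""

    __slots__ = ()

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam with decoupled weight decay, matching the usual defaults."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decay_overrides: dict[int, float] | None = None,
        lr_overrides: dict[int, float] | None = None,
    ):
        """``decay_overrides`` / ``lr_overrides`` map ``id(param)`` to a
        per-parameter weight decay / relative learning-rate factor,
        overriding the global values (the lr override is a multiplier on
        ``self.lr`` so external schedules still apply)."""
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay = [
            (decay_overrides or {}).get(id(p), weight_decay) for p in self.params
        ]
        self.lr_scale = [
            (lr_overrides or {}).get(id(p), 1.0) for p in self.params
        ]
        self.t = 0
        # float32 moments: the largest parameter dominates step cost and
        # the moment estimates do not need full precision
        self.m = [np.zeros(p.data.shape, dtype=np.float32) for p in self.params]
        self.v = [np.zeros(p.data.shape, dtype=np.float32) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 / (1 - self.b1**self.t)
        c2 = 1.0 / (1 - self.b2**self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.decay[i]:
                g = g + self.decay[i] * p.data
            m, v = self.m[i], self.v[i]
            # in-place moment updates: the largest parameters dominate the
            # per-step cost, so avoid temporaries where possible
            g32 = g.astype(np.float32, copy=False)
            m *= self.b1
            m += (1 - self.b1) * g32
            v *= self.b2
            v += (1 - self.b2) * (g32 * g32)
            denom = np.sqrt(v * np.float32(c2))
            denom += np.float32(self.eps)
            update = m * np.float32(self.lr * self.lr_scale[i] * c1)
            update /= denom
            p.data -= update
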