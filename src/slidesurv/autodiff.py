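"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order and accumulates gradients.  Only the primitives the tile-graph survival
model needs are implemented: broadcast arithmetic, 2-D matmul, the usual
pointwise nonlinearities, row gather / segment scatter-sum (the message-passing
primitives), axis reductions, concatenation, reshape, and a causal shift used
by the depthwise convolution of the state-space branch.

Gradients of every primitive are exercised against central finite differences
in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_max",
    "causal_shift",
    "expm1_over_x",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        # float32 arrays stay float32 (model training); everything else is
        # promoted to float64 (the default for analytic/numerical work)
        arr = np.asarray(data)
        self.data = arr if arr.dtype == np.float32 else np.asarray(arr, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
            if self.grad.shape != self.data.shape:  # scalar broadcast
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _lift_like(self, x) -> "Tensor":
        """Wrap a constant, keeping 0-d values in this tensor's dtype so
        python scalars do not silently promote float32 graphs to float64."""
        if isinstance(x, Tensor):
            return x
        a = np.asarray(x)
        if a.ndim == 0:
            a = a.astype(self.data.dtype)
        return Tensor(a)

    def __add__(self, other) -> "Tensor":
        other = self._lift_like(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift_like(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift_like(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift_like(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift_like(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift_like(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * p * self.data ** (p - 1)
        )
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = _bw
        return out

    # -- pointwise nonlinearities ------------------------------------------

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        # closures must not capture `out` (out._backward -> closure -> out
        # would be a reference cycle, and tapes would pile up on the GC)
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (1.0 - y**2)
        )
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * s * (1.0 - s)
        )
        return out

    def silu(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * s * (1.0 + self.data * (1.0 - s))
        )
        return out

    def softplus(self) -> "Tensor":
        # numerically stable log(1 + e^x)
        y = np.logaddexp(0.0, self.data)
        out = Tensor(y, self.requires_grad, (self,))
        s = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda g: self.requires_grad and self._accum(g * s)
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (self.data > 0.0)
        )
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0.0, 1.0, slope).astype(self.data.dtype)
        out = Tensor(self.data * factor, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * factor)
        return out

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        no_repeats = all(isinstance(p, (slice, int)) for p in parts)

        def _bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            if no_repeats:  # slices cannot alias, so += beats np.add.at
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accum(full)

        out._backward = _bw
        return out


# -- free functions ---------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = _bw
    return out


def gather_rows(t: Tensor, idx: np.ndarray, injective: bool = False) -> Tensor:
    """Select rows ``t[idx]`` along axis 0; backward scatter-adds.

    Set ``injective=True`` when ``idx`` has no repeats: the backward pass then
    uses direct assignment instead of the much slower ``np.add.at``.
    """
    idx = np.asarray(idx)
    out = Tensor(t.data[idx], t.requires_grad, (t,))

    def _bw(g):
        if not t.requires_grad:
            return
        full = np.zeros_like(t.data)
        if injective:
            full[idx] = g
        elif idx.ndim == 1 and g.ndim <= 2:
            # sort + grouped reduce is far faster than np.add.at
            order = np.argsort(idx, kind="stable")
            sorted_idx = idx[order]
            starts = np.r_[0, np.flatnonzero(np.diff(sorted_idx)) + 1]
            full[sorted_idx[starts]] = np.add.reduceat(g[order], starts, axis=0)
        else:
            np.add.at(full, idx, g)
        t._accum(full)

    out._backward = _bw
    return out


def segment_sum(t: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given by ``seg``."""
    seg = np.asarray(seg)
    data = np.zeros((num_segments,) + t.data.shape[1:], dtype=t.data.dtype)
    np.add.at(data, seg, t.data)
    out = Tensor(data, t.requires_grad, (t,))
    out._backward = lambda g: t.requires_grad and t._accum(g[seg])
    return out


def segment_max(values: np.ndarray, seg: np.ndarray, num_segments: int) -> np.ndarray:
    """Per-segment maximum of a plain array (used as a constant softmax shift)."""
    out = np.full(num_segments, -np.inf, dtype=values.dtype)
    np.maximum.at(out, seg, values)
    return out


def causal_shift(t: Tensor, s: int, axis: int = 1) -> Tensor:
    """Shift a (batch, length, ...) tensor forward by ``s`` steps, zero-filled.

    ``out[:, s:] = t[:, :-s]`` — the building block of a causal depthwise
    convolution along the sequence axis.
    """
    if s == 0:
        return t
    data = np.zeros_like(t.data)
    src = [slice(None)] * t.data.ndim
    dst = [slice(None)] * t.data.ndim
    src[axis] = slice(None, -s)
    dst[axis] = slice(s, None)
    data[tuple(dst)] = t.data[tuple(src)]
    out = Tensor(data, t.requires_grad, (t,))

    def _bw(g):
        if not t.requires_grad:
            return
        gg = np.zeros_like(t.data)
        gg[tuple(src)] = g[tuple(dst)]
        t._accum(gg)

    out._backward = _bw
    return out


def _expm1_over_x_vals(x: np.ndarray) -> np.ndarray:
    # (e^x - 1)/x with the removable singularity at 0.  expm1 keeps the
    # quotient accurate for tiny |x|; only exact zeros need patching.
    x = np.asarray(x, dtype=np.float64)
    out = np.atleast_1d(np.expm1(x))
    zero = np.atleast_1d(x == 0.0)
    np.divide(out, np.atleast_1d(x), out=out, where=~zero)
    if np.any(zero):
        out[zero] = 1.0
    return out.reshape(x.shape)


def expm1_over_x(t: Tensor) -> Tensor:
    """phi1(x) = (e^x - 1)/x, the zero-order-hold input-response factor.

    phi1(0) = 1; phi1'(x) = (x e^x - (e^x - 1))/x^2 with phi1'(0) = 1/2.
    """
    x = t.data
    out = Tensor(_expm1_over_x_vals(x), t.requires_grad, (t,))
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    deriv = np.where(
        small,
        0.5 + x / 6.0,
        (safe * np.exp(safe) - np.expm1(safe)) / safe**2,
    )
    out._backward = lambda g: t.requires_grad and t._accum(g * deriv)
    return out
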