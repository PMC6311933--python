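"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the sequence classifier:
broadcasting arithmetic, matmul, pointwise nonlinearities, reductions,
1-D convolution, max pooling, indexing/concatenation, and a numerically
stable binary cross-entropy on logits.  Gradients flow to any leaf
tensor created with ``requires_grad=True`` — model parameters during
training, the one-hot input during saliency computation.
"""

from __future__ import annotations

import contextlib
import gc

import numpy as np

__all__ = ["Tensor", "concat", "stack", "paused_gc"]


@contextlib.contextmanager
def paused_gc():
    """Disable the cyclic garbage collector inside graph-heavy loops.

    The autograd graph is a DAG freed by reference counting alone, but
    its tens of thousands of tracked containers trigger pathological
    full GC sweeps mid-epoch.  Collection runs once on exit.
    """
    was_enabled = gc.isenabled()
    gc.disable()
    try:
        yield
    finally:
        if was_enabled:
            gc.enable()
            gc.collect()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _coerce(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph construction helper ------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = _coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_coerce(other))

    def __rsub__(self, other):
        return _coerce(other) + (-self)

    def __truediv__(self, other):
        other = _coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = _coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    def pow(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities ------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions and reshaping --------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        parts = idx if isinstance(idx, tuple) else (idx,)
        fancy = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if fancy:  # repeated indices need unbuffered accumulation
                    np.add.at(full, idx, g)
                else:
                    full[idx] += g
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- convolution / pooling -----------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """Valid cross-correlation.

        self: (N, C_in, W); weight: (C_out, C_in, K); bias: (C_out,).
        Returns (N, C_out, W - K + 1).
        """
        x, w = self.data, weight.data
        k = w.shape[2]
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        out_data = np.einsum("ock,nctk->not", w, windows, optimize=True)
        out_data += bias.data[None, :, None]

        def backward(g):
            if weight.requires_grad:
                weight._accum(np.einsum("not,nctk->ock", g, windows, optimize=True))
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if self.requires_grad:
                dx = np.zeros_like(x)
                t = g.shape[2]
                for j in range(k):
                    dx[:, :, j : j + t] += np.einsum(
                        "oc,not->nct", w[:, :, j], g, optimize=True
                    )
                self._accum(dx)

        return Tensor._make(out_data, (self, weight, bias), backward)

    def maxpool1d(self, width: int):
        """Non-overlapping max pooling along the last axis; tail dropped."""
        n, c, t = self.data.shape
        t_out = t // width
        trimmed = self.data[:, :, : t_out * width].reshape(n, c, t_out, width)
        arg = trimmed.argmax(axis=3)
        out_data = np.take_along_axis(trimmed, arg[..., None], axis=3)[..., 0]

        def backward(g):
            if not self.requires_grad:
                return
            dtr = np.zeros((n, c, t_out, width))
            np.put_along_axis(dtr, arg[..., None], g[..., None], axis=3)
            full = np.zeros_like(self.data)
            full[:, :, : t_out * width] = dtr.reshape(n, c, t_out * width)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- loss ----------------------------------------------------------
    def bce_with_logits(self, targets: np.ndarray):
        """Mean binary cross-entropy on logits (numerically stable)."""
        z = self.data
        y = np.asarray(targets, dtype=np.float64)
        loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
        out_data = loss.mean()
        p = 0.5 * (1.0 + np.tanh(0.5 * z))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (p - y) / z.size)

        return Tensor._make(out_data, (self,), backward)

    # -- backward driver -----------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
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
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(np.squeeze(piece, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
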