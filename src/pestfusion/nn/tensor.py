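"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  The operation set is exactly what the density
network needs: broadcast arithmetic, (batched) matmul, 1-D/2-D convolution,
the usual pointwise nonlinearities, reductions, reshaping/indexing and
concatenation.  All gradients are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "concatenate", "where",
           "conv1d", "conv2d", "softmax"]

_GRAD_ENABLED = [True]


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference fast path)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_tensor(x, like: "Tensor | None" = None) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    if like is not None and isinstance(x, (int, float)):
        # keep the computation in the partner's dtype (0-d float64 arrays
        # would otherwise upcast every float32 op they touch)
        return Tensor(np.asarray(x, dtype=like.data.dtype))
    return Tensor(np.asarray(x))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        track = is_grad_enabled() and any(
            p.requires_grad or p._prev for p in parents)
        out = Tensor(data, requires_grad=False)
        if track:
            out._prev = tuple(parents)
            out._backward = backward
            out.requires_grad = True  # participates in the graph
        return out

    def _needs_grad(self) -> bool:
        return self.requires_grad or bool(self._prev)

    def _accum(self, g: np.ndarray, owned: bool = False) -> None:
        # constants that feed the graph never need their gradient
        if not (self.requires_grad or self._prev):
            return
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            if owned and g.dtype == self.data.dtype and g.base is None:
                self.grad = g
            elif g.dtype == self.data.dtype:
                self.grad = g.copy()
            else:
                self.grad = g.astype(self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # free the graph eagerly: each node's backward closure references the
        # node itself, a cycle the reference counter alone cannot collect;
        # intermediate gradient buffers are dropped with it (leaf gradients
        # survive — leaves have no parents and are skipped here)
        for node in topo:
            if node._prev:
                node._backward = None
                node._prev = ()
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic properties --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, like=self)
        out_data = self.data + other.data

        def backward():
            if out.grad is None:
                return
            self._accum(out.grad)
            other._accum(out.grad)

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other, like=self)
        out_data = self.data * other.data

        def backward():
            if self._needs_grad():
                self._accum(out.grad * other.data, owned=True)
            if other._needs_grad():
                other._accum(out.grad * self.data, owned=True)

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other, like=self))

    def __rsub__(self, other):
        return _as_tensor(other, like=self) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other, like=self)
        out_data = self.data / other.data

        def backward():
            inv = 1.0 / other.data
            ga = out.grad * inv
            if self._needs_grad():
                self._accum(ga, owned=not other._needs_grad())
            if other._needs_grad():
                other._accum(-ga * out_data, owned=True)

        out = Tensor._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other, like=self) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward():
            self._accum(out.grad * exponent * self.data ** (exponent - 1), owned=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward():
            if self._needs_grad():
                self._accum(np.matmul(out.grad,
                                      other.data.swapaxes(-1, -2)),
                            owned=True)
            if other._needs_grad():
                other._accum(np.matmul(self.data.swapaxes(-1, -2), out.grad),
                             owned=True)

        out = Tensor._make(out_data, (self, other), backward)
        return out

    # -- pointwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            self._accum(out.grad * out_data, owned=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self):
        out_data = np.log(self.data)

        def backward():
            self._accum(out.grad / self.data, owned=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward():
            self._accum(out.grad * 0.5 / out_data, owned=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward():
            self._accum(out.grad * (1.0 - out_data ** 2), owned=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        # numerically stable logistic
        out_data = np.where(self.data >= 0,
                            1.0 / (1.0 + np.exp(-np.clip(self.data, None, 50))),
                            np.exp(np.clip(self.data, -50, None))
                            / (1.0 + np.exp(np.clip(self.data, -50, None))))

        def backward():
            self._accum(out.grad * out_data * (1.0 - out_data), owned=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward():
            self._accum(out.grad * mask, owned=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def abs(self):
        sign = np.sign(self.data)
        out_data = np.abs(self.data)

        def backward():
            self._accum(out.grad * sign, owned=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward():
            self._accum(out.grad.reshape(orig))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward():
            self._accum(out.grad.transpose(inv))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def swapaxes(self, a: int, b: int):
        out_data = self.data.swapaxes(a, b)

        def backward():
            self._accum(out.grad.swapaxes(a, b))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward():
            g = np.zeros_like(self.data)
            basic = isinstance(idx, (int, slice)) or (
                isinstance(idx, tuple)
                and all(isinstance(i, (int, slice)) for i in idx))
            if basic:  # no repeated positions possible
                g[idx] += out.grad
            else:
                np.add.at(g, idx, out.grad)
            self._accum(g)

        out = Tensor._make(out_data, (self,), backward)
        return out


# -- free functions --------------------------------------------------------

def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out_data.ndim
            sl[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def where(condition: np.ndarray, a, b) -> Tensor:
    """Select elementwise; ``condition`` is a constant boolean array."""
    a, b = _as_tensor(a), _as_tensor(b)
    cond = np.asarray(condition, dtype=bool)
    out_data = np.where(cond, a.data, b.data)

    def backward():
        a._accum(np.where(cond, out.grad, 0.0))
        b._accum(np.where(cond, 0.0, out.grad))

    out = Tensor._make(out_data, (a, b), backward)
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` with the analytic Jacobian-vector backward
    ``dx = w * (g - sum(g * w))``."""
    shifted = t.data - np.max(t.data, axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward():
        g = out.grad
        tmp = g * out_data
        t._accum(tmp - out_data * tmp.sum(axis=axis, keepdims=True),
                 owned=True)

    out = Tensor._make(out_data, (t,), backward)
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W), w: (Cout,Cin,kh,kw)."""
    n, c, h, wd = x.data.shape
    cout, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding))) if padding else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, c * kh * kw)
    wmat = w.data.reshape(cout, -1)
    out_flat = cols @ wmat.T
    if b is not None:
        out_flat = out_flat + b.data
    out_data = out_flat.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)

    def backward():
        go = np.ascontiguousarray(out.grad.transpose(0, 2, 3, 1)).reshape(
            -1, cout)
        if w._needs_grad():
            w._accum((go.T @ cols).reshape(w.data.shape), owned=True)
        if b is not None and b._needs_grad():
            b._accum(go.sum(axis=0), owned=True)
        if x._needs_grad():
            dcols = (go @ wmat).reshape(n, oh, ow, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * oh:stride,
                        j:j + stride * ow:stride] += dcols[:, :, :, :, i, j
                                                           ].transpose(0, 3,
                                                                       1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp, owned=not padding)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, parents, backward)
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """1-D temporal cross-correlation. x: (N,C,L), w: (Cout,Cin,k)."""
    n, c, length = x.data.shape
    if padding:
        zeros = Tensor(np.zeros((n, c, padding), dtype=x.data.dtype))
        x = concatenate([zeros, x, zeros], axis=2)
        length += 2 * padding
    x4 = x.reshape(n, c, 1, length)
    w4 = w.reshape(w.data.shape[0], w.data.shape[1], 1, w.data.shape[2])
    out4 = conv2d(x4, w4, b, stride=stride, padding=0)
    return out4.reshape(out4.shape[0], out4.shape[1], out4.shape[3])
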