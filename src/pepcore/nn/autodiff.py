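"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations needed by the design network are implemented: broadcast
arithmetic, matmul, reshape/transpose/concat, reductions, elementwise
nonlinearities, softmax, and same-padded 1-D/2-D convolutions. Gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

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
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
        if g.shape == shape:
            return g
        nd = g.ndim - len(shape)
        if nd > 0:
            g = g.sum(axis=tuple(range(nd)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g

    def _make(self, data: np.ndarray, prev: tuple["Tensor", ...], backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    @property
    def T(self):
        return self.transpose()

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise --------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        c = np.sqrt(2.0 / np.pi)
        inner = (self * c) * (1.0 + self * self * 0.044715)
        return self * 0.5 * (1.0 + inner.tanh())


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    return x._make(y, (x,), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(t for t in tensors if t.requires_grad)

        def bw(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)

        out._backward = bw
    return out


def _same_pad_1d(n: int, k: int) -> tuple[int, int]:
    total = k - 1
    return total // 2, total - total // 2


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1-D convolution. x: (C_in, N), w: (C_out, C_in, k),
    b: (C_out,) -> (C_out, N)."""
    c_in, n = x.data.shape
    c_out, _, k = w.data.shape
    lo, hi = _same_pad_1d(n, k)
    xp = np.pad(x.data, ((0, 0), (lo, hi)))
    patches = np.stack([xp[:, t:t + n] for t in range(k)], axis=1)  # (C_in, k, N)
    out_data = np.einsum("oik,ikn->on", w.data, patches) + b.data[:, None]

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("on,ikn->oik", g, patches))
        if b.requires_grad:
            b._accum(g.sum(axis=1))
        if x.requires_grad:
            gp = np.einsum("on,oik->ikn", g, w.data)
            gx = np.zeros_like(xp)
            for t in range(k):
                gx[:, t:t + n] += gp[:, t, :]
            x._accum(gx[:, lo:lo + n])

    return x._make(out_data, (x, w, b), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 2-D convolution. x: (C_in, H, W), w: (C_out, C_in, k, k),
    b: (C_out,) -> (C_out, H, W)."""
    c_in, h, wd = x.data.shape
    c_out, _, k, _ = w.data.shape
    lo, hi = _same_pad_1d(h, k)
    xp = np.pad(x.data, ((0, 0), (lo, hi), (lo, hi)))
    patches = np.empty((c_in, k, k, h, wd))
    for u in range(k):
        for v in range(k):
            patches[:, u, v] = xp[:, u:u + h, v:v + wd]
    out_data = np.einsum("oiuv,iuvhw->ohw", w.data, patches) + b.data[:, None, None]

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("ohw,iuvhw->oiuv", g, patches))
        if b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))
        if x.requires_grad:
            gp = np.einsum("ohw,oiuv->iuvhw", g, w.data)
            gx = np.zeros_like(xp)
            for u in range(k):
                for v in range(k):
                    gx[:, u:u + h, v:v + wd] += gp[:, u, v]
            x._accum(gx[:, lo:lo + h, lo:lo + wd])

    return x._make(out_data, (x, w, b), bw)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
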