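"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network and the CRF recurrent layer in this package are
built on this engine.  It provides exactly the operator set those models
need — broadcasting arithmetic, reductions, stable softmax, 3D convolutions
(stride-1 "same" and the 2x2x2 stride-2 down/up pair), channel layer
normalisation and dropout — plus a hook (:func:`from_op`) for fused custom
operations with hand-written backward passes.

Tensors are plain ``float64`` numpy arrays in channel-first layout
``(C, X, Y, Z)`` with no batch axis; the models in this package always
process one volume at a time.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "from_op", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g, owned: bool = False):
        """Add `g` to the gradient.  `owned=True` promises that `g` is a
        freshly allocated array of the right shape that the caller will not
        reuse, letting the first accumulation take it by reference."""
        if self.grad is None:
            if owned and isinstance(g, np.ndarray) and g.shape == self.data.shape:
                self.grad = g
            else:
                self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                     dtype=np.float64)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # The backward closures reference their own output node, forming
        # reference cycles that keep volume-sized arrays alive until the
        # cycle collector runs; tear the graph down eagerly instead.
        for t in topo:
            t._backward = None
            t._parents = ()
            if not t.requires_grad:
                t.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = from_op(self.data + other.data, (self, other))

        def bw():
            if self.requires_grad_path:
                g = _unbroadcast(out.grad, self.shape)
                self._accumulate(g, owned=g is not out.grad)
            if other.requires_grad_path:
                g = _unbroadcast(out.grad, other.shape)
                other._accumulate(g, owned=g is not out.grad)

        out._backward = bw
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = from_op(self.data * other.data, (self, other))

        def bw():
            if self.requires_grad_path:
                self._accumulate(_unbroadcast(out.grad * other.data,
                                              self.shape), owned=True)
            if other.requires_grad_path:
                other._accumulate(_unbroadcast(out.grad * self.data,
                                               other.shape), owned=True)

        out._backward = bw
        return out

    def __neg__(self):
        out = from_op(-self.data, (self,))

        def bw():
            self._accumulate(-out.grad, owned=True)

        out._backward = bw
        return out

    def __sub__(self, other):
        other = _as_tensor(other)
        out = from_op(self.data - other.data, (self, other))

        def bw():
            if self.requires_grad_path:
                g = _unbroadcast(out.grad, self.shape)
                self._accumulate(g, owned=g is not out.grad)
            if other.requires_grad_path:
                other._accumulate(-_unbroadcast(out.grad, other.shape),
                                  owned=True)

        out._backward = bw
        return out

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    __radd__ = __add__
    __rmul__ = __mul__

    def __pow__(self, p: float):
        out = from_op(self.data ** p, (self,))

        def bw():
            self._accumulate(out.grad * p * self.data ** (p - 1.0), owned=True)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = from_op(self.data[idx], (self,))

        def bw():
            g = np.zeros_like(self.data)
            g[idx] = out.grad
            self._accumulate(g, owned=True)

        out._backward = bw
        return out

    def exp(self):
        out = from_op(np.exp(self.data), (self,))

        def bw():
            self._accumulate(out.grad * out.data, owned=True)

        out._backward = bw
        return out

    def log(self):
        out = from_op(np.log(self.data), (self,))

        def bw():
            self._accumulate(out.grad / self.data, owned=True)

        out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        out = from_op(np.maximum(self.data, 0.0), (self,))

        def bw():
            self._accumulate(out.grad * (self.data > 0), owned=True)

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        out = from_op(self.data.reshape(*shape), (self,))

        def bw():
            self._accumulate(out.grad.reshape(self.shape))  # view: not owned

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy(), owned=True)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def softmax(self, axis: int = 0):
        """Numerically stable softmax along `axis`."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = from_op(y, (self,))

        def bw():
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot), owned=True)

        out._backward = bw
        return out

    def matmul(self, other: "Tensor"):
        other = _as_tensor(other)
        out = from_op(self.data @ other.data, (self, other))

        def bw():
            if self.requires_grad_path:
                self._accumulate(out.grad @ other.data.T, owned=True)
            if other.requires_grad_path:
                other._accumulate(self.data.T @ out.grad, owned=True)

        out._backward = bw
        return out

    @property
    def requires_grad_path(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def __float__(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"


class Parameter(Tensor):
    """A trainable tensor (``requires_grad=True`` by default)."""

    def __init__(self, data, requires_grad: bool = True):
        super().__init__(data, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def from_op(data: np.ndarray, parents: tuple) -> Tensor:
    """Create a graph node; parents that cannot need gradients are pruned."""
    parents = tuple(p for p in parents if p.requires_grad or p._parents)
    out = Tensor(data)
    out._parents = parents
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = from_op(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw():
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            if t.requires_grad_path:
                t._accumulate(g)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Neural-net operations (channel-first volumes, no batch axis)
# ---------------------------------------------------------------------------

_IM2COL_BUDGET = 3 * 10 ** 7   # patch-matrix elements (~240 MB float64)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, zero-padded "same" 3D convolution.

    x: (C, X, Y, Z); w: (O, C, k, k, k); b: (O,).  Uses an im2col patch
    matrix and a single BLAS matmul when the patch matrix fits a fixed
    memory budget, otherwise k^3 shifted matmuls.  Both paths compute the
    exact dense convolution.
    """
    O, C, k, _, _ = w.shape
    p = k // 2
    X, Y, Z = x.shape[1:]
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    n = X * Y * Z
    if C * k ** 3 * n <= _IM2COL_BUDGET:
        return _conv3d_im2col(x, w, b, xp)
    out = np.zeros((O, n))
    for i in range(k):
        for j in range(k):
            for l in range(k):
                patch = xp[:, i:i + X, j:j + Y, l:l + Z].reshape(C, n)
                out += w.data[:, :, i, j, l] @ patch
    out = out.reshape(O, X, Y, Z) + b.data[:, None, None, None]
    res = from_op(out, (x, w, b))

    def bw():
        g = res.grad.reshape(O, n)
        if x.requires_grad_path:
            gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    if w.requires_grad:
                        patch = xp[:, i:i + X, j:j + Y, l:l + Z].reshape(C, n)
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        w.grad[:, :, i, j, l] += g @ patch.T
                    if x.requires_grad_path:
                        gxp[:, i:i + X, j:j + Y, l:l + Z] += (
                            w.data[:, :, i, j, l].T @ g).reshape(C, X, Y, Z)
        if x.requires_grad_path:
            x._accumulate(gxp[:, p:p + X, p:p + Y, p:p + Z].copy()
                          if p else gxp, owned=True)
        if b.requires_grad:
            b._accumulate(res.grad.sum(axis=(1, 2, 3)), owned=True)

    res._backward = bw
    return res


def _conv3d_im2col(x: Tensor, w: Tensor, b: Tensor, xp: np.ndarray) -> Tensor:
    O, C, k, _, _ = w.shape
    p = k // 2
    X, Y, Z = x.shape[1:]
    n = X * Y * Z
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                   axis=(1, 2, 3))
    # (C, X, Y, Z, k, k, k) -> (C*k^3, N)
    patches = np.ascontiguousarray(
        win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(C * k ** 3, n))
    wm = w.data.reshape(O, C * k ** 3)
    out = (wm @ patches).reshape(O, X, Y, Z) + b.data[:, None, None, None]
    res = from_op(out, (x, w, b))

    def bw():
        g = res.grad.reshape(O, n)
        if w.requires_grad:
            gw = (g @ patches.T).reshape(w.data.shape)
            w._accumulate(gw, owned=True)
        if b.requires_grad:
            b._accumulate(res.grad.sum(axis=(1, 2, 3)), owned=True)
        if x.requires_grad_path:
            dpatch = (wm.T @ g).reshape(C, k, k, k, X, Y, Z)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gxp[:, i:i + X, j:j + Y, l:l + Z] += dpatch[:, i, j, l]
            x._accumulate(gxp[:, p:p + X, p:p + Y, p:p + Z].copy()
                          if p else gxp, owned=True)

    res._backward = bw
    return res


def down_conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2x2 convolution with stride 2 (halves each spatial axis).

    w: (O, C, 2, 2, 2).
    """
    O, C = w.shape[:2]
    X, Y, Z = x.shape[1:]
    out = np.zeros((O, X // 2, Y // 2, Z // 2))
    for i in range(2):
        for j in range(2):
            for l in range(2):
                sub = x.data[:, i::2, j::2, l::2]
                out += np.tensordot(w.data[:, :, i, j, l], sub, axes=(1, 0))
    out += b.data[:, None, None, None]
    res = from_op(out, (x, w, b))

    def bw():
        g = res.grad
        if x.requires_grad_path:
            gx = np.zeros_like(x.data)
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    if w.requires_grad:
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        sub = x.data[:, i::2, j::2, l::2]
                        w.grad[:, :, i, j, l] += np.tensordot(
                            g, sub, axes=((1, 2, 3), (1, 2, 3)))
                    if x.requires_grad_path:
                        gx[:, i::2, j::2, l::2] += np.tensordot(
                            w.data[:, :, i, j, l], g, axes=(0, 0))
        if x.requires_grad_path:
            x._accumulate(gx, owned=True)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)), owned=True)

    res._backward = bw
    return res


def up_conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2x2 transposed convolution with stride 2 (doubles each axis).

    w: (C_in, O, 2, 2, 2) — transposed-convolution weight convention.
    """
    C, O = w.shape[:2]
    X, Y, Z = x.shape[1:]
    out = np.empty((O, 2 * X, 2 * Y, 2 * Z))
    for i in range(2):
        for j in range(2):
            for l in range(2):
                out[:, i::2, j::2, l::2] = np.tensordot(
                    w.data[:, :, i, j, l], x.data, axes=(0, 0))
    out += b.data[:, None, None, None]
    res = from_op(out, (x, w, b))

    def bw():
        if x.requires_grad_path:
            gx = np.zeros_like(x.data)
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    g = res.grad[:, i::2, j::2, l::2]
                    if w.requires_grad:
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        w.grad[:, :, i, j, l] += np.tensordot(
                            x.data, g, axes=((1, 2, 3), (1, 2, 3)))
                    if x.requires_grad_path:
                        gx += np.tensordot(w.data[:, :, i, j, l], g, axes=(1, 0))
        if x.requires_grad_path:
            x._accumulate(gx, owned=True)
        if b.requires_grad:
            b._accumulate(res.grad.sum(axis=(1, 2, 3)), owned=True)

    res._backward = bw
    return res


def avg_pool2(x: Tensor) -> Tensor:
    """Average-pool by a factor of 2 along each spatial axis."""
    C, X, Y, Z = x.shape
    v = x.data.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2)
    out = from_op(v.mean(axis=(2, 4, 6)), (x,))

    def bw():
        g = np.repeat(np.repeat(np.repeat(
            out.grad, 2, axis=1), 2, axis=2), 2, axis=3) / 8.0
        x._accumulate(g, owned=True)

    out._backward = bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    out = from_op(x.data * mask, (x,))

    def bw():
        x._accumulate(out.grad * mask, owned=True)

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the channel axis (axis 0), per voxel.

    Fused forward/backward (the composition of primitive ops would allocate
    about ten intermediate volumes per call).
    """
    c = x.shape[0]
    gb = (c,) + (1,) * (x.ndim - 1)
    mu = x.data.mean(axis=0, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=0, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    g = gamma.data.reshape(gb)
    out = from_op(xhat * g + beta.data.reshape(gb), (x, gamma, beta))

    def bw():
        go = out.grad
        if gamma.requires_grad:
            gamma._accumulate((go * xhat).sum(axis=tuple(range(1, x.ndim))))
        if beta.requires_grad:
            beta._accumulate(go.sum(axis=tuple(range(1, x.ndim))))
        if x.requires_grad_path:
            gh = go * g
            t1 = gh.mean(axis=0, keepdims=True)
            t2 = (gh * xhat).mean(axis=0, keepdims=True)
            x._accumulate(inv * (gh - t1 - xhat * t2), owned=True)

    out._backward = bw
    return out


class Adam:
    """Adam optimiser over a dict of named Parameters."""

    def __init__(self, params: dict, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = {k: p for k, p in params.items() if p.requires_grad}
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
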