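"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine provides exactly the operator set the segmentation networks and
losses need: broadcasting arithmetic, reductions, elementwise nonlinearities,
channel concatenation/slicing, and three 3D convolution primitives —
same-padded stride-1 convolution (kernel 1 or 3), non-overlapping stride-2
kernel-2 down-convolution, and its transposed counterpart.  Restricting the
convolutions to these cases keeps every forward/backward pass a handful of
reshapes plus one einsum/tensordot, which is fast enough on a single CPU for
the patch sizes this package trains at.

Gradients accumulate into ``Tensor.grad`` on ``backward()``; correctness of
every primitive is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "Adam", "concat", "conv3d_same", "down_conv",
           "up_conv", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = _GRAD_ENABLED and (
            bool(requires_grad) or any(p.requires_grad for p in _parents)
        )
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor(self.data**e, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * e * self.data ** (e - 1.0))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        out._backward = bw
        return out

    # -- reductions & elementwise -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the interior, zero outside."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def softmax(self, axis: int = 1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters are trainable even if built under no_grad


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# 3D convolution primitives.  Layout: x (N, C, D, H, W); weights
# (C_out, C_in, k, k, k) for conv and down_conv, (C_in, C_out, 2, 2, 2) for
# the transposed up_conv; bias (C_out,).


def _conv_same_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    k = w.shape[-1]
    if k == 1:
        return np.einsum("ncdhw,oc->nodhw", x, w[:, :, 0, 0, 0], optimize=True)
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    out = np.tensordot(v, w, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    return np.moveaxis(out, -1, 1)


def conv3d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, same-padded 3D convolution for odd kernels (1 or 3)."""
    k = w.data.shape[-1]
    out_data = _conv_same_raw(x.data, w.data) + b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(out_data, _parents=(x, w, b))

    def bw(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            if k == 1:
                gw = np.einsum("nodhw,ncdhw->oc", g, x.data, optimize=True)
                w._accumulate(gw.reshape(w.data.shape))
            else:
                p = k // 2
                xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
                v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
                gw = np.tensordot(g, v, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                w._accumulate(gw)
        if x.requires_grad:
            # input gradient = same-padded correlation with the spatially
            # flipped, channel-transposed kernel
            wt = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            )
            x._accumulate(_conv_same_raw(g, wt))

    out._backward = bw
    return out


def down_conv(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Kernel-2, stride-2 convolution (non-overlapping): halves each spatial dim."""
    n, c, d, h, wd = x.data.shape
    xr = x.data.reshape(n, c, d // 2, 2, h // 2, 2, wd // 2, 2)
    out_data = np.einsum("ncdahbwe,ocabe->nodhw", xr, w.data, optimize=True)
    out_data += b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(out_data, _parents=(x, w, b))

    def bw(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            w._accumulate(np.einsum("nodhw,ncdahbwe->ocabe", g, xr, optimize=True))
        if x.requires_grad:
            gx = np.einsum("nodhw,ocabe->ncdahbwe", g, w.data, optimize=True)
            x._accumulate(gx.reshape(n, c, d, h, wd))

    out._backward = bw
    return out


def up_conv(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Kernel-2, stride-2 transposed convolution: doubles each spatial dim."""
    n, c, d, h, wd = x.data.shape
    o = w.data.shape[1]
    out_r = np.einsum("ncdhw,coabe->nodahbwe", x.data, w.data, optimize=True)
    out_data = out_r.reshape(n, o, 2 * d, 2 * h, 2 * wd) + b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(out_data, _parents=(x, w, b))

    def bw(g):
        gr = g.reshape(n, o, d, 2, h, 2, wd, 2)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            w._accumulate(np.einsum("nodahbwe,ncdhw->coabe", gr, x.data, optimize=True))
        if x.requires_grad:
            x._accumulate(np.einsum("nodahbwe,coabe->ncdhw", gr, w.data, optimize=True))

    out._backward = bw
    return out


class Adam:
    """Adam with decoupled weight decay and an externally settable learning rate."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1**self.t)
            v_hat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)
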