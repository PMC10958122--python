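"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set needed by the inpainting generator,
the spatio-temporal patch discriminator and their losses: broadcasting
arithmetic, matmul, 2D/3D convolution (im2col), nearest-neighbour
upsampling, elementwise nonlinearities and reductions.  Gradients are
accumulated by a topological backward sweep; correctness is pinned by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "conv2d", "conv3d", "upsample_nearest2d"]


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
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        # parents: sequence of (parent_tensor, fn mapping out-grad -> parent-grad)
        self._parents = tuple(parents)

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, fn in t._parents:
                if not p.requires_grad:
                    continue
                pg = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, self.requires_grad, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.data.shape
                    ),
                ),
            ),
        )
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data
        out = Tensor(
            a @ b,
            self.requires_grad or other.requires_grad,
            parents=(
                (self, lambda g: _unbroadcast(g @ b.swapaxes(-1, -2), a.shape)),
                (other, lambda g: _unbroadcast(a.swapaxes(-1, -2) @ g, b.shape)),
            ),
        )
        return out

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor(
            self.data * mask, self.requires_grad, parents=((self, lambda g: g * mask),)
        )

    def tanh(self):
        y = np.tanh(self.data)
        return Tensor(
            y, self.requires_grad, parents=((self, lambda g: g * (1.0 - y * y)),)
        )

    def exp(self):
        y = np.exp(self.data)
        return Tensor(y, self.requires_grad, parents=((self, lambda g: g * y),))

    def abs(self):
        s = np.sign(self.data)  # subgradient 0 at 0
        return Tensor(
            np.abs(self.data), self.requires_grad, parents=((self, lambda g: g * s),)
        )

    # -- reductions & shaping --------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return np.broadcast_to(g2, self.data.shape).copy()

        return Tensor(out_data, self.requires_grad, parents=((self, grad_fn),))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape),
            self.requires_grad,
            parents=((self, lambda g: g.reshape(old)),),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            self.requires_grad,
            parents=((self, lambda g: g.transpose(inv)),),
        )


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)

    def make_fn(i):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    parents = tuple((t, make_fn(i)) for i, t in enumerate(tensors))
    return Tensor(data, any(t.requires_grad for t in tensors), parents=parents)


# -- convolution ----------------------------------------------------------


def _im2col2d(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # (N, C, Ho, Wo, kh, kw)
    return win


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """x: (N,C,H,W); w: (O,C,kh,kw); b: (O,)."""
    n, c, h, wd = x.data.shape
    o, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols6 = _im2col2d(xp, kh, kw, stride, stride)
    _, _, ho, wo, _, _ = cols6.shape
    cols = cols6.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, -1)
    out = (cols @ wmat.T + b.data).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def grad_x(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        gcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if padding:
            return gxp[:, :, padding:-padding, padding:-padding]
        return gxp

    def grad_w(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        return (gmat.T @ cols).reshape(o, c, kh, kw)

    def grad_b(g):
        return g.sum(axis=(0, 2, 3))

    req = x.requires_grad or w.requires_grad or b.requires_grad
    return Tensor(out, req, parents=((x, grad_x), (w, grad_w), (b, grad_b)))


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride=(1, 1, 1), padding=(1, 1, 1)) -> Tensor:
    """x: (N,C,T,H,W); w: (O,C,kt,kh,kw); b: (O,)."""
    n, c, t, h, wd = x.data.shape
    o, _, kt, kh, kw = w.data.shape
    st, sh, sw = stride
    pt, ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::st, ::sh, ::sw]  # (N,C,To,Ho,Wo,kt,kh,kw)
    _, _, to, ho, wo, _, _, _ = win.shape
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * to * ho * wo, c * kt * kh * kw)
    wmat = w.data.reshape(o, -1)
    out = (cols @ wmat.T + b.data).reshape(n, to, ho, wo, o).transpose(0, 4, 1, 2, 3)

    def grad_x(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(n * to * ho * wo, o)
        gcols = (gmat @ wmat).reshape(n, to, ho, wo, c, kt, kh, kw)
        gxp = np.zeros_like(xp)
        for a in range(kt):
            for i in range(kh):
                for j in range(kw):
                    gxp[
                        :,
                        :,
                        a : a + to * st : st,
                        i : i + ho * sh : sh,
                        j : j + wo * sw : sw,
                    ] += gcols[:, :, :, :, :, a, i, j].transpose(0, 4, 1, 2, 3)
        sl = [slice(None), slice(None)]
        for p in (pt, ph, pw):
            sl.append(slice(p, -p) if p else slice(None))
        return gxp[tuple(sl)]

    def grad_w(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(n * to * ho * wo, o)
        return (gmat.T @ cols).reshape(o, c, kt, kh, kw)

    def grad_b(g):
        return g.sum(axis=(0, 2, 3, 4))

    req = x.requires_grad or w.requires_grad or b.requires_grad
    return Tensor(out, req, parents=((x, grad_x), (w, grad_w), (b, grad_b)))


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of (N,C,H,W) by an integer factor."""
    f = int(factor)
    out = x.data.repeat(f, axis=2).repeat(f, axis=3)
    n, c, h, w = x.data.shape

    def grad_fn(g):
        return g.reshape(n, c, h, f, w, f).sum(axis=(3, 5))

    return Tensor(out, x.requires_grad, parents=((x, grad_fn),))
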