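"""Minimal reverse-mode automatic differentiation over real numpy arrays.

The engine supports exactly the operations needed by the complex-valued
encoder-decoder: elementwise arithmetic, ReLU, sqrt, abs, channel
concatenation, 2D convolution / transposed convolution with TensorFlow-style
"same" padding, and masked reductions. Complex tensors are carried as
(real, imaginary) pairs of `Tensor`s, so the real chain rule yields the
correct Wirtinger-consistent gradients for free.

Everything is float32 by default for speed; gradients are accumulated in the
same dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d_same", "conv2d_transpose_same"]


class Tensor:
    """A node in the computation graph wrapping a real ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            self._accum(g)
            other._accum(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        out._backward = backward
        return out

    # -- nonlinearities --------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sqrt(self):
        root = np.sqrt(self.data)
        out = Tensor(root, parents=(self,))
        out._backward = lambda g: self._accum(g * (0.5 / np.maximum(root, 1e-20)))
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * sign)
        return out

    def square(self):
        out = Tensor(self.data * self.data, parents=(self,))
        out._backward = lambda g: self._accum(2.0 * g * self.data)
        return out

    # -- reductions ------------------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    # -- backprop --------------------------------------------------------

    def backward(self):
        """Backpropagate from a scalar output."""
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
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward(node.grad)
            # release upstream buffers eagerly
            if node is not self:
                node._backward = None


def _unbroadcast(g, shape):
    """Sum gradient `g` down to `shape` (inverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors, axis=-1):
    """Concatenate tensors along `axis`."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = backward
    return out


def concat_channels(tensors):
    """Concatenate along the trailing (channel) axis."""
    return concat(tensors, axis=-1)


def take_channels(t, start, stop):
    """Slice the trailing (channel) axis: t[..., start:stop]."""
    out = Tensor(t.data[..., start:stop], parents=(t,))

    def backward(g):
        full = np.zeros_like(t.data)
        full[..., start:stop] = g
        t._accum(full)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Real 2D convolution primitives (NHWC, kernel (kh, kw, cin, cout),
# TensorFlow-style "same" padding). Forward, input-gradient and
# weight-gradient are exposed separately so that the transposed convolution
# can be wired as the exact adjoint.
# ---------------------------------------------------------------------------


def _same_pads(size, k, s):
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


def _im2col(x, kh, kw, stride):
    n, h, w, c = x.shape
    oh, pt, pb = _same_pads(h, kh, stride)
    ow, pl, pr = _same_pads(w, kw, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (n, h', w', c, kh, kw) -> subsample by stride
    win = win[:, ::stride, ::stride]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, kh * kw * c)
    return np.ascontiguousarray(cols), (oh, ow, pt, pl, xp.shape)


def _conv_forward(x, w, stride):
    kh, kw, cin, cout = w.shape
    cols, (oh, ow, _, _, _) = _im2col(x, kh, kw, stride)
    y = cols @ w.reshape(kh * kw * cin, cout)
    return y.reshape(x.shape[0], oh, ow, cout)


def _conv_backward_w(x, gy, w_shape, stride):
    kh, kw, cin, cout = w_shape
    cols, _ = _im2col(x, kh, kw, stride)
    gw = cols.T @ gy.reshape(-1, cout)
    return gw.reshape(w_shape)


def _conv_backward_x(gy, w, x_shape, stride):
    n, h, wd, cin = x_shape
    kh, kw, _, cout = w.shape
    if stride == 1 and kh % 2 == 1 and kw % 2 == 1:
        # adjoint of a stride-1 odd-kernel "same" conv is a "same" conv with
        # the spatially flipped, channel-transposed kernel
        wf = np.ascontiguousarray(w[::-1, ::-1].transpose(0, 1, 3, 2))
        return _conv_forward(gy, wf, 1)
    oh, pt, _ = _same_pads(h, kh, stride)
    ow, pl, _ = _same_pads(wd, kw, stride)
    # scatter-add per kernel offset into the padded gradient buffer
    hp = max((oh - 1) * stride + kh, h + pt)
    wp = max((ow - 1) * stride + kw, wd + pl)
    gxp = np.zeros((n, hp, wp, cin), dtype=gy.dtype)
    # g for each output location times kernel weights
    gcols = gy.reshape(n * oh * ow, cout) @ w.reshape(kh * kw * cin, cout).T
    gcols = gcols.reshape(n, oh, ow, kh, kw, cin)
    for i in range(kh):
        for j in range(kw):
            gxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride] += gcols[
                :, :, :, i, j
            ]
    return gxp[:, pt : pt + h, pl : pl + wd]


def conv2d_same(x: Tensor, w: Tensor, stride: int = 1) -> Tensor:
    """2D convolution, NHWC, "same" padding, square stride.

    The im2col matrix of the forward pass is cached for the weight gradient.
    """
    kh, kw, cin, cout = w.data.shape
    cache = {}

    def forward():
        cols, (oh, ow, _, _, _) = _im2col(x.data, kh, kw, stride)
        if w.requires_grad:
            cache["cols"] = cols
        y = cols @ w.data.reshape(kh * kw * cin, cout)
        return y.reshape(x.data.shape[0], oh, ow, cout)

    out = Tensor(forward(), parents=(x, w))

    def backward(g):
        if x.requires_grad:
            x._accum(_conv_backward_x(g, w.data, x.data.shape, stride))
        if w.requires_grad:
            gw = cache["cols"].T @ g.reshape(-1, cout)
            w._accum(gw.reshape(w.data.shape))
            cache.clear()

    out._backward = backward
    return out


def conv2d_transpose_same(x: Tensor, w: Tensor, stride: int = 2) -> Tensor:
    """Transposed (fractionally strided) convolution: exact adjoint of
    :func:`conv2d_same` with the same kernel, output spatial size = stride * input.

    Kernel layout is (kh, kw, cout, cin) — the kernel of the forward
    convolution whose adjoint this is.
    """
    n, h, wd, cin = x.data.shape
    kh, kw, cout, _ = w.data.shape
    out_shape = (n, h * stride, wd * stride, cout)
    out = Tensor(
        _conv_backward_x(x.data, w.data, out_shape, stride), parents=(x, w)
    )

    def backward(g):
        if x.requires_grad:
            x._accum(_conv_forward(g, w.data, stride))
        if w.requires_grad:
            w._accum(_conv_backward_w(g, x.data, w.data.shape, stride))

    out._backward = backward
    return out
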