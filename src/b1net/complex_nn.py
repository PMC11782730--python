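"""Complex-valued neural-network primitives.

Complex 2D convolutions, the ModReLU activation, complex Glorot
initialisation, joint-mask complex dropout and the perpendicular + L2
training loss. Two surfaces are provided:

* plain functions on numpy complex arrays (``complex_conv2d``, ``modrelu``,
  ...) — the reference semantics, convenient for testing and inference;
* autograd layer classes (``CConv2d``, ``CConvTranspose2d``, ``ModReLU``,
  ``CDropout``) built on :mod:`b1net._autograd` — used by the trainable
  encoder-decoder.

A complex tensor is carried as a (real, imaginary) pair everywhere inside
the autograd graph, so real-valued backpropagation yields the correct
gradients for every complex operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, concat, conv2d_same, conv2d_transpose_same, take_channels
from ._autograd import _conv_forward, _conv_backward_x

EPS_PERP = 1e-8
_EPS_MAG = 1e-12


# ---------------------------------------------------------------------------
# Kernel container + initialisation
# ---------------------------------------------------------------------------


@dataclass
class ComplexKernel:
    """Weights of one complex convolution layer.

    ``weights``: complex, shape (kh, kw, c_in, c_out).
    ``bias``: complex, per output channel.
    ``modrelu_bias``: real, per output channel (the learnable magnitude
    shift of the ModReLU that follows the convolution).
    """

    weights: np.ndarray
    bias: np.ndarray = None
    modrelu_bias: np.ndarray = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.complex64)
        cout = self.weights.shape[-1]
        if self.bias is None:
            self.bias = np.zeros(cout, dtype=np.complex64)
        if self.modrelu_bias is None:
            self.modrelu_bias = np.zeros(cout, dtype=np.float32)
        self.bias = np.asarray(self.bias, dtype=np.complex64)
        self.modrelu_bias = np.asarray(self.modrelu_bias, dtype=np.float32)


def complex_glorot_init(shape, seed: int) -> ComplexKernel:
    """Glorot-uniform initialisation adapted to complex weights.

    Real and imaginary parts are drawn independently from a uniform
    distribution whose variance is half the Glorot target, so that
    E[|w|^2] = 2 / (fan_in + fan_out) — the variance a real Glorot layer of
    the same shape would have.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError(f"non-positive kernel dimension in shape {shape}")
    kh, kw, cin, cout = shape
    fan_in, fan_out = kh * kw * cin, kh * kw * cout
    limit = np.sqrt(3.0 / (fan_in + fan_out))
    rng = np.random.default_rng(seed)
    re = rng.uniform(-limit, limit, size=shape)
    im = rng.uniform(-limit, limit, size=shape)
    return ComplexKernel(weights=(re + 1j * im).astype(np.complex64))


# ---------------------------------------------------------------------------
# Functional reference ops (numpy complex in / complex out)
# ---------------------------------------------------------------------------


def _as_batched(x):
    x = np.asarray(x)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected (H, W, C) or (N, H, W, C) input, got ndim={x.ndim}")


def complex_conv2d(x, kernel: ComplexKernel, stride=(1, 1), padding="same"):
    """Complex 2D convolution with "same" padding.

    output = conv(Re x, Re k) - conv(Im x, Im k)
             + i [conv(Re x, Im k) + conv(Im x, Re k)] + bias
    """
    if padding != "same":
        raise ValueError("only 'same' padding is supported")
    s = stride[0] if isinstance(stride, (tuple, list)) else stride
    if isinstance(stride, (tuple, list)) and stride[0] != stride[1]:
        raise ValueError("only square strides are supported")
    if s not in (1, 2):
        raise ValueError("stride must be (1,1) or (2,2)")
    xb, squeeze = _as_batched(x)
    w = kernel.weights
    if xb.shape[-1] != w.shape[2]:
        raise ValueError(
            f"channel mismatch: input has {xb.shape[-1]} channels, "
            f"kernel expects {w.shape[2]} (dimension c_in)"
        )
    xr, xi = np.ascontiguousarray(xb.real, dtype=np.float32), np.ascontiguousarray(
        xb.imag, dtype=np.float32
    )
    wr, wi = w.real.astype(np.float32), w.imag.astype(np.float32)
    yr = _conv_forward(xr, wr, s) - _conv_forward(xi, wi, s)
    yi = _conv_forward(xr, wi, s) + _conv_forward(xi, wr, s)
    y = yr + 1j * yi + kernel.bias
    return y[0] if squeeze else y


def complex_transposed_conv2d(x, kernel: ComplexKernel):
    """Complex transposed convolution, stride fixed at (2,2); doubles H and W.

    Exact adjoint wiring of :func:`complex_conv2d`; kernel weights are laid
    out (kh, kw, c_out, c_in).
    """
    xb, squeeze = _as_batched(x)
    w = kernel.weights  # (kh, kw, cout, cin)
    if xb.shape[-1] != w.shape[3]:
        raise ValueError(
            f"channel mismatch: input has {xb.shape[-1]} channels, "
            f"kernel expects {w.shape[3]} (dimension c_in)"
        )
    n, h, wd, _ = xb.shape
    out_shape = (n, 2 * h, 2 * wd, w.shape[2])
    xr = np.ascontiguousarray(xb.real, dtype=np.float32)
    xi = np.ascontiguousarray(xb.imag, dtype=np.float32)
    wr, wi = w.real.astype(np.float32), w.imag.astype(np.float32)
    yr = _conv_backward_x(xr, wr, out_shape, 2) - _conv_backward_x(xi, wi, out_shape, 2)
    yi = _conv_backward_x(xr, wi, out_shape, 2) + _conv_backward_x(xi, wr, out_shape, 2)
    cout = w.shape[2]
    bias = kernel.bias
    if bias.shape[0] != cout:
        if bias.any():
            raise ValueError(
                f"bias has {bias.shape[0]} entries but the transposed kernel "
                f"produces {cout} output channels (dimension c_out)"
            )
        bias = np.zeros(cout, dtype=np.complex64)
    y = yr + 1j * yi + bias
    return y[0] if squeeze else y


def modrelu(z, b):
    """ModReLU(z) = ReLU(|z| + b) * exp(i angle(z)); b broadcast per channel.

    At z = 0 the phase is undefined and the output is defined as 0.
    """
    z = np.asarray(z, dtype=np.complex64)
    mag = np.abs(z)
    gated = np.maximum(mag + np.asarray(b, dtype=np.float32), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        phasor = np.where(mag > 0, z / np.maximum(mag, _EPS_MAG), 0.0 + 0.0j)
    return (gated * phasor).astype(np.complex64)


def complex_dropout(z, rate: float, training: bool = True, seed: int = 0):
    """Dropout zeroing real and imaginary parts jointly (one Bernoulli mask).

    Surviving entries are scaled by 1/(1-rate); identity when not training.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must satisfy 0 <= rate < 1, got {rate}")
    z = np.asarray(z, dtype=np.complex64)
    if not training or rate == 0.0:
        return z.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(z.shape) >= rate
    return (z * keep / (1.0 - rate)).astype(np.complex64)


def _target_phasor(target):
    """Unit phasor of the target; 1 where the target vanishes (so that
    zero-target voxels are penalized with a plain squared residual)."""
    tmag = np.abs(target)
    u = np.where(tmag > EPS_PERP, target / np.maximum(tmag, EPS_PERP), 1.0 + 0.0j)
    return u, tmag


def perp_l2_loss(pred, target, mask=None, lambda_l2: float = 1.0) -> float:
    """Perpendicular + L2 loss on complex maps.

    The prediction is decomposed against the target phasor u = T/|T|:
    the perpendicular residual Im(u* P) (pure phase-direction error) and
    the in-line residual Re(u* P) - |T| (magnitude-direction error). The
    loss averages

        (Im(u* P))^2 + lambda (Re(u* P) - |T|)^2

    over the masked voxels. It is zero iff P = T, symmetric in magnitude
    and phase errors, and reduces exactly to the complex mean squared error
    for lambda = 1; lambda re-weights phase-perpendicular against in-line
    errors. Where the target vanishes the phasor is taken as 1, giving a
    plain squared pull toward zero.
    """
    pred = np.asarray(pred, dtype=np.complex64)
    target = np.asarray(target, dtype=np.complex64)
    if pred.shape != target.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs target {target.shape}"
        )
    if mask is None:
        mask = np.ones(pred.shape, dtype=bool)
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), pred.shape)
    if not mask.any():
        raise ValueError("empty mask")
    u, tmag = _target_phasor(target)
    proj = np.conj(u) * pred
    perp = proj.imag ** 2
    inline = (proj.real - tmag) ** 2
    return float(np.mean((perp + lambda_l2 * inline)[mask]))


# ---------------------------------------------------------------------------
# Autograd layers
# ---------------------------------------------------------------------------


class CConv2d:
    """Trainable complex convolution (+ optional stride-2 downsampling).

    Internally runs as one real convolution on stacked [Re | Im] channels
    with the block kernel [[Wr, Wi], [-Wi, Wr]], which is exactly the
    complex product written in real arithmetic.
    """

    def __init__(self, cin, cout, stride=1, kernel_size=3, seed=0):
        k = complex_glorot_init((kernel_size, kernel_size, cin, cout), seed)
        self.wr = Tensor(k.weights.real, requires_grad=True)
        self.wi = Tensor(k.weights.imag, requires_grad=True)
        self.br = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.bi = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.cout = cout

    @property
    def params(self):
        return [self.wr, self.wi, self.br, self.bi]

    def _stacked_kernel(self):
        # (kh, kw, 2*cin, 2*cout): out[:cout] = xr*wr - xi*wi,
        #                          out[cout:] = xr*wi + xi*wr
        left = concat([self.wr, -self.wi], axis=2)
        right = concat([self.wi, self.wr], axis=2)
        return concat([left, right], axis=3)

    def __call__(self, xr, xi):
        x2 = concat([xr, xi], axis=-1)
        y = conv2d_same(x2, self._stacked_kernel(), self.stride)
        yr = take_channels(y, 0, self.cout) + self.br
        yi = take_channels(y, self.cout, 2 * self.cout) + self.bi
        return yr, yi


class CConvTranspose2d:
    """Trainable complex transposed convolution, stride 2 (doubles H, W)."""

    def __init__(self, cin, cout, kernel_size=3, seed=0):
        k = complex_glorot_init((kernel_size, kernel_size, cout, cin), seed)
        self.wr = Tensor(k.weights.real, requires_grad=True)
        self.wi = Tensor(k.weights.imag, requires_grad=True)
        self.br = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.bi = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.cout = cout

    @property
    def params(self):
        return [self.wr, self.wi, self.br, self.bi]

    def _stacked_kernel(self):
        # transposed-conv kernels are laid out (kh, kw, cout, cin)
        top = concat([self.wr, self.wi], axis=2)
        bottom = concat([-self.wi, self.wr], axis=2)
        return concat([top, bottom], axis=3)

    def __call__(self, xr, xi):
        x2 = concat([xr, xi], axis=-1)
        y = conv2d_transpose_same(x2, self._stacked_kernel(), 2)
        yr = take_channels(y, 0, self.cout) + self.br
        yi = take_channels(y, self.cout, 2 * self.cout) + self.bi
        return yr, yi


class ModReLU:
    """ModReLU with a learnable real per-channel bias, initialised to 0."""

    def __init__(self, channels):
        self.b = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    @property
    def params(self):
        return [self.b]

    def __call__(self, xr, xi):
        mag = (xr.square() + xi.square() + _EPS_MAG).sqrt()
        scale = (mag + self.b).relu() / mag
        return xr * scale, xi * scale


class CDropout:
    """Joint real/imag dropout; identity when not training."""

    def __init__(self, rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must satisfy 0 <= rate < 1, got {rate}")
        self.rate = rate

    params: list = []

    def __call__(self, xr, xi, training=False, rng=None):
        if not training or self.rate == 0.0:
            return xr, xi
        keep = (rng.random(xr.data.shape) >= self.rate).astype(np.float32)
        m = Tensor(keep / (1.0 - self.rate))
        return xr * m, xi * m


def perp_l2_loss_autograd(pr: Tensor, pi: Tensor, target, mask, lambda_l2=1.0):
    """Autograd version of :func:`perp_l2_loss` (target, mask are constants)."""
    target = np.asarray(target, dtype=np.complex64)
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), target.shape)
    if not mask.any():
        raise ValueError("empty mask")
    u, tmag = _target_phasor(target)
    w = Tensor(mask.astype(np.float32) / mask.sum())
    ur = Tensor(np.ascontiguousarray(u.real))
    ui = Tensor(np.ascontiguousarray(u.imag))
    # conj(u) * P: real part ur Pr + ui Pi, imaginary part ur Pi - ui Pr
    perp = (ur * pi - ui * pr).square()
    inline = (ur * pr + ui * pi - Tensor(tmag)).square()
    return ((perp + lambda_l2 * inline) * w).sum()
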