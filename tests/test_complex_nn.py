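"""Oracle tests for the complex-valued layer primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from b1net._autograd import Tensor
from b1net.complex_nn import (
    CConv2d,
    ComplexKernel,
    ModReLU,
    complex_conv2d,
    complex_dropout,
    complex_glorot_init,
    complex_transposed_conv2d,
    modrelu,
    perp_l2_loss,
    perp_l2_loss_autograd,
)


def brute_complex_conv(x, w, stride):
    """Brute-force complex multiply-accumulate with 'same' padding."""
    h, wd, ci = x.shape
    kh, kw, _, co = w.shape
    oh, ow = -(-h // stride), -(-wd // stride)
    pt = max((oh - 1) * stride + kh - h, 0) // 2
    pl = max((ow - 1) * stride + kw - wd, 0) // 2
    y = np.zeros((oh, ow, co), dtype=complex)
    for a in range(oh):
        for b in range(ow):
            for i in range(kh):
                for j in range(kw):
                    r, c = a * stride + i - pt, b * stride + j - pl
                    if 0 <= r < h and 0 <= c < wd:
                        y[a, b] += x[r, c] @ w[i, j]
    return y


class TestComplexConv:
    def test_scalar_complex_product(self):
        # 1x1 input z = 2+i, 1x1 kernel w = 1+i -> (2+i)(1+i) = 1+3i
        x = np.array([[[2 + 1j]]])
        k = ComplexKernel(weights=np.array([[[[1 + 1j]]]]))
        out = complex_conv2d(x, k)
        assert np.allclose(out, np.array([[[1 + 3j]]]), atol=1e-6)

    def test_real_inputs_stay_real(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 5, 2)).astype(complex)
        k = ComplexKernel(weights=rng.normal(size=(3, 3, 2, 2)).astype(complex))
        assert np.allclose(complex_conv2d(x, k).imag, 0, atol=1e-6)

    def test_identity_kernel(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 4, 1)) + 1j * rng.normal(size=(4, 4, 1))
        k = ComplexKernel(weights=np.ones((1, 1, 1, 1), dtype=complex))
        assert np.allclose(complex_conv2d(x, k), x, atol=1e-6)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_matches_brute_force_on_random_instances(self, stride):
        rng = np.random.default_rng(42)
        for _ in range(100):
            h, wd = rng.integers(1, 6, 2)
            ci, co = rng.integers(1, 3, 2)
            kh = int(rng.choice([1, 3]))
            x = rng.normal(size=(h, wd, ci)) + 1j * rng.normal(size=(h, wd, ci))
            w = rng.normal(size=(kh, kh, ci, co)) + 1j * rng.normal(
                size=(kh, kh, ci, co)
            )
            k = ComplexKernel(weights=w)
            got = complex_conv2d(x, k, stride=(stride, stride))
            assert np.allclose(got, brute_complex_conv(x, w, stride), atol=1e-5)

    def test_channel_mismatch_names_dimension(self):
        x = np.zeros((4, 4, 3), dtype=complex)
        k = ComplexKernel(weights=np.zeros((3, 3, 2, 2), dtype=complex))
        with pytest.raises(ValueError, match="c_in"):
            complex_conv2d(x, k)


class TestTransposedConv:
    def test_doubles_spatial_size(self):
        x = np.zeros((5, 7, 2), dtype=complex)
        k = ComplexKernel(weights=np.zeros((3, 3, 3, 2), dtype=complex))
        assert complex_transposed_conv2d(x, k).shape == (10, 14, 3)

    def test_zero_input_gives_bias(self):
        x = np.zeros((2, 2, 1), dtype=complex)
        k = ComplexKernel(
            weights=np.ones((3, 3, 1, 1), dtype=complex), bias=np.array([2 - 1j])
        )
        out = complex_transposed_conv2d(x, k)
        assert np.allclose(out, 2 - 1j)

    def test_degenerate_size_matches_conv(self):
        # on a 1x1 input with a 1x1 kernel the populated output entry equals
        # the stride-1 convolution of that instance
        x = np.array([[[1.5 - 0.5j]]])
        k = ComplexKernel(weights=np.array([[[[0.5 + 2j]]]]))
        conv = complex_conv2d(x, k)
        tk = ComplexKernel(weights=np.array([[[[0.5 + 2j]]]]))
        up = complex_transposed_conv2d(x, tk)
        assert np.allclose(up[0, 0], conv[0, 0], atol=1e-6)
        assert np.allclose(up[1, 1], 0, atol=1e-6)


class TestModReLU:
    def test_closed_form_value(self):
        out = modrelu(np.array(3 + 4j), b=-1.0)
        assert np.allclose(out, 2.4 + 3.2j, atol=1e-6)

    def test_clamps_below_bias(self):
        z = np.array([0.5 + 0.5j, 1e-3, -0.2j])
        assert np.allclose(modrelu(z, b=-2.0), 0)

    def test_identity_for_zero_bias(self):
        z = np.array([1 + 0j, 0.3 - 0.4j])
        assert np.allclose(modrelu(z, b=0.0), z, atol=1e-6)

    def test_zero_input_maps_to_zero(self):
        assert modrelu(np.array(0j), b=1.0) == 0

    def test_closed_form_on_many_random_points(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=10 ** 5) + 1j * rng.normal(size=10 ** 5)
        b = -0.5
        got = modrelu(z, b)
        expect = np.maximum(np.abs(z) + b, 0) * np.exp(1j * np.angle(z))
        assert np.allclose(got, expect, atol=1e-5)

    @settings(derandomize=True, max_examples=50)
    @given(
        re=st.floats(-5, 5),
        im=st.floats(-5, 5),
        b=st.floats(-2, 2),
        phi=st.floats(0, 2 * np.pi),
    )
    def test_phase_equivariance(self, re, im, b, phi):
        z = np.complex128(re + 1j * im)
        rot = np.exp(1j * phi)
        assert np.allclose(
            modrelu(np.array(rot * z), b), rot * modrelu(np.array(z), b), atol=1e-5
        )


class TestGlorotInit:
    def test_deterministic_for_fixed_seed(self):
        a = complex_glorot_init((3, 3, 4, 8), seed=5)
        b = complex_glorot_init((3, 3, 4, 8), seed=5)
        assert np.array_equal(a.weights, b.weights)

    def test_different_seeds_differ(self):
        a = complex_glorot_init((3, 3, 4, 8), seed=5)
        b = complex_glorot_init((3, 3, 4, 8), seed=6)
        assert not np.array_equal(a.weights, b.weights)

    def test_variance_matches_glorot_target(self):
        # E|w|^2 = 2 / (fan_in + fan_out), Monte-Carlo over ~1e5 draws
        k = complex_glorot_init((3, 3, 64, 64), seed=0)  # 36864 weights
        k2 = complex_glorot_init((3, 3, 64, 64), seed=1)
        k3 = complex_glorot_init((3, 3, 64, 64), seed=2)
        samples = np.concatenate(
            [np.abs(k.weights.ravel()) ** 2 for k in (k, k2, k3)]
        )
        target = 2.0 / (9 * 64 + 9 * 64)
        assert abs(samples.mean() - target) < 0.05 * target

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            complex_glorot_init((3, 3, 0, 4), seed=0)


class TestComplexDropout:
    def test_identity_when_not_training(self):
        z = np.arange(12).reshape(3, 4).astype(complex)
        assert np.array_equal(complex_dropout(z, 0.5, training=False, seed=0), z)

    def test_identity_for_zero_rate(self):
        z = np.ones((4, 4), dtype=complex)
        assert np.array_equal(complex_dropout(z, 0.0, training=True, seed=0), z)

    def test_rejects_rate_one(self):
        with pytest.raises(ValueError):
            complex_dropout(np.ones(3, dtype=complex), 1.0)

    def test_zeroed_fraction_and_joint_masking(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=10 ** 6) + 1j * rng.normal(size=10 ** 6)
        out = complex_dropout(z, 0.5, training=True, seed=3)
        zeroed = out == 0
        assert abs(zeroed.mean() - 0.5) < 0.002
        # real and imaginary parts vanish jointly, survivors scaled by 2
        assert np.allclose(out[~zeroed], 2 * z[~zeroed], atol=1e-5)


class TestPerpL2Loss:
    def test_zero_for_perfect_prediction(self):
        rng = np.random.default_rng(11)
        t = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        assert perp_l2_loss(t, t) < 1e-12

    def test_orthogonal_prediction_value(self):
        # T = 1, P = i: perpendicular residual 1, in-line residual -1
        t = np.ones((3, 3), dtype=complex)
        p = 1j * np.ones((3, 3))
        assert np.isclose(perp_l2_loss(p, t, lambda_l2=1.0), 2.0)

    def test_scaled_parallel_prediction_closed_form(self):
        rng = np.random.default_rng(12)
        t = rng.normal(size=(5, 5)) + 1j * rng.normal(size=(5, 5))
        c = 1.7
        lam = 0.5
        expect = lam * (c - 1) ** 2 * np.mean(np.abs(t) ** 2)
        assert np.isclose(perp_l2_loss(c * t, t, lambda_l2=lam), expect, rtol=1e-5)

    def test_lambda_one_equals_complex_mse(self):
        rng = np.random.default_rng(13)
        t = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        p = t + 0.3 * (rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8)))
        assert np.isclose(
            perp_l2_loss(p, t, lambda_l2=1.0), np.mean(np.abs(p - t) ** 2), rtol=1e-5
        )

    def test_antiparallel_prediction_is_penalized(self):
        t = np.full((4, 4), 1 + 1j)
        assert perp_l2_loss(-t, t) > 1.0

    def test_empty_mask_rejected(self):
        t = np.ones((3, 3), dtype=complex)
        with pytest.raises(ValueError, match="mask"):
            perp_l2_loss(t, t, mask=np.zeros((3, 3), bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            perp_l2_loss(np.ones((2, 2), complex), np.ones((3, 3), complex))


def test_gradient_through_conv_and_modrelu_matches_finite_differences():
    """Autodiff gradient of the loss through one complex convolution +
    ModReLU agrees with central finite differences to 1e-4 relative."""
    rng = np.random.default_rng(21)
    conv = CConv2d(2, 3, stride=1, seed=0)
    act = ModReLU(3)
    for p in conv.params + act.params:
        p.data = p.data.astype(np.float64)
    act.b.data += 0.1  # probe a non-degenerate gate point
    x = rng.normal(size=(1, 5, 5, 2)) + 1j * rng.normal(size=(1, 5, 5, 2))
    t = rng.normal(size=(1, 5, 5, 3)) + 1j * rng.normal(size=(1, 5, 5, 3))
    mask = np.ones(t.shape, bool)
    params = conv.params + act.params

    def build():
        for p in params:
            p.grad = None
        pr, pi = act(*conv(Tensor(x.real), Tensor(x.imag)))
        return perp_l2_loss_autograd(pr, pi, t, mask)

    loss = build()
    loss.backward()
    grads = [p.grad.copy() for p in params]
    eps = 1e-6
    for p, g in zip(params, grads):
        flat_idx = list(np.ndindex(p.data.shape))
        for idx in flat_idx[:: max(1, len(flat_idx) // 10)]:
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = float(build().data)
            p.data[idx] = orig - eps
            lm = float(build().data)
            p.data[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - g[idx]) <= 1e-4 * max(1.0, abs(num))


def test_dropout_off_and_identity_kernel_compose_to_identity():
    rng = np.random.default_rng(22)
    z = rng.normal(size=(6, 6, 1)) + 1j * rng.normal(size=(6, 6, 1))
    k = ComplexKernel(weights=np.ones((1, 1, 1, 1), dtype=complex))
    out = complex_dropout(complex_conv2d(z, k), 0.4, training=False, seed=0)
    assert np.allclose(out, z, atol=1e-6)
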