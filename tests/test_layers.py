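"""Layer-semantics oracles: convolution, pooling, batch norm, softmax."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histofuse.layers import (
    BatchNormParams,
    batchnorm,
    conv2d,
    cross_entropy,
    global_maxpool,
    maxpool,
    relu,
    softmax,
)


def conv_oracle(x, w, b, stride, padding):
    """Independent nested-loop cross-correlation (no im2col)."""
    H, W, Cin = x.shape
    kh, kw, _, Cout = w.shape
    sh, sw = stride
    if padding == "same":
        oh, ow = -(-H // sh), -(-W // sw)
        ph = max((oh - 1) * sh + kh - H, 0)
        pw = max((ow - 1) * sw + kw - W, 0)
        xp = np.pad(x, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0)))
    else:
        xp = x
        oh, ow = (H - kh) // sh + 1, (W - kw) // sw + 1
    y = np.zeros((oh, ow, Cout))
    for i in range(oh):
        for j in range(ow):
            patch = xp[i * sh:i * sh + kh, j * sw:j * sw + kw, :]
            for c in range(Cout):
                y[i, j, c] = (patch * w[:, :, :, c]).sum() + b[c]
    return y


class TestConv:
    def test_identity_kernel(self, rng):
        x = rng.random((5, 5, 1))
        w = np.ones((1, 1, 1, 1))
        assert np.allclose(conv2d(x, w, np.zeros(1)), x)

    def test_all_ones_center_value(self):
        x = np.ones((3, 3, 1))
        w = np.ones((3, 3, 1, 1))
        y = conv2d(x, w, np.zeros(1), padding="same")
        assert y[1, 1, 0] == 9.0

    def test_zero_input_gives_bias(self, rng):
        x = np.zeros((4, 4, 2))
        w = rng.random((3, 3, 2, 3))
        b = np.array([1.0, -2.0, 0.5])
        y = conv2d(x, w, b, padding="same")
        assert np.allclose(y, np.broadcast_to(b, y.shape))

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            conv2d(rng.random((4, 4, 3)), rng.random((3, 3, 2, 4)), np.zeros(4))

    @pytest.mark.parametrize("stride,padding", [
        ((1, 1), "same"), ((2, 2), "same"), ((1, 1), "valid"), ((2, 1), "valid"),
    ])
    def test_against_nested_loop_oracle(self, stride, padding, rng):
        x = rng.standard_normal((8, 8, 2))
        w = rng.standard_normal((3, 3, 2, 4))
        b = rng.standard_normal(4)
        got = conv2d(x, w, b, stride=stride, padding=padding)
        want = conv_oracle(x, w, b, stride, padding)
        assert np.abs(got - want).max() <= 1e-5

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), kh=st.sampled_from([1, 3, 5]))
    def test_oracle_property_random_kernels(self, seed, kh):
        r = np.random.default_rng(seed)
        x = r.standard_normal((8, 8, 2))
        w = r.standard_normal((kh, kh, 2, 3))
        b = r.standard_normal(3)
        got = conv2d(x, w, b, stride=(1, 1), padding="same")
        want = conv_oracle(x, w, b, (1, 1), "same")
        assert np.abs(got - want).max() <= 1e-5

    def test_grouped_conv_splits_channels(self, rng):
        x = rng.standard_normal((4, 4, 4))
        w = rng.standard_normal((1, 1, 2, 4))  # 2 groups x 2 in x 2 out
        y = conv2d(x, w, np.zeros(4), groups=2)
        first = conv2d(x[:, :, :2], w[:, :, :, :2], np.zeros(2))
        assert np.allclose(y[:, :, :2], first)


class TestReLU:
    def test_examples(self):
        assert np.array_equal(relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])
        assert (relu(-np.ones((3, 3))) == 0).all()
        x = np.abs(np.random.default_rng(0).standard_normal((4, 4)))
        assert np.array_equal(relu(x), x)


class TestMaxPool:
    def test_2x2_window(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert maxpool(x, 2, 2)[0, 0, 0] == 4.0

    def test_constant_input(self):
        x = np.full((4, 4, 2), 3.5)
        assert (maxpool(x, 2, 2) == 3.5).all()

    def test_window_one_stride_one_is_identity(self, rng):
        x = rng.random((5, 5, 2))
        assert np.allclose(maxpool(x, 1, 1), x)

    def test_oversized_window_raises(self, rng):
        with pytest.raises(ValueError):
            maxpool(rng.random((3, 3, 1)), 5, 1, padding="valid")

    def test_global_maxpool(self, rng):
        x = rng.random((6, 7, 3))
        assert np.allclose(global_maxpool(x)[0, 0], x.max(axis=(0, 1)))


class TestBatchNorm:
    def test_two_value_batch(self):
        x = np.array([[0.0], [2.0]])
        p = BatchNormParams(np.ones(1), np.zeros(1), epsilon=1e-12)
        assert np.allclose(batchnorm(x, p), [[-1.0], [1.0]], atol=1e-5)

    def test_normalisation_contract(self, rng):
        x = rng.standard_normal((64, 3)) * 5 + 2
        p = BatchNormParams(np.ones(3), np.zeros(3))
        y = batchnorm(x, p)
        assert np.allclose(y.mean(axis=0), 0, atol=1e-6)
        assert np.allclose(y.var(axis=0), 1, atol=1e-3)

    def test_affine_contract(self, rng):
        x = rng.standard_normal((256, 2))
        x = (x - x.mean(0)) / x.std(0)
        p = BatchNormParams(np.full(2, 2.0), np.full(2, 3.0))
        y = batchnorm(x, p)
        assert np.allclose(y.mean(axis=0), 3, atol=1e-2)
        assert np.allclose(y.std(axis=0), 2, atol=1e-2)

    def test_batch_of_one_rejected(self):
        p = BatchNormParams(np.ones(1), np.zeros(1))
        with pytest.raises(ValueError):
            batchnorm(np.ones((1, 1)), p, mode="train")

    def test_epsilon_positive(self):
        with pytest.raises(ValueError):
            BatchNormParams(np.ones(1), np.zeros(1), epsilon=0.0)


class TestSoftmax:
    def test_analytic_values(self):
        assert np.allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5])
        assert np.allclose(softmax(np.log([1.0, 3.0])), [0.25, 0.75])
        assert np.allclose(softmax(np.array([7.0])), [1.0])

    def test_rows_sum_to_one(self, rng):
        z = rng.standard_normal((50, 8)) * 30  # large logits: overflow-safe
        p = softmax(z)
        assert np.abs(p.sum(axis=1) - 1).max() <= 1e-6
        assert (p > 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([]))

    def test_cross_entropy_gradient_is_p_minus_y(self):
        z = np.array([[1.0, 2.0, 0.5]])
        loss, g = cross_entropy(z, np.array([1]))
        p = softmax(z)
        assert np.allclose(g, p - np.array([[0, 1, 0]]))
        assert loss == pytest.approx(-np.log(p[0, 1]))
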