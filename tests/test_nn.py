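"""Convolution primitives against brute-force and finite-difference oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from har2dcnn import nn
from har2dcnn.errors import GeometryError
from reference_impl import conv2d_loops, maxpool_loops


class TestConvForward:
    def test_identity_kernel_reproduces_input(self, rng):
        x = rng.normal(size=(1, 4, 6))
        w = np.ones((1, 1, 1, 1))
        out = nn.conv2d_forward(x, w, np.zeros(1))
        np.testing.assert_allclose(out, x)

    def test_valid_convolution_shape(self, rng):
        x = rng.normal(size=(1, 4, 24))
        w = rng.normal(size=(1, 8, 3, 3))
        assert nn.conv2d_forward(x, w, np.zeros(8)).shape == (8, 2, 22)

    def test_kernel_larger_than_input_is_a_geometry_error(self, rng):
        with pytest.raises(GeometryError):
            nn.conv2d_forward(
                rng.normal(size=(1, 2, 5)), rng.normal(size=(1, 1, 3, 3)), np.zeros(1)
            )

    @pytest.mark.parametrize("strides", [(1, 1), (1, 2), (2, 3)])
    def test_matches_nested_loop_oracle(self, rng, strides):
        x = rng.normal(size=(2, 6, 9))
        w = rng.normal(size=(2, 3, 2, 2))
        b = rng.normal(size=3)
        got = nn.conv2d_forward(x, w, b, strides)
        np.testing.assert_allclose(got, conv2d_loops(x, w, b, strides), atol=1e-12)

    def test_batched_equals_per_sample(self, rng):
        x = rng.normal(size=(5, 2, 5, 7))
        w = rng.normal(size=(2, 4, 2, 3))
        b = rng.normal(size=4)
        batch = nn.conv2d_forward(x, w, b)
        for i in range(5):
            np.testing.assert_allclose(batch[i], nn.conv2d_forward(x[i], w, b))

    def test_linearity_in_input(self, rng):
        w = rng.normal(size=(2, 3, 2, 2))
        b = np.zeros(3)
        x1, x2 = rng.normal(size=(2, 2, 5, 6))
        lhs = nn.conv2d_forward(2.0 * x1 + 3.0 * x2, w, b)
        rhs = 2.0 * nn.conv2d_forward(x1, w, b) + 3.0 * nn.conv2d_forward(x2, w, b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    @given(
        h=st.integers(1, 8),
        w=st.integers(1, 12),
        kh=st.integers(1, 4),
        kw=st.integers(1, 4),
        hs=st.integers(1, 3),
        ws=st.integers(1, 3),
    )
    def test_output_shape_formula(self, h, w, kh, kw, hs, ws):
        if kh > h or kw > w:
            return
        x = np.zeros((1, h, w))
        kern = np.zeros((1, 1, kh, kw))
        out = nn.conv2d_forward(x, kern, np.zeros(1), (hs, ws))
        assert out.shape == (1, (h - kh) // hs + 1, (w - kw) // ws + 1)


class TestConv1d:
    def test_width_one_identity(self, rng):
        x = rng.normal(size=(1, 2, 24))
        w = np.ones((1, 1, 1, 1))
        np.testing.assert_allclose(nn.conv1d_forward(x, w, np.zeros(1)), x)

    def test_shape_keeps_height(self, rng):
        x = rng.normal(size=(1, 2, 24))
        w = rng.normal(size=(1, 4, 1, 3))
        assert nn.conv1d_forward(x, w, np.zeros(4)).shape == (4, 2, 22)

    def test_rejects_tall_kernels(self, rng):
        with pytest.raises(GeometryError):
            nn.conv1d_forward(
                rng.normal(size=(1, 2, 8)), rng.normal(size=(1, 1, 2, 3)), np.zeros(1)
            )

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(1, 3, 10))
        w = rng.normal(size=(1, 2, 1, 4))
        b = rng.normal(size=2)
        np.testing.assert_allclose(
            nn.conv1d_forward(x, w, b), conv2d_loops(x, w, b), atol=1e-12
        )


class TestRelu:
    def test_definition(self):
        z = np.array([-2.0, 0.0, 3.5])
        np.testing.assert_array_equal(nn.relu(z), [0.0, 0.0, 3.5])
        np.testing.assert_array_equal(nn.relu_grad(z), [0.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        z = rng.normal(size=(3, 4))
        np.testing.assert_array_equal(nn.relu(nn.relu(z)), nn.relu(z))


class TestMaxPool:
    def test_single_tile(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        out, arg = nn.maxpool_forward(x, (2, 2))
        assert out[0, 0, 0] == 4.0

    def test_tie_takes_first_index(self):
        x = np.full((1, 2, 2), 7.0)
        out, arg = nn.maxpool_forward(x, (2, 2))
        assert out[0, 0, 0] == 7.0
        assert arg[0, 0, 0] == 0

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(3, 4, 6))
        out, _ = nn.maxpool_forward(x, (2, 2))
        np.testing.assert_array_equal(out, maxpool_loops(x, (2, 2)))

    def test_non_dividing_pool_is_a_geometry_error(self, rng):
        with pytest.raises(GeometryError):
            nn.maxpool_forward(rng.normal(size=(1, 5, 6)), (2, 2))

    def test_backward_routes_gradient_to_argmax(self, rng):
        x = rng.normal(size=(2, 4, 4))
        out, arg = nn.maxpool_forward(x, (2, 2))
        dout = rng.normal(size=out.shape)
        dx = nn.maxpool_backward(dout, arg, (2, 2), x.shape)
        assert dx.shape == x.shape
        # gradient mass is conserved and lands only on the max positions
        np.testing.assert_allclose(dx.sum(), dout.sum())
        assert np.count_nonzero(dx) <= dout.size
        mask = dx != 0
        np.testing.assert_array_equal(
            nn.maxpool_forward(np.where(mask, x, -np.inf), (2, 2))[0], out
        )


class TestBackward:
    def test_zero_delta_gives_zero_everything(self, rng):
        x = rng.normal(size=(1, 4, 5))
        w = rng.normal(size=(1, 2, 2, 2))
        z = nn.conv2d_forward(x, w, np.zeros(2))
        delta = np.zeros_like(z)
        np.testing.assert_array_equal(
            nn.conv_backward_delta(delta, w, (1, 1), x), np.zeros_like(x)
        )
        dw, db = nn.conv_weight_grad(delta, x, (2, 2))
        assert not dw.any() and not db.any()

    def test_identity_kernel_passes_delta_through(self, rng):
        x = np.abs(rng.normal(size=(1, 3, 3))) + 0.1  # positive -> relu_grad = 1
        w = np.ones((1, 1, 1, 1))
        delta = rng.normal(size=(1, 3, 3))
        np.testing.assert_allclose(
            nn.conv_backward_delta(delta, w, (1, 1), x), delta
        )

    def test_unit_impulse_weight_grad_is_the_input_patch(self, rng):
        x = rng.normal(size=(1, 5, 5))
        delta = np.zeros((1, 3, 3))
        delta[0, 1, 2] = 1.0
        dw, db = nn.conv_weight_grad(delta, x, (3, 3))
        np.testing.assert_allclose(dw[0, 0], x[0, 1:4, 2:5])
        assert db[0] == 1.0

    def test_conv_chain_gradients_match_finite_differences(self, rng):
        """Analytic residual backprop + weight grads vs central differences
        through a conv-relu-conv-relu-dense-softmax chain."""
        x = rng.normal(size=(1, 4, 6))
        params = {
            "w1": rng.normal(size=(1, 3, 2, 2)) * 0.5,
            "b1": rng.normal(size=3) * 0.1,
            "w2": rng.normal(size=(3, 2, 2, 3)) * 0.5,
            "b2": rng.normal(size=2) * 0.1,
        }
        feat_dim = 2 * 2 * 3  # (maps, h, w) after the two conv layers
        wd = rng.normal(size=(3, feat_dim)) * 0.5
        y = 1

        def forward():
            z1 = nn.conv2d_forward(x, params["w1"], params["b1"])
            a1 = nn.relu(z1)
            z2 = nn.conv2d_forward(a1, params["w2"], params["b2"])
            a2 = nn.relu(z2)
            probs = nn.dense_softmax_forward(a2.reshape(-1), wd, np.zeros(3))
            return z1, a1, z2, a2, probs

        z1, a1, z2, a2, probs = forward()
        dlogits = probs.copy()
        dlogits[y] -= 1.0
        dfeat = (dlogits[None] @ wd).reshape(a2.shape)
        delta2 = dfeat * nn.relu_grad(z2)
        dw2, db2 = nn.conv_weight_grad(delta2, a1, (2, 3))
        delta1 = nn.conv_backward_delta(delta2, params["w2"], (1, 1), z1)
        dw1, db1 = nn.conv_weight_grad(delta1, x, (2, 2))

        fd = nn.finite_difference_grads(
            lambda: nn.cross_entropy(forward()[4], y), params
        )
        for analytic, name in [(dw1, "w1"), (db1, "b1"), (dw2, "w2"), (db2, "b2")]:
            scale = max(np.max(np.abs(fd[name])), 1e-8)
            assert np.max(np.abs(analytic - fd[name])) / scale < 1e-6


class TestSoftmaxDense:
    def test_zero_logits_are_uniform(self):
        probs = nn.dense_softmax_forward(np.zeros(4), np.zeros((4, 4)), np.zeros(4))
        np.testing.assert_allclose(probs, 0.25)

    def test_shift_invariance(self, rng):
        logits = rng.normal(size=7)
        np.testing.assert_allclose(
            nn.softmax(logits), nn.softmax(logits + 123.456), atol=1e-12
        )

    def test_matches_direct_formula_at_low_magnitude(self, rng):
        logits = rng.normal(size=5)
        direct = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(nn.softmax(logits), direct, atol=1e-12)

    def test_output_is_a_simplex_point_for_extreme_logits(self):
        probs = nn.softmax(np.array([1e4, -1e4, 0.0]))
        assert np.all(probs >= 0) and abs(probs.sum() - 1.0) < 1e-12


class TestFiniteDifferences:
    def test_quadratic_is_exact_to_truncation_order(self):
        params = {"t": np.array([3.0])}
        fd = nn.finite_difference_grads(
            lambda: float(params["t"][0] ** 2), params, epsilon=1e-5
        )
        np.testing.assert_allclose(fd["t"], [6.0], atol=1e-8)

    def test_linear_is_exact(self):
        params = {"t": np.array([1.0, -2.0])}
        coeff = np.array([4.0, 0.5])
        fd = nn.finite_difference_grads(
            lambda: float(coeff @ params["t"]), params, epsilon=1e-6
        )
        np.testing.assert_allclose(fd["t"], coeff, atol=1e-9)
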