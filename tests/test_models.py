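"""Parameter accounting, network assembly, sharing and training."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from har2dcnn import nn
from har2dcnn.data import ActionPictureSet
from har2dcnn.errors import ConfigurationError, ParameterError
from har2dcnn.models import (
    ConvLayerSpec,
    Network,
    NetworkSpec,
    TrainingConfig,
    build_network,
    compact_stack,
    count_conv_params,
    count_layer_params,
    fit,
    reference_stack,
    train,
)


def _tiny_spec(shared=True, maps=3, classes=3, rows=4, window=12):
    stack = (
        ConvLayerSpec("c1", (2, 3), 1, maps),
        ConvLayerSpec("c2", (2, 3), maps, maps + 1),
    )
    return NetworkSpec(
        axis_rows=rows,
        window=window,
        conv_stack=stack,
        n_classes=classes,
        class_labels=tuple(f"k{i}" for i in range(classes)),
        shared=shared,
    )


class TestParamCounting:
    @pytest.mark.parametrize(
        "in_maps,out_maps,kernel,expected",
        [
            (1, 64, (3, 3), 640),
            (64, 64, (3, 3), 36928),
            (64, 64, (5, 1), 20544),
            (1, 1, (1, 1), 2),
        ],
    )
    def test_layer_counts(self, in_maps, out_maps, kernel, expected):
        spec = ConvLayerSpec("l", kernel, in_maps, out_maps)
        assert count_layer_params(spec) == expected

    def test_reference_stack_totals(self):
        stack = reference_stack()
        spec = lambda shared: NetworkSpec(
            axis_rows=16, window=24, conv_stack=stack, n_classes=5, shared=shared
        )
        assert count_conv_params(spec(False)) == 235968
        assert count_conv_params(spec(True)) == 78656
        assert 235968 == 3 * 78656

    def test_single_branch_makes_sharing_a_noop(self):
        stack = (ConvLayerSpec("c1", (1, 3), 1, 4),)
        kw = dict(
            axis_rows=2, window=12, conv_stack=stack, n_classes=2,
            n_axis_branches=1,
        )
        assert count_conv_params(NetworkSpec(shared=False, **kw)) == count_conv_params(
            NetworkSpec(shared=True, **kw)
        )

    @given(
        maps=st.lists(st.integers(1, 8), min_size=1, max_size=4),
        kh=st.integers(1, 3),
        kw=st.integers(1, 3),
    )
    def test_sharing_identity_for_arbitrary_stacks(self, maps, kh, kw):
        """Non-shared conv parameters are exactly branch-count times the
        shared count for any stack of identical tri-axial branches."""
        stack, prev = [], 1
        for i, m in enumerate(maps):
            stack.append(ConvLayerSpec(f"c{i}", (kh, kw), prev, m))
            prev = m
        kw_args = dict(
            axis_rows=3 * kh + len(maps), window=3 * kw + len(maps) + 10,
            conv_stack=tuple(stack), n_classes=2,
        )
        non_shared = count_conv_params(NetworkSpec(shared=False, **kw_args))
        shared = count_conv_params(NetworkSpec(shared=True, **kw_args))
        assert non_shared == 3 * shared

    def test_infeasible_stack_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            NetworkSpec(
                axis_rows=4, window=24, conv_stack=reference_stack(8), n_classes=3
            )


class TestBuildNetwork:
    def test_shared_store_has_exactly_the_counted_parameters(self):
        spec = _tiny_spec(shared=True)
        net = build_network(spec, seed=0)
        assert net.n_conv_params() == count_conv_params(spec)

    def test_non_shared_has_three_distinct_parameter_sets(self):
        net = build_network(_tiny_spec(shared=False), seed=0)
        prefixes = {n.split(".")[0] for n in net.conv_param_names()}
        assert prefixes == {"axis_x", "axis_y", "axis_z"}

    def test_same_seed_gives_bit_identical_weights(self):
        a = build_network(_tiny_spec(), seed=42)
        b = build_network(_tiny_spec(), seed=42)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_scalar_branch_requires_time_only_kernels(self):
        with pytest.raises(ConfigurationError):
            NetworkSpec(
                axis_rows=4, window=12,
                conv_stack=(ConvLayerSpec("c1", (2, 3), 1, 2),),
                n_classes=2, scalar_rows=2,
                scalar_conv_stack=(ConvLayerSpec("s1", (2, 3), 1, 2),),
            )


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        net = build_network(_tiny_spec(), seed=1)
        xa = rng.normal(size=(5, 3, 4, 12))
        probs = net.forward(xa)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs > 0).all()

    def test_shared_net_treats_identical_pictures_identically(self, rng):
        """Swapping two identical pictures cannot change a shared net's
        output, because the branches reference one parameter set."""
        net = build_network(_tiny_spec(shared=True), seed=2)
        pic = rng.normal(size=(4, 12))
        xa = np.stack([pic, pic, rng.normal(size=(4, 12))])[None]
        swapped = xa[:, [1, 0, 2]]
        np.testing.assert_allclose(net.forward(xa), net.forward(swapped), atol=1e-12)

    def test_forward_composes_the_core_ops(self, rng):
        """A shared 2-layer net must equal manual composition of the conv,
        relu, flatten and dense-softmax primitives."""
        spec = _tiny_spec(shared=True)
        net = build_network(spec, seed=3)
        xa = rng.normal(size=(1, 3, 4, 12))
        feats = []
        for b in range(3):
            x = xa[0, b][None]
            for ls in spec.conv_stack:
                x = nn.relu(
                    nn.conv2d_forward(
                        x, net.params[f"axis.{ls.name}.w"],
                        net.params[f"axis.{ls.name}.b"], ls.strides,
                    )
                )
            feats.append(x.reshape(-1))
        manual = nn.dense_softmax_forward(
            np.concatenate(feats), net.params["dense.w"], net.params["dense.b"]
        )
        np.testing.assert_allclose(net.forward(xa)[0], manual, atol=1e-12)

    def test_forward_is_deterministic(self, rng):
        net = build_network(_tiny_spec(), seed=4)
        xa = rng.normal(size=(2, 3, 4, 12))
        np.testing.assert_array_equal(net.forward(xa), net.forward(xa))


class TestTraining:
    def _data(self, rng, n=12, spec=None):
        spec = spec or _tiny_spec()
        xa = rng.normal(size=(n, 3, spec.axis_rows, spec.window))
        y = rng.integers(0, spec.n_classes, size=n)
        return xa, y

    def test_zero_learning_rate_stops_after_one_epoch(self, rng):
        spec = _tiny_spec()
        net = build_network(spec, seed=5)
        before = {k: v.copy() for k, v in net.params.items()}
        xa, y = self._data(rng)
        history = fit(net, xa, None, y, TrainingConfig(
            learning_rate=0.0, epochs=10, threshold=1e-12, seed=0))
        assert len(history) == 1
        for k in net.params:
            np.testing.assert_array_equal(net.params[k], before[k])

    def test_single_sample_loss_is_non_increasing(self, rng):
        spec = _tiny_spec()
        net = build_network(spec, seed=6)
        xa = rng.normal(size=(1, 3, 4, 12))
        y = np.array([1])
        history = fit(net, xa, None, y, TrainingConfig(
            learning_rate=0.005, epochs=10, batch_size=1, seed=0))
        diffs = np.diff(history)
        assert (diffs <= 1e-12).all()

    def test_shared_gradient_is_the_sum_over_branches(self, rng):
        """The analytic gradient of a shared 3-branch net must match finite
        differences through the full network — which only holds if the
        shared stack accumulates all three branch contributions."""
        spec = _tiny_spec(shared=True, maps=2)
        net = build_network(spec, seed=7)
        xa = rng.normal(size=(2, 3, 4, 12))
        y = np.array([0, 2])
        _, grads = net.loss_and_grads(xa, None, y)
        fd = nn.finite_difference_grads(
            lambda: nn.cross_entropy(net.forward(xa), y), net.params
        )
        for k in net.params:
            scale = max(np.max(np.abs(fd[k])), 1e-8)
            assert np.max(np.abs(grads[k] - fd[k])) / scale < 1e-5, k

    def test_shared_branches_cannot_drift_apart(self, rng):
        """After updates, the three branches still read the same arrays —
        sharing is structural (one store), not a synchronised copy."""
        net = build_network(_tiny_spec(shared=True), seed=8)
        xa, y = self._data(rng)
        fit(net, xa, None, y, TrainingConfig(epochs=3, seed=0))
        assert net._axis_prefix(0) == net._axis_prefix(1) == net._axis_prefix(2)

    def test_train_on_picture_sets_maps_labels(self, rng):
        spec = _tiny_spec()
        net = build_network(spec, seed=9)
        samples = [
            ActionPictureSet(rng.normal(size=(3, 4, 12)), None, f"k{i % 3}")
            for i in range(6)
        ]
        _, history = train(net, samples, TrainingConfig(epochs=2, seed=0))
        assert len(history) == 2

    def test_unknown_label_is_rejected(self, rng):
        net = build_network(_tiny_spec(), seed=10)
        samples = [ActionPictureSet(rng.normal(size=(3, 4, 12)), None, "nope")]
        with pytest.raises(ParameterError):
            train(net, samples, TrainingConfig(epochs=1))


class TestCheckpoint:
    def test_round_trip_reproduces_forward_bit_exactly(self, rng, tmp_path):
        spec = _tiny_spec()
        net = build_network(spec, seed=11)
        xa, y = rng.normal(size=(4, 3, 4, 12)), np.array([0, 1, 2, 0])
        fit(net, xa, None, y, TrainingConfig(epochs=2, seed=1))
        path = tmp_path / "ckpt.npz"
        net.save(path)
        back = Network.load(path)
        assert back.spec == spec
        assert back.history == net.history
        np.testing.assert_array_equal(back.forward(xa), net.forward(xa))
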