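"""Network assembly, parameter accounting and training.

Model variants
--------------
The input of the 2-D variants is the set of three per-axis action pictures
(P positions × T timestamps, one picture per axis).  Each picture runs
through its own stack of valid convolutions with ReLU, is flattened, and the
three (or four, with a scalar-channel picture) branch outputs are
concatenated into a single dense softmax head:

* **T-2DCNN** — three independent convolution stacks, one per axis picture.
* **TS-2DCNN** — one stack whose parameters are *shared* by all three axis
  pictures, cutting the tri-axial convolution parameters threefold.
* **M-2DCNN / MS-2DCNN** — the same two layouts plus a fourth branch of
  height-1 (time-only) convolutions over the scalar-channel picture.
* **1-D baseline** — a single branch treating all channels as rows of one
  picture, filtered with height-1 kernels only (the conventional per-channel
  organisation the 2-D input construction is compared against).

Parameter accounting
--------------------
A convolution layer with K_n^{l−1} input maps, K_n^l output maps and a
K_h × K_w kernel trains ``K_n^{l−1}·K_n^l·K_h·K_w + K_n^l`` parameters.  The
reference stack (3×3 1→64, 3×3 64→64, 5×1 64→64, 5×1 64→64) therefore costs
640 + 36928 + 20544 + 20544 = 78656 per picture — 235968 for three
independent stacks but 78656 when the one stack is shared, which is the
saving the shared variants exist for.  Dense-head parameters are excluded
from this accounting (it compares convolution layers).

Training is plain mini-batch SGD on categorical cross-entropy.  In shared
mode the three branches literally reference one parameter store, so the
shared gradient is the sum of the per-branch gradients, as the chain rule
over shared parameters dictates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .data import ActionPictureSet
from .errors import (
    ConfigurationError,
    GeometryError,
    ParameterError,
    TrainingDivergenceError,
)

__all__ = [
    "ConvLayerSpec",
    "NetworkSpec",
    "TrainingConfig",
    "count_layer_params",
    "count_conv_params",
    "reference_stack",
    "compact_stack",
    "scalar_stack",
    "build_network",
    "Network",
    "train",
]

AXIS_BRANCHES = ("x", "y", "z")


@dataclass(frozen=True)
class ConvLayerSpec:
    """Geometry of one convolution layer."""

    name: str
    kernel: tuple[int, int]  # (K_h, K_w)
    in_maps: int
    out_maps: int
    strides: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernel", tuple(int(k) for k in self.kernel))
        object.__setattr__(self, "strides", tuple(int(s) for s in self.strides))
        if min(*self.kernel, *self.strides, self.in_maps, self.out_maps) < 1:
            raise ParameterError(f"layer {self.name!r}: all dims must be >= 1")

    @property
    def conv_dim(self) -> int:
        """1 for time-only (height-1) kernels, else 2."""
        return 1 if self.kernel[0] == 1 else 2

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kernel": list(self.kernel),
            "in_maps": self.in_maps,
            "out_maps": self.out_maps,
            "strides": list(self.strides),
        }

    @classmethod
    def from_dict(cls, d) -> "ConvLayerSpec":
        return cls(
            d["name"], tuple(d["kernel"]), d["in_maps"], d["out_maps"],
            tuple(d.get("strides", (1, 1))),
        )


def count_layer_params(spec: ConvLayerSpec) -> int:
    """Trainable parameters of one conv layer:
    ``in_maps · out_maps · K_h · K_w + out_maps`` (weights plus biases)."""
    kh, kw = spec.kernel
    return spec.in_maps * spec.out_maps * kh * kw + spec.out_maps


def reference_stack(maps: int = 64) -> tuple[ConvLayerSpec, ...]:
    """The reference 4-layer stack: 3×3 1→maps, 3×3, 5×1, 5×1.

    At maps=64 the per-layer costs are 640, 36928, 20544, 20544."""
    return (
        ConvLayerSpec("conv1", (3, 3), 1, maps),
        ConvLayerSpec("conv2", (3, 3), maps, maps),
        ConvLayerSpec("conv3", (5, 1), maps, maps),
        ConvLayerSpec("conv4", (5, 1), maps, maps),
    )


def compact_stack(picture_rows: int, maps: int = 8) -> tuple[ConvLayerSpec, ...]:
    """A 4-layer stack with the reference shape (two cross-position kernels
    followed by two time-only kernels) whose kernel heights are scaled down
    so the stack is feasible for pictures with only ``picture_rows`` rows
    (e.g. 4 accelerometer positions instead of 16 sensors)."""
    if picture_rows < 1:
        raise ParameterError("picture_rows must be >= 1")
    heights = {1: (1, 1), 2: (2, 1), 3: (2, 2)}.get(picture_rows, (3, 2))
    h1, h2 = heights
    return (
        ConvLayerSpec("conv1", (h1, 3), 1, maps),
        ConvLayerSpec("conv2", (h2, 3), maps, maps),
        ConvLayerSpec("conv3", (1, 5), maps, maps),
        ConvLayerSpec("conv4", (1, 5), maps, maps),
    )


def scalar_stack(maps: int = 8) -> tuple[ConvLayerSpec, ...]:
    """Time-only stack for the scalar-channel picture, mirroring the
    reference kernel widths (3, 3, 5, 5)."""
    return (
        ConvLayerSpec("sconv1", (1, 3), 1, maps),
        ConvLayerSpec("sconv2", (1, 3), maps, maps),
        ConvLayerSpec("sconv3", (1, 5), maps, maps),
        ConvLayerSpec("sconv4", (1, 5), maps, maps),
    )


@dataclass(frozen=True)
class NetworkSpec:
    """Full network geometry: branch inputs, conv stacks, sharing, head.

    ``axis_rows`` is the picture height (number of tri-axial positions for
    the 2-D variants; total channel count for the 1-D baseline, which uses
    ``n_axis_branches = 1``).  ``shared=True`` makes all axis branches
    reference one parameter set.  The scalar branch, when present, always
    has its own (time-only) parameters — its geometry differs from the axis
    pictures, so it cannot share theirs.
    """

    axis_rows: int
    window: int
    conv_stack: tuple[ConvLayerSpec, ...]
    n_classes: int
    class_labels: tuple[str, ...] = ()
    shared: bool = False
    n_axis_branches: int = 3
    scalar_rows: int = 0
    scalar_conv_stack: tuple[ConvLayerSpec, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_stack", tuple(self.conv_stack))
        if self.scalar_conv_stack is not None:
            object.__setattr__(
                self, "scalar_conv_stack", tuple(self.scalar_conv_stack)
            )
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        if self.class_labels and len(self.class_labels) != self.n_classes:
            raise ConfigurationError("class_labels length must equal n_classes")
        if self.n_axis_branches < 1:
            raise ConfigurationError("need at least one branch")
        if self.conv_stack and self.conv_stack[0].in_maps != 1:
            raise ConfigurationError("first conv layer must take the 1-map picture")
        if (self.scalar_rows > 0) != (self.scalar_conv_stack is not None):
            raise ConfigurationError(
                "scalar_conv_stack must be given iff scalar_rows > 0"
            )
        for ls in self.scalar_conv_stack or ():
            if ls.kernel[0] != 1:
                raise ConfigurationError("scalar branch layers must have K_h = 1")
        # Validate feasibility by tracing shapes once.
        self.branch_output_shape()
        if self.scalar_rows:
            self.scalar_output_shape()

    def _trace(self, shape: tuple[int, int], stack) -> tuple[int, int, int]:
        h, w = shape
        maps = 1
        for ls in stack:
            try:
                h = nn.conv_output_shape(h, ls.kernel[0], ls.strides[0])
                w = nn.conv_output_shape(w, ls.kernel[1], ls.strides[1])
            except GeometryError as e:
                raise ConfigurationError(f"layer {ls.name!r} infeasible: {e}") from e
            maps = ls.out_maps
        return maps, h, w

    def branch_output_shape(self) -> tuple[int, int, int]:
        return self._trace((self.axis_rows, self.window), self.conv_stack)

    def scalar_output_shape(self) -> tuple[int, int, int]:
        return self._trace((self.scalar_rows, self.window), self.scalar_conv_stack)

    @property
    def feature_dim(self) -> int:
        """Length of the concatenated flattened branch outputs."""
        c, h, w = self.branch_output_shape()
        dim = self.n_axis_branches * c * h * w
        if self.scalar_rows:
            c, h, w = self.scalar_output_shape()
            dim += c * h * w
        return dim

    def to_dict(self) -> dict:
        return {
            "axis_rows": self.axis_rows,
            "window": self.window,
            "conv_stack": [ls.to_dict() for ls in self.conv_stack],
            "n_classes": self.n_classes,
            "class_labels": list(self.class_labels),
            "shared": self.shared,
            "n_axis_branches": self.n_axis_branches,
            "scalar_rows": self.scalar_rows,
            "scalar_conv_stack": (
                None
                if self.scalar_conv_stack is None
                else [ls.to_dict() for ls in self.scalar_conv_stack]
            ),
        }

    @classmethod
    def from_dict(cls, d) -> "NetworkSpec":
        return cls(
            axis_rows=d["axis_rows"],
            window=d["window"],
            conv_stack=tuple(ConvLayerSpec.from_dict(x) for x in d["conv_stack"]),
            n_classes=d["n_classes"],
            class_labels=tuple(d.get("class_labels", ())),
            shared=d["shared"],
            n_axis_branches=d.get("n_axis_branches", 3),
            scalar_rows=d.get("scalar_rows", 0),
            scalar_conv_stack=(
                None
                if d.get("scalar_conv_stack") is None
                else tuple(ConvLayerSpec.from_dict(x) for x in d["scalar_conv_stack"])
            ),
        )


def count_conv_params(spec: NetworkSpec, include_scalar: bool = False) -> int:
    """Total trainable convolution-layer parameters.

    Non-shared: every axis branch has its own stack, so the per-stack sum is
    multiplied by the branch count; shared: one stack serves all branches.
    The scalar branch (always unshared) is excluded by default to match the
    convention of comparing the tri-axial convolution stacks, and added when
    ``include_scalar`` is set.
    """
    per_stack = sum(count_layer_params(ls) for ls in spec.conv_stack)
    total = per_stack if spec.shared else spec.n_axis_branches * per_stack
    if include_scalar and spec.scalar_conv_stack:
        total += sum(count_layer_params(ls) for ls in spec.scalar_conv_stack)
    return total


@dataclass
class TrainingConfig:
    """Mini-batch SGD hyper-parameters.

    Training stops when the largest absolute parameter change over a full
    epoch drops below ``threshold``, or when the epoch budget is exhausted.
    """

    learning_rate: float = 0.01
    epochs: int = 40
    batch_size: int = 32
    threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")
        if self.threshold < 0:
            raise ParameterError("threshold must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("epochs and batch_size must be >= 1")


class Network:
    """A built network: a flat named parameter store plus branch wiring.

    In shared mode the axis branches map to the *same* parameter names, so
    there is literally one store — gradient contributions from the three
    branches accumulate into it and the weights can never drift apart.
    """

    def __init__(self, spec: NetworkSpec, params: dict[str, np.ndarray], seed: int):
        self.spec = spec
        self.params = params
        self.seed = seed
        self.history: list[float] = []

    # -- wiring ------------------------------------------------------------

    def _axis_prefix(self, branch_index: int) -> str:
        if self.spec.shared or self.spec.n_axis_branches == 1:
            return "axis"
        return f"axis_{AXIS_BRANCHES[branch_index]}"

    def conv_param_names(self) -> list[str]:
        """Names of all convolution parameters (deduplicated under sharing)."""
        names: list[str] = []
        prefixes = {self._axis_prefix(i) for i in range(self.spec.n_axis_branches)}
        for prefix in sorted(prefixes):
            for ls in self.spec.conv_stack:
                names += [f"{prefix}.{ls.name}.w", f"{prefix}.{ls.name}.b"]
        if self.spec.scalar_conv_stack:
            for ls in self.spec.scalar_conv_stack:
                names += [f"scalar.{ls.name}.w", f"scalar.{ls.name}.b"]
        return names

    def n_conv_params(self) -> int:
        return sum(self.params[n].size for n in self.conv_param_names())

    # -- forward / backward ------------------------------------------------

    def _run_stack(self, x: np.ndarray, stack, prefix: str):
        """Forward one branch; returns (flattened output, caches)."""
        caches = []
        for ls in stack:
            w = self.params[f"{prefix}.{ls.name}.w"]
            b = self.params[f"{prefix}.{ls.name}.b"]
            z = nn.conv2d_forward(x, w, b, ls.strides)
            caches.append((x, z))
            x = nn.relu(z)
        return x.reshape(x.shape[0], -1), caches

    def _branch_inputs(self, x_axis: np.ndarray, x_scalar: np.ndarray | None):
        x_axis = np.asarray(x_axis, dtype=np.float64)
        if x_axis.ndim != 4 or x_axis.shape[1] != self.spec.n_axis_branches:
            raise GeometryError(
                f"axis input must be (N, {self.spec.n_axis_branches}, "
                f"{self.spec.axis_rows}, {self.spec.window}); got {x_axis.shape}"
            )
        branches = [x_axis[:, i][:, None] for i in range(self.spec.n_axis_branches)]
        scalar = None
        if self.spec.scalar_rows:
            if x_scalar is None:
                raise GeometryError("this network expects a scalar picture")
            scalar = np.asarray(x_scalar, dtype=np.float64)[:, None]
        return branches, scalar

    def _forward_full(self, x_axis, x_scalar):
        branches, scalar = self._branch_inputs(x_axis, x_scalar)
        feats, caches = [], []
        for i, xb in enumerate(branches):
            f, c = self._run_stack(xb, self.spec.conv_stack, self._axis_prefix(i))
            feats.append(f)
            caches.append(c)
        scalar_cache = None
        if scalar is not None:
            f, scalar_cache = self._run_stack(
                scalar, self.spec.scalar_conv_stack, "scalar"
            )
            feats.append(f)
        features = np.concatenate(feats, axis=1)
        probs = nn.dense_softmax_forward(
            features, self.params["dense.w"], self.params["dense.b"]
        )
        return probs, features, caches, scalar_cache, [f.shape[1] for f in feats]

    def forward(
        self, x_axis: np.ndarray, x_scalar: np.ndarray | None = None
    ) -> np.ndarray:
        """Class probabilities, shape (N, C); rows sum to 1."""
        return self._forward_full(x_axis, x_scalar)[0]

    def forward_one(self, pictures: ActionPictureSet) -> np.ndarray:
        """Probabilities for a single :class:`ActionPictureSet`."""
        xs = (
            pictures.scalar_picture[None]
            if pictures.scalar_picture is not None and self.spec.scalar_rows
            else None
        )
        return self.forward(pictures.axis_pictures[None], xs)[0]

    def predict(self, x_axis, x_scalar=None) -> np.ndarray:
        return self.forward(x_axis, x_scalar).argmax(axis=1)

    def _stack_backward(self, dflat, caches, stack, prefix, grads, out_shape):
        dout = dflat.reshape(dflat.shape[0], *out_shape)
        for li in range(len(stack) - 1, -1, -1):
            ls = stack[li]
            x_prev, z = caches[li]
            delta = dout * nn.relu_grad(z)
            dw, db = nn.conv_weight_grad(delta, x_prev, ls.kernel, ls.strides)
            grads[f"{prefix}.{ls.name}.w"] += dw
            grads[f"{prefix}.{ls.name}.b"] += db
            if li > 0:
                dout = nn.conv_backward_input(
                    delta, self.params[f"{prefix}.{ls.name}.w"], ls.strides,
                    x_prev.shape,
                )

    def loss_and_grads(
        self, x_axis, x_scalar, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy and its gradient for every parameter.

        Under sharing the three axis branches write into the same gradient
        arrays, so the shared-stack gradient is the sum over branches.
        """
        y = np.asarray(y, dtype=int)
        probs, features, caches, scalar_cache, feat_dims = self._forward_full(
            x_axis, x_scalar
        )
        n = len(y)
        loss = nn.cross_entropy(probs, y)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads["dense.w"] += dlogits.T @ features
        grads["dense.b"] += dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["dense.w"]
        offset = 0
        out_shape = self.spec.branch_output_shape()
        for i in range(self.spec.n_axis_branches):
            seg = dfeat[:, offset : offset + feat_dims[i]]
            offset += feat_dims[i]
            self._stack_backward(
                seg, caches[i], self.spec.conv_stack, self._axis_prefix(i),
                grads, out_shape,
            )
        if scalar_cache is not None:
            seg = dfeat[:, offset:]
            self._stack_backward(
                seg, scalar_cache, self.spec.scalar_conv_stack, "scalar",
                grads, self.spec.scalar_output_shape(),
            )
        return loss, grads

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint (spec + seed + weights + history); reloading
        reproduces forward outputs bit-exactly."""
        meta = json.dumps(
            {"spec": self.spec.to_dict(), "seed": self.seed, "history": self.history}
        )
        np.savez(path, __meta__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            params = {k: f[k].copy() for k in f.files if k != "__meta__"}
        net = cls(NetworkSpec.from_dict(meta["spec"]), params, meta["seed"])
        net.history = list(meta["history"])
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Initialise a network: He-scaled zero-mean Gaussian weights (fan-in =
    in_maps·K_h·K_w), zero biases, from a seeded generator — the same seed
    always yields bit-identical weights."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}

    def init_stack(stack, prefix):
        for ls in stack:
            kh, kw = ls.kernel
            fan_in = ls.in_maps * kh * kw
            params[f"{prefix}.{ls.name}.w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(ls.in_maps, ls.out_maps, kh, kw)
            )
            params[f"{prefix}.{ls.name}.b"] = np.zeros(ls.out_maps)

    if spec.shared or spec.n_axis_branches == 1:
        init_stack(spec.conv_stack, "axis")
    else:
        for i in range(spec.n_axis_branches):
            init_stack(spec.conv_stack, f"axis_{AXIS_BRANCHES[i]}")
    if spec.scalar_conv_stack:
        init_stack(spec.scalar_conv_stack, "scalar")
    fdim = spec.feature_dim
    params["dense.w"] = rng.normal(
        0.0, np.sqrt(2.0 / fdim), size=(spec.n_classes, fdim)
    )
    params["dense.b"] = np.zeros(spec.n_classes)
    net = Network(spec, params, seed)
    expected = count_conv_params(spec, include_scalar=True)
    assert net.n_conv_params() == expected, "parameter wiring out of sync"
    return net


def fit(
    net: Network,
    x_axis: np.ndarray,
    x_scalar: np.ndarray | None,
    y: np.ndarray,
    cfg: TrainingConfig,
) -> list[float]:
    """Mini-batch SGD on cross-entropy; returns the per-epoch mean loss.

    Stops early when the largest absolute parameter change over an epoch is
    below ``cfg.threshold``.  A non-finite loss raises
    :class:`TrainingDivergenceError` naming the epoch.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 1:
        raise ParameterError("need at least one training sample")
    if y.min() < 0 or y.max() >= net.spec.n_classes:
        raise ParameterError("labels out of class range")
    rng = np.random.default_rng(cfg.seed)
    for epoch in range(cfg.epochs):
        before = {k: v.copy() for k, v in net.params.items()}
        order = rng.permutation(n)
        losses, weights = [], []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xs = None if x_scalar is None else x_scalar[idx]
            loss, grads = net.loss_and_grads(x_axis[idx], xs, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            for k in net.params:
                net.params[k] -= cfg.learning_rate * grads[k]
            losses.append(loss)
            weights.append(len(idx))
        net.history.append(float(np.average(losses, weights=weights)))
        max_change = max(
            np.max(np.abs(net.params[k] - before[k])) for k in net.params
        )
        if max_change < cfg.threshold:
            break
    return net.history


def train(
    net: Network, samples: Sequence[ActionPictureSet], cfg: TrainingConfig
) -> tuple[Network, list[float]]:
    """Train on a sequence of picture sets (labels must be the class labels
    recorded in the network spec)."""
    if not samples:
        raise ParameterError("need at least one training sample")
    if not net.spec.class_labels:
        raise ConfigurationError("network spec carries no class labels")
    index = {c: i for i, c in enumerate(net.spec.class_labels)}
    try:
        y = np.array([index[s.label] for s in samples])
    except KeyError as e:
        raise ParameterError(f"label {e.args[0]!r} not in the class set") from e
    xa = np.stack([s.axis_pictures for s in samples])
    xs = (
        np.stack([s.scalar_picture for s in samples])
        if net.spec.scalar_rows
        else None
    )
    history = fit(net, xa, xs, y, cfg)
    return net, history
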