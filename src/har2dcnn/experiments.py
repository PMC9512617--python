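"""End-to-end experiment glue: simulate → window → train → score.

The canonical study conditions are 4 accelerometer positions, 5 activity
classes plus NULL, a 24-sample window with 50% overlap (~2,000 windows), a
contiguous 70/30 time split, per-channel z-scoring with training-split
statistics, and the compact 8-map stack.  ``compare_variants`` reproduces
the sensor-subset experiment design: every model variant crossed with
position subsets of growing size, reporting weighted F1 and the convolution
parameter count of each cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import (
    MultiPositionRecording,
    compute_channel_stats,
    normalize_channels,
    segment_windows,
    windows_to_arrays,
)
from .errors import ParameterError
from .evaluate import ConfusionMatrix, accuracy, confusion, weighted_f1
from .models import (
    Network,
    NetworkSpec,
    TrainingConfig,
    build_network,
    compact_stack,
    count_conv_params,
    fit,
    scalar_stack,
)
from .sim import default_profiles, default_segment_plan, simulate_recording

__all__ = [
    "VARIANTS",
    "make_network_spec",
    "Dataset",
    "prepare_dataset",
    "default_recording",
    "ExperimentResult",
    "run_experiment",
    "compare_variants",
]

#: Model variants: the 1-D per-channel baseline, the per-axis 2-D models
#: (T = tri-axial, M = mixed with a scalar branch) and their
#: parameter-shared counterparts (TS, MS).
VARIANTS = ("1d-baseline", "t2dcnn", "ts2dcnn", "m2dcnn", "ms2dcnn")


def make_network_spec(
    variant: str,
    n_positions: int,
    window: int,
    n_scalar: int,
    class_labels: Sequence[str],
    maps: int = 8,
) -> NetworkSpec:
    """Network geometry for one variant at the given input dimensions."""
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; pick from {VARIANTS}")
    class_labels = tuple(class_labels)
    common = dict(
        window=window, n_classes=len(class_labels), class_labels=class_labels
    )
    if variant == "1d-baseline":
        rows = 3 * n_positions + n_scalar
        return NetworkSpec(
            axis_rows=rows,
            conv_stack=scalar_stack(maps),
            shared=False,
            n_axis_branches=1,
            **common,
        )
    shared = variant in ("ts2dcnn", "ms2dcnn")
    mixed = variant in ("m2dcnn", "ms2dcnn")
    if mixed and n_scalar == 0:
        raise ParameterError(f"variant {variant!r} needs scalar channels")
    return NetworkSpec(
        axis_rows=n_positions,
        conv_stack=compact_stack(n_positions, maps),
        shared=shared,
        n_axis_branches=3,
        scalar_rows=n_scalar if mixed else 0,
        scalar_conv_stack=scalar_stack(maps) if mixed else None,
        **common,
    )


@dataclass
class Dataset:
    """Windowed, normalized train/test arrays for one recording."""

    class_labels: tuple[str, ...]
    xa_train: np.ndarray
    xs_train: np.ndarray | None
    y_train: np.ndarray
    xa_test: np.ndarray
    xs_test: np.ndarray | None
    y_test: np.ndarray
    test_labels: list[str]


def prepare_dataset(
    rec: MultiPositionRecording,
    window: int = 24,
    overlap: float = 0.5,
    train_fraction: float = 0.7,
) -> Dataset:
    """Split by contiguous time blocks, z-score with training statistics,
    window both blocks and stack the action pictures.

    A block split (rather than shuffling windows) keeps 50%-overlapping
    windows from leaking between train and test.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must lie in (0, 1)")
    cut = int(round(train_fraction * rec.n_samples))
    rec_train = rec.slice_time(0, cut)
    rec_test = rec.slice_time(cut, rec.n_samples)
    stats = compute_channel_stats(rec_train)
    rec_train = normalize_channels(rec_train, stats)
    rec_test = normalize_channels(rec_test, stats)
    train_w = segment_windows(rec_train, window, overlap)
    test_w = segment_windows(rec_test, window, overlap)
    if not train_w or not test_w:
        raise ParameterError("recording too short for the requested windowing")
    classes = tuple(sorted(set(rec.labels.tolist())))
    index = {c: i for i, c in enumerate(classes)}
    xa_tr, xs_tr, lab_tr = windows_to_arrays(train_w)
    xa_te, xs_te, lab_te = windows_to_arrays(test_w)
    return Dataset(
        class_labels=classes,
        xa_train=xa_tr,
        xs_train=xs_tr,
        y_train=np.array([index[l] for l in lab_tr]),
        xa_test=xa_te,
        xs_test=xs_te,
        y_test=np.array([index[l] for l in lab_te]),
        test_labels=lab_te,
    )


def default_recording(
    seed: int,
    n_positions: int = 4,
    n_classes: int = 5,
    n_scalar: int = 0,
    total_length: int = 24012,
) -> MultiPositionRecording:
    """The package's canonical synthetic recording (about 2,000 windows at
    window 24 / 50% overlap when ``total_length`` is 24012)."""
    profiles = default_profiles(n_positions, n_classes)
    plan = default_segment_plan(profiles, total_length)
    return simulate_recording(profiles, n_positions, plan, n_scalar, seed=seed)


def _variant_inputs(spec: NetworkSpec, xa, xs):
    """Map dataset arrays onto the branch inputs a variant expects."""
    if spec.n_axis_branches == 1:
        # (N, 3, P, T) -> (N, 3P, T), position-major / axis-minor row order
        # to match MultiPositionRecording.channel_matrix.
        n, _, p, t = xa.shape
        stacked = xa.transpose(0, 2, 1, 3).reshape(n, 3 * p, t)
        if xs is not None:
            stacked = np.concatenate([stacked, xs], axis=1)
        return stacked[:, None], None
    return xa, (xs if spec.scalar_rows else None)


@dataclass
class ExperimentResult:
    variant: str
    positions: tuple[str, ...]
    spec: NetworkSpec
    network: Network
    history: list[float]
    cm: ConfusionMatrix
    weighted_f1: float
    accuracy: float
    conv_params: int
    n_train: int
    n_test: int


def run_experiment(
    rec: MultiPositionRecording,
    variant: str = "ts2dcnn",
    window: int = 24,
    overlap: float = 0.5,
    maps: int = 8,
    training: TrainingConfig | None = None,
    train_fraction: float = 0.7,
) -> ExperimentResult:
    """Train one variant on one recording and score the held-out block."""
    training = training or TrainingConfig()
    ds = prepare_dataset(rec, window, overlap, train_fraction)
    spec = make_network_spec(
        variant,
        rec.n_positions,
        window,
        rec.layout.n_scalar,
        ds.class_labels,
        maps,
    )
    net = build_network(spec, seed=training.seed)
    xa_tr, xs_tr = _variant_inputs(spec, ds.xa_train, ds.xs_train)
    xa_te, xs_te = _variant_inputs(spec, ds.xa_test, ds.xs_test)
    history = fit(net, xa_tr, xs_tr, ds.y_train, training)
    pred = net.predict(xa_te, xs_te)
    pred_labels = [ds.class_labels[i] for i in pred]
    cm = confusion(ds.test_labels, pred_labels, labels=ds.class_labels)
    return ExperimentResult(
        variant=variant,
        positions=rec.layout.positions,
        spec=spec,
        network=net,
        history=history,
        cm=cm,
        weighted_f1=weighted_f1(cm),
        accuracy=accuracy(cm),
        conv_params=count_conv_params(spec),
        n_train=len(ds.y_train),
        n_test=len(ds.y_test),
    )


def compare_variants(
    rec: MultiPositionRecording,
    variants: Sequence[str] = VARIANTS,
    subset_sizes: Sequence[int] | None = None,
    window: int = 24,
    overlap: float = 0.5,
    maps: int = 8,
    training: TrainingConfig | None = None,
) -> list[ExperimentResult]:
    """The sensor-subset experiment: every variant crossed with position
    subsets of growing size (prefixes of the configured position order)."""
    if subset_sizes is None:
        subset_sizes = range(1, rec.n_positions + 1)
    results = []
    for size in subset_sizes:
        if not 1 <= size <= rec.n_positions:
            raise ParameterError(f"subset size {size} out of range")
        sub = rec.select_positions(rec.layout.positions[:size])
        for variant in variants:
            if variant in ("m2dcnn", "ms2dcnn") and rec.layout.n_scalar == 0:
                continue
            results.append(
                run_experiment(sub, variant, window, overlap, maps, training)
            )
    return results


def format_comparison(results: Sequence[ExperimentResult]) -> str:
    lines = [
        f"{'variant':<14} {'positions':>9} {'conv params':>12} "
        f"{'weighted F1':>12} {'accuracy':>9}"
    ]
    for r in results:
        lines.append(
            f"{r.variant:<14} {len(r.positions):>9d} {r.conv_params:>12d} "
            f"{r.weighted_f1:>12.4f} {r.accuracy:>9.4f}"
        )
    return "\n".join(lines)
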