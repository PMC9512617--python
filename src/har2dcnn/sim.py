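"""Synthetic multi-position accelerometer recordings.

The simulator stands in for body-worn activity datasets: several tri-axial
accelerometers at different body positions, a mid-level activity label per
timestamp including a NULL/background class, class imbalance, and optional
scalar channels (heart-rate-like).  It is first-class, tested code — every
model-level result in this package is measured on its output.

Signal model, per position p and axis a at sample t:

    s[p, a, t] = g_a(pose of p during the activity)
               + A · ( κ · sin(2π f_a t + φ_a)            # shared across positions
                     + (1 − κ) · sin(2π f_{p,a} t + φ_{p,a}) )  # position-private
               + ε,   ε ~ N(0, noise_sd²)

The gravity term is the static reading of a resting accelerometer in one of
six axis-aligned device poses (±g on exactly one axis; readings are in units
of g, represented as 1.0).  The coupling factor κ ∈ [0, 1] sets how strongly
the same axis co-varies across positions: the shared sinusoid has one
frequency/phase per (activity, axis), while the private sinusoid differs per
position, so high κ makes same-axis cross-position channel pairs strongly
correlated and cross-axis pairs weakly correlated — the statistical premise
that motivates per-axis action pictures, realised here by construction.

Scalar channels are smooth AR(1) random walks, a generic stand-in for slow
physiological signals; they carry no class information by default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .data import MultiPositionRecording, SensorLayout
from .errors import ParameterError

__all__ = [
    "Orientation",
    "gravity_vector",
    "ActivityProfile",
    "simulate_recording",
    "class_balance",
    "default_profiles",
    "default_segment_plan",
    "NULL_LABEL",
]

NULL_LABEL = "null"

#: Axis-specific multipliers applied to a profile's base frequency so the
#: three axes of the shared oscillation are mutually near-uncorrelated
#: (distinct frequencies rather than phase offsets, which would still
#: correlate at a common frequency).
_AXIS_FREQ_MULT = (1.0, 1.37, 1.71)


class Orientation(enum.Enum):
    """Six axis-aligned device poses of a resting tri-axial accelerometer."""

    LEFT_SIDE_DOWN = "left-side-down"
    RIGHT_SIDE_DOWN = "right-side-down"
    UPRIGHT = "upright"
    HEAD_DOWN = "head-down"
    SCREEN_UP = "screen-up"
    SCREEN_DOWN = "screen-down"


_GRAVITY_CASES: dict[Orientation, tuple[float, float, float]] = {
    Orientation.LEFT_SIDE_DOWN: (1.0, 0.0, 0.0),
    Orientation.RIGHT_SIDE_DOWN: (-1.0, 0.0, 0.0),
    Orientation.UPRIGHT: (0.0, 1.0, 0.0),
    Orientation.HEAD_DOWN: (0.0, -1.0, 0.0),
    Orientation.SCREEN_UP: (0.0, 0.0, 1.0),
    Orientation.SCREEN_DOWN: (0.0, 0.0, -1.0),
}


def gravity_vector(o: Orientation, g: float = 1.0) -> np.ndarray:
    """Static tri-axial reading (a_x, a_y, a_z) of a device resting in pose
    ``o``: ±g on the vertical axis, 0 elsewhere; Euclidean norm g."""
    try:
        o = Orientation(o)
    except ValueError as e:
        raise ParameterError(f"unknown orientation {o!r}") from e
    return g * np.array(_GRAVITY_CASES[o])


@dataclass(frozen=True)
class ActivityProfile:
    """Generative parameters of one activity class.

    ``frequency`` is in cycles/sample (must stay below Nyquist, 0.5, after
    the per-axis multipliers); ``amplitude`` and ``noise_sd`` are in g.
    ``orientations`` gives the base device pose per position (a single pose
    is broadcast to all positions).
    """

    name: str
    amplitude: float
    frequency: float
    kappa: float
    orientations: tuple[Orientation, ...] | Orientation
    phase: float = 0.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ParameterError("amplitude and noise_sd must be >= 0")
        if not 0.0 <= self.frequency < 0.5 / max(_AXIS_FREQ_MULT):
            raise ParameterError(
                "frequency must lie in [0, 0.5/1.71) cycles/sample"
            )
        if not 0.0 <= self.kappa <= 1.0:
            raise ParameterError("kappa must lie in [0, 1]")

    def orientation_at(self, position_index: int) -> Orientation:
        if isinstance(self.orientations, Orientation):
            return self.orientations
        return self.orientations[position_index % len(self.orientations)]


def default_profiles(n_positions: int = 4, n_classes: int = 5) -> list[ActivityProfile]:
    """The study conditions used throughout the package: ``n_classes``
    activity classes with distinct oscillation frequencies and per-position
    pose assignments, plus a NULL class (no oscillation, gravity + noise).
    """
    if not 1 <= n_classes <= 5:
        raise ParameterError("default profile set supports 1..5 activity classes")
    poses = list(Orientation)
    freqs = (0.040, 0.068, 0.102, 0.145, 0.190)
    profiles = [
        ActivityProfile(
            name=NULL_LABEL,
            amplitude=0.0,
            frequency=0.0,
            kappa=0.8,
            orientations=Orientation.SCREEN_UP,
            noise_sd=0.05,
        )
    ]
    for c in range(n_classes):
        orients = tuple(
            poses[(c + 1 + p) % len(poses)] for p in range(n_positions)
        )
        profiles.append(
            ActivityProfile(
                name=f"act{c + 1}",
                amplitude=0.4,
                frequency=freqs[c],
                kappa=0.8,
                orientations=orients,
                phase=0.6 * c,
                noise_sd=0.05,
            )
        )
    return profiles


def default_segment_plan(
    profiles: Sequence[ActivityProfile],
    total_length: int,
    base_segment: int = 80,
    weights: Mapping[str, int] | None = None,
) -> list[tuple[str, int]]:
    """Imbalanced activity schedule: cycle through the classes, each segment
    ``weight · base_segment`` samples long, trimmed to ``total_length``.

    The default weights make the NULL class the most frequent and give the
    activity classes unequal support, the shape real mid-level-gesture label
    tracks have.
    """
    if total_length < 1:
        raise ParameterError("total_length must be >= 1")
    if weights is None:
        default_w = [6, 5, 4, 3, 3, 2]
        weights = {
            p.name: default_w[i % len(default_w)] for i, p in enumerate(profiles)
        }
    plan: list[tuple[str, int]] = []
    total = 0
    while total < total_length:
        for p in profiles:
            seg = weights.get(p.name, 1) * base_segment
            seg = min(seg, total_length - total)
            if seg <= 0:
                break
            plan.append((p.name, seg))
            total += seg
    return plan


def simulate_recording(
    profiles: Sequence[ActivityProfile],
    positions: int | Sequence[str],
    segment_plan: Sequence[tuple[str, int]],
    scalar_channels: int | Sequence[str] = 0,
    seed: int = 0,
) -> MultiPositionRecording:
    """Generate a labelled multi-position recording.

    ``segment_plan`` is the label track blueprint: a sequence of
    (profile name, length) activity segments.  Identical seeds give identical
    recordings.  With ``noise_sd = 0`` and ``amplitude = 0`` every tri-axial
    sample equals the pose's gravity vector exactly.
    """
    if len(profiles) < 2:
        raise ParameterError("need at least two activity profiles")
    if isinstance(positions, int):
        positions = [f"pos{i + 1}" for i in range(positions)]
    positions = list(positions)
    if not positions:
        raise ParameterError("need at least one position")
    if isinstance(scalar_channels, int):
        scalar_channels = [f"aux{i + 1}" for i in range(scalar_channels)]
    scalar_channels = list(scalar_channels)
    if not segment_plan:
        raise ParameterError("segment plan is empty")
    by_name = {p.name: p for p in profiles}
    for name, length in segment_plan:
        if name not in by_name:
            raise ParameterError(f"segment plan names unknown profile {name!r}")
        if length < 1:
            raise ParameterError("segment lengths must be >= 1")

    P, S = len(positions), len(scalar_channels)
    n = sum(length for _, length in segment_plan)
    rng = np.random.default_rng(seed)

    # Deterministic draw order: shared phases per (profile, axis), then
    # private frequency/phase per (profile, position, axis).
    shared_phase: dict[tuple[str, int], float] = {}
    private: dict[tuple[str, int, int], tuple[float, float]] = {}
    for prof in profiles:
        for a in range(3):
            shared_phase[(prof.name, a)] = float(rng.uniform(0, 2 * np.pi))
        for p in range(P):
            for a in range(3):
                jitter = float(rng.uniform(0.75, 1.35))
                private[(prof.name, p, a)] = (
                    prof.frequency * _AXIS_FREQ_MULT[a] * jitter,
                    float(rng.uniform(0, 2 * np.pi)),
                )

    tri = np.empty((P, 3, n))
    labels = np.empty(n, dtype=object)
    t0 = 0
    for name, length in segment_plan:
        prof = by_name[name]
        t = np.arange(t0, t0 + length, dtype=float)
        labels[t0 : t0 + length] = name
        for p in range(P):
            gvec = gravity_vector(prof.orientation_at(p))
            for a in range(3):
                f_shared = prof.frequency * _AXIS_FREQ_MULT[a]
                shared = np.sin(
                    2 * np.pi * f_shared * t + shared_phase[(name, a)] + prof.phase
                )
                f_priv, ph_priv = private[(name, p, a)]
                priv = np.sin(2 * np.pi * f_priv * t + ph_priv)
                sig = gvec[a] + prof.amplitude * (
                    prof.kappa * shared + (1.0 - prof.kappa) * priv
                )
                if prof.noise_sd > 0:
                    sig = sig + rng.normal(0.0, prof.noise_sd, size=length)
                tri[p, a, t0 : t0 + length] = sig
        t0 += length

    if S:
        # AR(1) smooth random walks: s_t = 0.995 s_{t-1} + 0.05 η_t.
        innov = rng.normal(0.0, 1.0, size=(S, n))
        scal = lfilter([0.05], [1.0, -0.995], innov, axis=1)
    else:
        scal = np.empty((0, n))

    layout = SensorLayout(tuple(positions), tuple(scalar_channels))
    return MultiPositionRecording(layout, tri, scal, labels.astype(str))


def class_balance(rec: MultiPositionRecording) -> dict[str, int]:
    """Per-label sample counts; they always sum to the recording length."""
    values, counts = np.unique(rec.labels, return_counts=True)
    return {str(v): int(c) for v, c in zip(values, counts)}
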