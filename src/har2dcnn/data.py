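"""Recordings, sliding-window segmentation and action-picture assembly.

A :class:`MultiPositionRecording` holds synchronized tri-axial accelerometer
streams (units of g) from several body positions plus optional scalar channels
(heart-rate-like) and one activity label per timestamp.  Fixed-length windows
cut from the recording are re-indexed into per-axis "action pictures": for
each axis (x, y, z) a ``P x T`` matrix whose rows are the P positions' traces
for that axis over the window.  A 2-D convolutional model consuming these
pictures sees the cross-position structure of a single axis as an image,
which is the input organisation this package is built around.

Windows are 0-based and half-open; a window's label is the label at its last
timestamp.  Recordings with missing (NaN) samples are rejected rather than
imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParameterError

AXES: tuple[str, str, str] = ("x", "y", "z")

__all__ = [
    "AXES",
    "SensorLayout",
    "MultiPositionRecording",
    "WindowedSample",
    "ActionPictureSet",
    "ChannelStats",
    "read_recording",
    "write_recording_csv",
    "read_fixture",
    "write_fixture",
    "compute_channel_stats",
    "normalize_channels",
    "segment_windows",
    "build_action_pictures",
    "windows_to_arrays",
]


@dataclass(frozen=True)
class SensorLayout:
    """Names of the body positions, scalar channels and special columns.

    The CSV dialect derived from a layout is one row per timestamp with
    columns ``t, <pos>_x, <pos>_y, <pos>_z, ..., <scalar>..., label``.
    """

    positions: tuple[str, ...]
    scalar_channels: tuple[str, ...] = ()
    label_column: str = "label"
    time_column: str = "t"

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        object.__setattr__(self, "scalar_channels", tuple(self.scalar_channels))
        if not self.positions:
            raise ParameterError("layout needs at least one tri-axial position")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_scalar(self) -> int:
        return len(self.scalar_channels)

    def triaxial_columns(self) -> list[str]:
        return [f"{p}_{a}" for p in self.positions for a in AXES]

    def columns(self) -> list[str]:
        return [
            self.time_column,
            *self.triaxial_columns(),
            *self.scalar_channels,
            self.label_column,
        ]

    def to_dict(self) -> dict:
        return {
            "positions": list(self.positions),
            "scalar_channels": list(self.scalar_channels),
            "label_column": self.label_column,
            "time_column": self.time_column,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SensorLayout":
        return cls(
            positions=tuple(d["positions"]),
            scalar_channels=tuple(d.get("scalar_channels", ())),
            label_column=d.get("label_column", "label"),
            time_column=d.get("time_column", "t"),
        )


@dataclass
class MultiPositionRecording:
    """Synchronized multi-position sensor streams with a label track.

    ``triaxial`` has shape ``(P, 3, n)`` (position, axis, time) in units of g;
    ``scalars`` has shape ``(S, n)``; ``labels`` has shape ``(n,)`` and draws
    from a finite label set that typically includes a NULL/background class.
    """

    layout: SensorLayout
    triaxial: np.ndarray
    scalars: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.triaxial = np.asarray(self.triaxial, dtype=np.float64)
        P, S = self.layout.n_positions, self.layout.n_scalar
        if self.triaxial.ndim != 3 or self.triaxial.shape[:2] != (P, 3):
            raise IntegrityError(
                f"triaxial block must have shape ({P}, 3, n); got {self.triaxial.shape}"
            )
        n = self.triaxial.shape[2]
        self.scalars = np.asarray(self.scalars, dtype=np.float64)
        if self.scalars.size == 0:
            self.scalars = np.empty((S, n) if S == 0 else (S, 0), dtype=np.float64)
        if self.scalars.shape != (S, n):
            raise IntegrityError(
                f"scalar block must have shape ({S}, {n}); got {self.scalars.shape}"
            )
        self.labels = np.asarray(self.labels).astype(str)
        if self.labels.shape != (n,):
            raise IntegrityError(
                f"label track must have length {n}; got shape {self.labels.shape}"
            )
        if not np.isfinite(self.triaxial).all() or not np.isfinite(self.scalars).all():
            raise IntegrityError("recording contains missing or non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.triaxial.shape[2]

    @property
    def n_positions(self) -> int:
        return self.layout.n_positions

    @property
    def n_channels(self) -> int:
        """Total channel count, 3·P + S."""
        return 3 * self.n_positions + self.layout.n_scalar

    @property
    def label_set(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels.tolist())))

    def axis_matrix(self, axis: int | str) -> np.ndarray:
        """The ``P x n`` matrix of one axis across all positions (a view)."""
        a = AXES.index(axis) if isinstance(axis, str) else int(axis)
        return self.triaxial[:, a, :]

    def channel_matrix(self) -> np.ndarray:
        """All channels stacked as a ``(3P + S) x n`` matrix (tri-axial first,
        position-major / axis-minor row order, then scalar channels)."""
        tri = self.triaxial.reshape(3 * self.n_positions, self.n_samples)
        return np.vstack([tri, self.scalars]) if self.layout.n_scalar else tri

    def channel_names(self) -> list[str]:
        return self.layout.triaxial_columns() + list(self.layout.scalar_channels)

    def select_positions(self, positions: Sequence[str]) -> "MultiPositionRecording":
        """Sub-recording restricted to the given positions (order preserved
        as passed)."""
        idx = []
        for p in positions:
            if p not in self.layout.positions:
                raise ParameterError(f"unknown position {p!r}")
            idx.append(self.layout.positions.index(p))
        layout = replace(self.layout, positions=tuple(positions))
        return MultiPositionRecording(
            layout, self.triaxial[idx], self.scalars.copy(), self.labels.copy()
        )

    def slice_time(self, start: int, stop: int) -> "MultiPositionRecording":
        """Contiguous time slice ``[start, stop)`` as a new recording."""
        if not 0 <= start <= stop <= self.n_samples:
            raise ParameterError(f"invalid slice [{start}, {stop})")
        return MultiPositionRecording(
            self.layout,
            self.triaxial[:, :, start:stop].copy(),
            self.scalars[:, start:stop].copy(),
            self.labels[start:stop].copy(),
        )


# ---------------------------------------------------------------------------
# File I/O: CSV dialect and binary fixture container
# ---------------------------------------------------------------------------


def write_recording_csv(rec: MultiPositionRecording, path) -> None:
    """Write the recording in the package CSV dialect (header mandatory)."""
    cols: dict[str, np.ndarray] = {rec.layout.time_column: np.arange(rec.n_samples)}
    for pi, p in enumerate(rec.layout.positions):
        for ai, a in enumerate(AXES):
            cols[f"{p}_{a}"] = rec.triaxial[pi, ai]
    for si, s in enumerate(rec.layout.scalar_channels):
        cols[s] = rec.scalars[si]
    cols[rec.layout.label_column] = rec.labels
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_recording(path, layout: SensorLayout) -> MultiPositionRecording:
    """Read a CSV recording and validate it against the declared layout.

    Raises :class:`FormatError` naming the first missing column, and
    :class:`IntegrityError` on missing samples.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in layout.columns():
        if col not in df.columns:
            raise FormatError(f"column {col!r} missing from {path}")
    n = len(df)
    tri = np.empty((layout.n_positions, 3, n))
    for pi, p in enumerate(layout.positions):
        for ai, a in enumerate(AXES):
            tri[pi, ai] = df[f"{p}_{a}"].to_numpy(dtype=float)
    scal = np.empty((layout.n_scalar, n))
    for si, s in enumerate(layout.scalar_channels):
        scal[si] = df[s].to_numpy(dtype=float)
    labels = df[layout.label_column].to_numpy().astype(str)
    return MultiPositionRecording(layout, tri, scal, labels)


def write_fixture(rec: MultiPositionRecording, path, manifest: Mapping | None = None) -> None:
    """Write the binary columnar fixture container (HDF5).

    Stores the channel matrices at full float64 precision so a round trip is
    value-identical, plus the layout and an optional provenance manifest
    (seed, generator parameters) as JSON attributes.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("triaxial", data=rec.triaxial)
        f.create_dataset("scalars", data=rec.scalars)
        f.create_dataset(
            "labels", data=np.array(rec.labels.tolist(), dtype=h5py.string_dtype())
        )
        f.attrs["layout"] = json.dumps(rec.layout.to_dict())
        if manifest is not None:
            f.attrs["manifest"] = json.dumps(dict(manifest))


def read_fixture(path) -> MultiPositionRecording:
    with h5py.File(path, "r") as f:
        layout = SensorLayout.from_dict(json.loads(f.attrs["layout"]))
        tri = f["triaxial"][()]
        scal = f["scalars"][()]
        labels = np.array([s.decode() for s in f["labels"][()]])
    return MultiPositionRecording(layout, tri, scal, labels)


def read_fixture_manifest(path) -> dict | None:
    with h5py.File(path, "r") as f:
        raw = f.attrs.get("manifest")
    return None if raw is None else json.loads(raw)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean/sd, for z-scoring with statistics from one split."""

    triaxial_mean: np.ndarray  # (P, 3)
    triaxial_sd: np.ndarray
    scalar_mean: np.ndarray  # (S,)
    scalar_sd: np.ndarray


def compute_channel_stats(rec: MultiPositionRecording) -> ChannelStats:
    if rec.n_samples < 2:
        raise ParameterError("need at least 2 samples per channel to normalize")
    return ChannelStats(
        triaxial_mean=rec.triaxial.mean(axis=2),
        triaxial_sd=rec.triaxial.std(axis=2),
        scalar_mean=rec.scalars.mean(axis=1),
        scalar_sd=rec.scalars.std(axis=1),
    )


def normalize_channels(
    rec: MultiPositionRecording, stats: ChannelStats | None = None
) -> MultiPositionRecording:
    """Per-channel z-score.  Constant channels map to all-zero.

    Pass ``stats`` computed on the training split to transform held-out data
    with training statistics (the usual leakage-free protocol).
    """
    if stats is None:
        stats = compute_channel_stats(rec)
    tsd = np.where(stats.triaxial_sd > 0, stats.triaxial_sd, 1.0)
    tri = (rec.triaxial - stats.triaxial_mean[:, :, None]) / tsd[:, :, None]
    tri[np.broadcast_to((stats.triaxial_sd == 0)[:, :, None], tri.shape)] = 0.0
    if rec.layout.n_scalar:
        ssd = np.where(stats.scalar_sd > 0, stats.scalar_sd, 1.0)
        scal = (rec.scalars - stats.scalar_mean[:, None]) / ssd[:, None]
        scal[np.broadcast_to((stats.scalar_sd == 0)[:, None], scal.shape)] = 0.0
    else:
        scal = rec.scalars.copy()
    return MultiPositionRecording(rec.layout, tri, scal, rec.labels.copy())


# ---------------------------------------------------------------------------
# Windowing and action pictures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowedSample:
    """One sliding window ``[start, start + length)`` over a recording.

    The window's label is the label of its final timestamp.
    """

    recording: MultiPositionRecording
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start + self.length > self.recording.n_samples:
            raise ParameterError(
                f"window [{self.start}, {self.start + self.length}) out of range"
            )

    @property
    def stop(self) -> int:
        return self.start + self.length

    @property
    def label(self) -> str:
        return str(self.recording.labels[self.stop - 1])

    def triaxial(self) -> np.ndarray:
        """View of shape (P, 3, T)."""
        return self.recording.triaxial[:, :, self.start : self.stop]

    def scalars(self) -> np.ndarray:
        """View of shape (S, T)."""
        return self.recording.scalars[:, self.start : self.stop]


def window_step(window: int, overlap: float) -> int:
    """Step between window starts: ``round(window * (1 - overlap))``, min 1."""
    if window < 1:
        raise ParameterError("window must be >= 1")
    if not 0.0 <= overlap < 1.0:
        raise ParameterError("overlap must lie in [0, 1)")
    return max(1, round(window * (1.0 - overlap)))


def segment_windows(
    rec: MultiPositionRecording, window: int, overlap: float = 0.5
) -> list[WindowedSample]:
    """Cut the recording into overlapping windows.

    Starts are 0, step, 2·step, ... with ``step = round(window·(1−overlap))``;
    the count is ``floor((n − window)/step) + 1`` when ``n ≥ window`` and 0
    otherwise (an over-short recording is not an error).
    """
    step = window_step(window, overlap)
    n = rec.n_samples
    if n < window:
        return []
    count = (n - window) // step + 1
    return [WindowedSample(rec, i * step, window) for i in range(count)]


@dataclass(frozen=True)
class ActionPictureSet:
    """The per-axis network input built from one window.

    ``axis_pictures`` has shape ``(3, P, T)``: one P×T picture per axis, rows
    in the recording's configured position order.  ``scalar_picture`` (S×T)
    is present iff the recording has scalar channels, giving the "3 or 4
    pictures" input of the mixed-sensor model variants.
    """

    axis_pictures: np.ndarray
    scalar_picture: np.ndarray | None
    label: str

    def __post_init__(self) -> None:
        ap = np.asarray(self.axis_pictures, dtype=np.float64)
        if ap.ndim != 3 or ap.shape[0] != 3:
            raise ParameterError(f"axis_pictures must be (3, P, T); got {ap.shape}")
        object.__setattr__(self, "axis_pictures", ap)
        if self.scalar_picture is not None:
            sp = np.asarray(self.scalar_picture, dtype=np.float64)
            if sp.ndim != 2 or sp.shape[1] != ap.shape[2]:
                raise ParameterError(
                    f"scalar_picture must be (S, T={ap.shape[2]}); got {sp.shape}"
                )
            object.__setattr__(self, "scalar_picture", sp)


def build_action_pictures(w: WindowedSample) -> ActionPictureSet:
    """Assemble the 3 axis pictures (plus the scalar picture when present).

    Pure re-indexing: entry (p, c) of the axis-a picture is the raw channel
    value of position p, axis a at timestamp ``start + c``.
    """
    tri = w.triaxial()  # (P, 3, T)
    axis_pics = np.ascontiguousarray(np.transpose(tri, (1, 0, 2)))  # (3, P, T)
    scal = w.scalars()
    scalar_pic = np.ascontiguousarray(scal) if scal.shape[0] else None
    return ActionPictureSet(axis_pics, scalar_pic, w.label)


def windows_to_arrays(
    samples: Sequence[WindowedSample],
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Stack windows into batch arrays: ``(N, 3, P, T)`` axis pictures,
    ``(N, S, T)`` scalar pictures (or None), and the label list."""
    if not samples:
        raise ParameterError("no windows to stack")
    pics = [build_action_pictures(w) for w in samples]
    xa = np.stack([p.axis_pictures for p in pics])
    xs = (
        np.stack([p.scalar_picture for p in pics])
        if pics[0].scalar_picture is not None
        else None
    )
    return xa, xs, [p.label for p in pics]
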