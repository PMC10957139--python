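"""Core IMU data types, static sensor calibration, windowing, and trace I/O.

Conventions used throughout the package: accelerometer channels are in g,
gyroscope channels in deg/s, sampling rate ``fs`` in Hz. Unit conversions
happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImuTrace",
    "AccelCalibration",
    "GyroCalibration",
    "Window",
    "calibrate_gyro",
    "apply_accel_calibration",
    "apply_gyro_calibration",
    "sliding_windows",
    "read_trace_csv",
    "write_trace_csv",
]

TRACE_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


@dataclass
class ImuTrace:
    """A 6-channel inertial stream: 3-axis accel (g) + 3-axis gyro (deg/s).

    ``accel`` and ``gyro`` are (n, 3) arrays sharing one length. Timestamps
    are optional; when absent, uniform sampling at ``fs`` is assumed.
    """

    accel: np.ndarray
    gyro: np.ndarray
    fs: float
    t: np.ndarray | None = None
    label: str | None = None
    participant_id: int | None = None

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must be an (n, 3) array")
        if self.gyro.shape != self.accel.shape:
            raise ValueError("gyro and accel must share one (n, 3) shape")
        if not self.fs > 0:
            raise ValueError("sampling rate fs must be positive")
        if self.t is not None:
            self.t = np.asarray(self.t, dtype=float)
            if self.t.shape != (len(self.accel),):
                raise ValueError("t must have one entry per sample")
            if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
                raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.accel)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def times(self) -> np.ndarray:
        """Per-sample times; synthesized from fs when no timestamps exist."""
        if self.t is not None:
            return self.t
        return np.arange(len(self)) / self.fs

    def slice(self, start: int, stop: int) -> "ImuTrace":
        return replace(
            self,
            accel=self.accel[start:stop],
            gyro=self.gyro[start:stop],
            t=None if self.t is None else self.t[start:stop],
        )


@dataclass(frozen=True)
class AccelCalibration:
    """Per-axis gain/bias of the six-position static accelerometer model.

    The raw reading on axis i is S_i = G_i * A_i + B_i; calibration inverts
    this as A_i = (S_i - B_i) / G_i.
    """

    gains: tuple[float, float, float]
    biases: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(g == 0 for g in self.gains):
            raise ValueError("accelerometer gains must be nonzero")


@dataclass(frozen=True)
class GyroCalibration:
    """Static gyroscope bias per axis, in deg/s."""

    static_bias: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.static_bias)):
            raise ValueError("gyro bias must be finite")


@dataclass(frozen=True)
class Window:
    """A contiguous, fully-contained slice of a parent trace."""

    samples: ImuTrace
    length_s: float
    label: str | None = None
    start_index: int = 0

    def __len__(self) -> int:
        return len(self.samples)


def calibrate_gyro(static_trace: ImuTrace) -> GyroCalibration:
    """Estimate static gyro bias from a nominally static recording.

    The bias on each axis is the arithmetic mean of that axis, so that
    subtracting it leaves zero-mean channels.
    """
    if len(static_trace) == 0:
        raise ValueError("cannot calibrate from an empty trace")
    bias = static_trace.gyro.mean(axis=0)
    return GyroCalibration(static_bias=tuple(float(b) for b in bias))


def apply_gyro_calibration(trace: ImuTrace, cal: GyroCalibration) -> ImuTrace:
    return replace(trace, gyro=trace.gyro - np.asarray(cal.static_bias))


def apply_accel_calibration(raw: np.ndarray, cal: AccelCalibration) -> np.ndarray:
    """Recover true acceleration A_i = (S_i - B_i) / G_i per axis.

    ``raw`` is a length-3 triplet or an (n, 3) array.
    """
    raw = np.asarray(raw, dtype=float)
    gains = np.asarray(cal.gains, dtype=float)
    biases = np.asarray(cal.biases, dtype=float)
    return (raw - biases) / gains


def calibrate_trace(
    trace: ImuTrace,
    accel_cal: AccelCalibration | None = None,
    gyro_cal: GyroCalibration | None = None,
) -> ImuTrace:
    """Apply accelerometer and/or gyroscope calibration to a full trace."""
    out = trace
    if accel_cal is not None:
        out = replace(out, accel=apply_accel_calibration(out.accel, accel_cal))
    if gyro_cal is not None:
        out = apply_gyro_calibration(out, gyro_cal)
    return out


def sliding_windows(
    trace: ImuTrace, length_s: float, stride_s: float
) -> Iterator[Window]:
    """Yield fully-contained fixed-length windows starting every stride.

    Sample counts follow round(seconds * fs); partial trailing windows are
    dropped so every window carries the same number of samples.
    """
    if length_s <= 0 or stride_s <= 0:
        raise ValueError("window length and stride must be positive")
    n_len = int(round(length_s * trace.fs))
    n_stride = int(round(stride_s * trace.fs))
    n = len(trace)
    start = 0
    while start + n_len <= n:
        yield Window(
            samples=trace.slice(start, start + n_len),
            length_s=length_s,
            label=trace.label,
            start_index=start,
        )
        start += n_stride


def read_trace_csv(
    path: str | Path,
    fs: float | None = None,
    label: str | None = None,
    participant_id: int | None = None,
) -> ImuTrace:
    """Read a delimited-text trace with columns t, ax, ay, az, gx, gy, gz[, label].

    The ``t`` column may be absent, in which case ``fs`` is required. When a
    ``t`` column exists and ``fs`` is not given, fs is taken as the inverse
    median sample spacing.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    t = df["t"].to_numpy(float) if "t" in df.columns else None
    if fs is None:
        if t is None or len(t) < 2:
            raise ValueError("fs must be given when the file has no usable t column")
        fs = 1.0 / float(np.median(np.diff(t)))
    if label is None and "label" in df.columns:
        uniq = df["label"].unique()
        label = str(uniq[0]) if len(uniq) == 1 else None
    return ImuTrace(
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        fs=fs,
        t=t,
        label=label,
        participant_id=participant_id,
    )


def write_trace_csv(trace: ImuTrace, path: str | Path) -> None:
    data = {
        "t": trace.times(),
        "ax": trace.accel[:, 0],
        "ay": trace.accel[:, 1],
        "az": trace.accel[:, 2],
        "gx": trace.gyro[:, 0],
        "gy": trace.gyro[:, 1],
        "gz": trace.gyro[:, 2],
    }
    df = pd.DataFrame(data)
    if trace.label is not None:
        df["label"] = trace.label
    df.to_csv(path, index=False)
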