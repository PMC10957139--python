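"""Per-window feature extraction.

Two schemes are provided:

* full (241-dim): 30 per-channel statistics applied to the 6 raw channels and
  to the accelerometer vector-sum and gyroscope sum series (8 x 30 = 240),
  plus one time-window feature.
* light (10-dim): maxima, minima, range, variance, and standard deviation of
  the accelerometer vector-sum and gyroscope sum series.

The vector-sum series are Ax^2+Ay^2+Az^2 (accel) and wx+wy+wz (gyro), per
sample. No normalization or standardization is applied to raw data.

Several statistics are only loosely named in the wider HAR literature; the
exact definitions pinned here are recorded in PINNED_DEFINITIONS so a
sidecar JSON can document (and alternates can replace) them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .imu_core import Window

__all__ = [
    "FeatureVector",
    "vector_sum_channels",
    "extract_full_features",
    "extract_light_features",
    "features_for_windows",
    "FULL_FEATURE_NAMES",
    "LIGHT_FEATURE_NAMES",
    "PINNED_DEFINITIONS",
]


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def vector_sum_channels(window: Window) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample accel vector sum (Ax^2+Ay^2+Az^2) and gyro sum (wx+wy+wz)."""
    if len(window) == 0:
        raise ValueError("window is empty")
    a = window.samples.accel
    g = window.samples.gyro
    return (a**2).sum(axis=1), g.sum(axis=1)


@dataclass(frozen=True)
class _Ctx:
    fs: float
    triplet: np.ndarray  # (n, 3) parent sensor triplet of the series


def _guarded(x: float) -> float:
    return float(x) if np.isfinite(x) else 0.0


def _dominant_sign(x, ctx):
    pos = int(np.sum(x > 0))
    neg = int(np.sum(x < 0))
    return float(np.sign(pos - neg))


def _entropy(x, ctx):
    counts, _ = np.histogram(x, bins=16)
    return _guarded(sstats.entropy(counts))


def _integration(x, ctx):
    return float(np.trapezoid(x, dx=1.0 / ctx.fs))


def _iqr(x, ctx):
    return float(sstats.iqr(x))


def _kurtosis(x, ctx):
    if np.ptp(x) == 0:
        return 0.0
    return _guarded(sstats.kurtosis(x))


def _mean_abs_dev(x, ctx):
    return float(np.mean(np.abs(x - x.mean())))


def _rolling(x, ctx) -> pd.core.window.rolling.Rolling:
    win = max(2, min(len(x), int(round(ctx.fs))))  # 1 s moving window
    return pd.Series(x).rolling(win, min_periods=1)


def _mov(statname):
    def f(x, ctx):
        r = _rolling(x, ctx)
        series = getattr(r, statname)()
        return _guarded(np.nanmean(series.to_numpy()))

    return f


def _autocorr(x, ctx):
    m = x.mean()
    denom = np.sum((x - m) ** 2)
    if denom == 0:
        return 0.0
    return float(np.sum((x[:-1] - m) * (x[1:] - m)) / denom)


def _avg_vec_norm(x, ctx):
    return float(np.mean(np.linalg.norm(ctx.triplet, axis=1)))


def _avg_z_score(x, ctx):
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(np.mean(np.abs((x - x.mean()) / sd)))


def _norm(x, ctx):
    return float(np.linalg.norm(x))


def _pearson_cc(x, ctx):
    if np.ptp(x[:-1]) == 0 or np.ptp(x[1:]) == 0:
        return 0.0
    return _guarded(np.corrcoef(x[:-1], x[1:])[0, 1])


def _slope_sign_change(x, ctx):
    d = np.sign(np.diff(x))
    return float(np.sum(np.abs(np.diff(d)) == 2))


def _signal_mag_area(x, ctx):
    return float(np.mean(np.abs(ctx.triplet).sum(axis=1)))


def _variation(x, ctx):
    m = x.mean()
    if abs(m) < 1e-15:
        return 0.0
    return float(x.std(ddof=1) / m)


def _zero_crossing(x, ctx):
    s = np.sign(x)
    return float(np.sum(np.abs(np.diff(s)) == 2))


# Name -> definition. Order fixed; variance/SD use the sample (n-1) convention.
_STATISTICS: dict[str, Callable] = {
    "dominant_sign": _dominant_sign,
    "entropy": _entropy,
    "integration": _integration,
    "iqr": _iqr,
    "kurtosis": _kurtosis,
    "mean_abs_dev": _mean_abs_dev,
    "max": lambda x, ctx: float(np.max(x)),
    "min": lambda x, ctx: float(np.min(x)),
    "mean": lambda x, ctx: float(np.mean(x)),
    "mov_mean": _mov("mean"),
    "mov_median": _mov("median"),
    "mov_max": _mov("max"),
    "mov_min": _mov("min"),
    "mov_sd": _mov("std"),
    "mov_var": _mov("var"),
    "mov_mad": lambda x, ctx: _guarded(
        np.nanmean(
            _rolling(x, ctx).apply(lambda w: np.mean(np.abs(w - w.mean())), raw=True)
        )
    ),
    "autocorr": _autocorr,
    "avg_vec_norm": _avg_vec_norm,
    "avg_z_score": _avg_z_score,
    "median": lambda x, ctx: float(np.median(x)),
    "norm": _norm,
    "pearson_cc": _pearson_cc,
    "range": lambda x, ctx: float(np.ptp(x)),
    "skewness": lambda x, ctx: 0.0 if np.ptp(x) == 0 else _guarded(sstats.skew(x)),
    "slope_sign_change": _slope_sign_change,
    "signal_mag_area": _signal_mag_area,
    "sd": lambda x, ctx: float(np.std(x, ddof=1)),
    "variance": lambda x, ctx: float(np.var(x, ddof=1)),
    "variation": _variation,
    "zero_crossing": _zero_crossing,
}

_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz", "avs", "gsum")
_LIGHT_STATS = ("max", "min", "range", "variance", "sd")

FULL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in _CHANNELS for stat in _STATISTICS
) + ("time_window",)
LIGHT_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in ("avs", "gsum") for stat in _LIGHT_STATS
)

PINNED_DEFINITIONS = {
    "dominant_sign": "sign of the sample majority (count(+) vs count(-))",
    "entropy": "Shannon entropy (nats) of a 16-bin histogram",
    "integration": "trapezoidal integral over the window at dx = 1/fs",
    "mov_*": "mean of a 1 s moving-window statistic (min_periods=1)",
    "autocorr": "lag-1 sample autocorrelation (overall mean/variance)",
    "avg_vec_norm": "mean per-sample Euclidean norm of the parent sensor triplet",
    "avg_z_score": "mean absolute z-score (sample SD)",
    "norm": "Euclidean norm of the series",
    "pearson_cc": "Pearson correlation of the series with its 1-sample lag",
    "variation": "coefficient of variation, SD/mean (0 when mean ~ 0)",
    "signal_mag_area": "mean of summed absolute parent-triplet channel values",
    "zero_crossing": "count of strict sign changes between consecutive samples",
    "slope_sign_change": "count of first-difference sign changes",
    "variance_sd": "sample (n-1) convention",
    "time_window": "elapsed seconds spanned by the window; (n-1)/fs without timestamps",
}


def _series_and_ctx(window: Window) -> dict[str, tuple[np.ndarray, _Ctx]]:
    trace = window.samples
    avs, gsum = vector_sum_channels(window)
    accel_ctx = _Ctx(fs=trace.fs, triplet=trace.accel)
    gyro_ctx = _Ctx(fs=trace.fs, triplet=trace.gyro)
    return {
        "ax": (trace.accel[:, 0], accel_ctx),
        "ay": (trace.accel[:, 1], accel_ctx),
        "az": (trace.accel[:, 2], accel_ctx),
        "gx": (trace.gyro[:, 0], gyro_ctx),
        "gy": (trace.gyro[:, 1], gyro_ctx),
        "gz": (trace.gyro[:, 2], gyro_ctx),
        "avs": (avs, accel_ctx),
        "gsum": (gsum, gyro_ctx),
    }


def _time_window(window: Window) -> float:
    trace = window.samples
    if trace.t is not None:
        return float(trace.t[-1] - trace.t[0])
    return (len(trace) - 1) / trace.fs


def extract_full_features(window: Window) -> FeatureVector:
    """Extract the 241-dimensional full feature scheme from one window."""
    if len(window) < 2:
        raise ValueError("window must contain at least 2 samples")
    series = _series_and_ctx(window)
    values = np.empty(len(FULL_FEATURE_NAMES))
    i = 0
    for ch in _CHANNELS:
        x, ctx = series[ch]
        for stat_fn in _STATISTICS.values():
            values[i] = stat_fn(x, ctx)
            i += 1
    values[i] = _time_window(window)
    return FeatureVector(values=values, names=FULL_FEATURE_NAMES)


def extract_light_features(window: Window) -> FeatureVector:
    """Extract the 10-dimensional lightweight scheme (vector-sum statistics)."""
    if len(window) < 2:
        raise ValueError("window must contain at least 2 samples")
    series = _series_and_ctx(window)
    values = np.empty(len(LIGHT_FEATURE_NAMES))
    i = 0
    for ch in ("avs", "gsum"):
        x, ctx = series[ch]
        for stat in _LIGHT_STATS:
            values[i] = _STATISTICS[stat](x, ctx)
            i += 1
    return FeatureVector(values=values, names=LIGHT_FEATURE_NAMES)


def features_for_windows(
    windows: Sequence[Window], scheme: str = "light"
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Stack per-window features into an (n_windows, dim) matrix."""
    if scheme == "light":
        fn, names = extract_light_features, LIGHT_FEATURE_NAMES
    elif scheme == "full":
        fn, names = extract_full_features, FULL_FEATURE_NAMES
    else:
        raise ValueError("scheme must be 'light' or 'full'")
    X = np.stack([fn(w).values for w in windows]) if windows else np.empty((0, len(names)))
    return X, names
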