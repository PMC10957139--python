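"""Synthetic ear-worn IMU data: head-rotation trajectories with ground-truth
orientation, nine activity-of-daily-living classes (including falls), and a
configurable sensor-error model.

The generator emulates ~100 Hz 6-channel traces from an ear-mounted IMU. Head
rotations use raised-cosine (bell-shaped) angular-velocity pulses that
integrate exactly to the commanded angles; activities are built from
class-characteristic signal families (gait harmonics, impact transients,
gravity-dominated postures) layered on the body-frame gravity vector.

Sensor errors follow the usual MEMS model: static gyro bias, gyro white noise
plus slow random-walk drift, per-axis accelerometer gain/bias errors, and
accelerometer white noise. Every stochastic operation is a pure function of
its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import euler_rates_to_body_rates, gravity_body
from .imu_core import ImuTrace, write_trace_csv

__all__ = [
    "NoiseSpec",
    "TrajectoryTruth",
    "ActivitySpec",
    "ACTIVITY_CLASSES",
    "simulate_head_trajectory",
    "imu_from_trajectory",
    "simulate_activity",
    "simulate_dataset",
    "default_participant_style",
]

ACTIVITY_CLASSES = ("W", "R", "J", "St", "Tl", "Tr", "Si", "L", "F")


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor-error model parameters.

    gyro_bias          deg/s per axis, constant over a trace
    gyro_noise_sd      deg/s, white
    gyro_drift_rw_sd   deg/s/sqrt(s), random-walk increment density
    accel_noise_sd     g, white
    accel_gain         unitless per axis (raw = gain * true + bias)
    accel_bias         g per axis
    linear_accel_sd    g, band-limited translational artifact amplitude
    """

    gyro_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro_noise_sd: float = 0.5
    gyro_drift_rw_sd: float = 0.05
    accel_noise_sd: float = 0.02
    accel_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    accel_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    linear_accel_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.gyro_noise_sd, self.gyro_drift_rw_sd, self.accel_noise_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(gyro_noise_sd=0.0, gyro_drift_rw_sd=0.0, accel_noise_sd=0.0)


@dataclass
class TrajectoryTruth:
    """Ground-truth orientation series and exact body angular rates."""

    t: np.ndarray  # s
    roll: np.ndarray  # deg
    pitch: np.ndarray  # deg
    yaw: np.ndarray  # deg
    body_rate: np.ndarray  # (n, 3) deg/s
    fs: float

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ActivitySpec:
    class_id: str
    duration_s: float = 25.0
    participant_style: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_id not in ACTIVITY_CLASSES:
            raise ValueError(f"unknown activity class {self.class_id!r}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


def _pulse_angle_and_rate(
    t: np.ndarray, t0: float, width: float, amplitude_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Raised-cosine rate pulse starting at t0; returns (angle, rate) series.

    rate(u) = A/width * (1 - cos(2 pi u / width)) for u in [0, width], whose
    integral is exactly A, with zero rate at both endpoints.
    """
    angle = np.zeros_like(t)
    rate = np.zeros_like(t)
    if width <= 0 or amplitude_deg == 0:
        return angle, rate
    u = t - t0
    inside = (u >= 0) & (u <= width)
    ui = u[inside]
    rate[inside] = amplitude_deg / width * (1 - np.cos(2 * np.pi * ui / width))
    angle[inside] = amplitude_deg * (ui / width - np.sin(2 * np.pi * ui / width) / (2 * np.pi))
    angle[u > width] = amplitude_deg
    return angle, rate


def simulate_head_trajectory(
    kind: str,
    target_azimuth: float,
    target_elevation: float,
    duration_s: float,
    peak_rate: float = 60.0,
    seed: int = 0,
    fs: float = 100.0,
    target2_azimuth: float | None = None,
    target2_elevation: float | None = None,
) -> TrajectoryTruth:
    """Simulate a head rotation from origin to target(s) and back.

    ``simple``: origin -> target -> origin (2 rotation phases).
    ``complex``: origin -> target1 -> target2 -> origin (3 phases). The second
    target defaults to the mirrored azimuth at half elevation.

    Each phase's angular-velocity profile is a raised-cosine bell whose peak
    equals ``peak_rate`` for the dominant angle; the profile integrates
    exactly to the commanded rotation, so the trajectory ends back at (0, 0).
    Azimuth drives yaw and elevation drives pitch; roll stays zero.
    """
    if kind not in ("simple", "complex"):
        raise ValueError("kind must be 'simple' or 'complex'")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if abs(target_azimuth) > 90 or abs(target_elevation) > 90:
        raise ValueError("targets must lie within +/-90 deg")

    if kind == "simple":
        waypoints = [(target_azimuth, target_elevation), (0.0, 0.0)]
    else:
        if target2_azimuth is None:
            target2_azimuth = -target_azimuth
        if target2_elevation is None:
            target2_elevation = target_elevation / 2.0
        waypoints = [
            (target_azimuth, target_elevation),
            (target2_azimuth, target2_elevation),
            (0.0, 0.0),
        ]

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # Per-phase commanded increments in (yaw, pitch).
    prev = (0.0, 0.0)
    deltas = []
    for wp in waypoints:
        deltas.append((wp[0] - prev[0], wp[1] - prev[1]))
        prev = wp
    widths = []
    for dyaw, dpitch in deltas:
        dominant = max(abs(dyaw), abs(dpitch))
        widths.append(2.0 * dominant / peak_rate if dominant > 0 else 0.0)
    total_motion = sum(widths)
    if total_motion > duration_s:
        raise ValueError("duration too short for the commanded rotations at peak_rate")

    # Distribute the remaining time as rest periods around the pulses; a seeded
    # jitter varies the holds without touching the rotation profiles.
    rng = np.random.default_rng(seed)
    n_rest = len(widths) + 1
    rest_w = rng.uniform(0.7, 1.3, size=n_rest)
    rests = (duration_s - total_motion) * rest_w / rest_w.sum()

    yaw = np.zeros(n)
    pitch = np.zeros(n)
    dyaw_t = np.zeros(n)
    dpitch_t = np.zeros(n)
    t0 = rests[0]
    for (dy, dp), width, rest in zip(deltas, widths, rests[1:]):
        ya, yr = _pulse_angle_and_rate(t, t0, width, dy)
        pa, pr = _pulse_angle_and_rate(t, t0, width, dp)
        yaw += ya
        pitch += pa
        dyaw_t += yr
        dpitch_t += pr
        t0 += width + rest

    roll = np.zeros(n)
    droll_t = np.zeros(n)
    body = np.empty((n, 3))
    for i in range(n):
        body[i] = euler_rates_to_body_rates(
            roll[i], pitch[i], droll_t[i], dpitch_t[i], dyaw_t[i]
        )
    return TrajectoryTruth(t=t, roll=roll, pitch=pitch, yaw=yaw, body_rate=body, fs=fs)


def _sensor_noise(
    n: int, fs: float, noise: NoiseSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Additive gyro error (bias + drift + white) and accel white noise."""
    dt = 1.0 / fs
    gyro_err = np.tile(np.asarray(noise.gyro_bias, float), (n, 1))
    if noise.gyro_drift_rw_sd > 0:
        steps = rng.normal(0.0, noise.gyro_drift_rw_sd * np.sqrt(dt), size=(n, 3))
        gyro_err += np.cumsum(steps, axis=0)
    if noise.gyro_noise_sd > 0:
        gyro_err += rng.normal(0.0, noise.gyro_noise_sd, size=(n, 3))
    accel_err = np.zeros((n, 3))
    if noise.accel_noise_sd > 0:
        accel_err += rng.normal(0.0, noise.accel_noise_sd, size=(n, 3))
    return gyro_err, accel_err


def _linear_artifact(
    n: int, fs: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited translational acceleration (g), ~0-5 Hz."""
    if sd <= 0:
        return np.zeros((n, 3))
    white = rng.normal(0.0, 1.0, size=(n, 3))
    # simple moving-average low-pass, then rescale to the requested sd
    k = max(3, int(round(fs / 5.0)))
    kernel = np.ones(k) / k
    smooth = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, white)
    s = smooth.std(axis=0, ddof=0)
    s[s == 0] = 1.0
    return smooth / s * sd


def imu_from_trajectory(
    truth: TrajectoryTruth, noise: NoiseSpec, fs: float | None = None, seed: int = 0
) -> ImuTrace:
    """Render an IMU trace from a ground-truth orientation series.

    gyro  = true body rate + static bias + random-walk drift + white noise
    accel = gravity rotated into the body frame (g), then gain/bias-corrupted
            and white-noise-perturbed; optional band-limited linear artifact.
    """
    fs = truth.fs if fs is None else fs
    if fs != truth.fs:
        raise ValueError("truth must be sampled at the requested fs")
    n = len(truth)
    rng = np.random.default_rng(seed)
    accel_clean = np.stack(
        [gravity_body(r, p) for r, p in zip(truth.roll, truth.pitch)]
    )
    accel_clean = accel_clean + _linear_artifact(n, fs, noise.linear_accel_sd, rng)
    gyro_err, accel_white = _sensor_noise(n, fs, noise, rng)
    gains = np.asarray(noise.accel_gain, float)
    biases = np.asarray(noise.accel_bias, float)
    accel = accel_clean * gains + biases + accel_white
    gyro = truth.body_rate + gyro_err
    return ImuTrace(accel=accel, gyro=gyro, fs=fs, t=truth.t.copy())


def default_participant_style(rng: np.random.Generator) -> dict:
    """Per-participant amplitude/cadence/phase/posture offsets."""
    return {
        "amp": float(rng.uniform(0.85, 1.15)),
        "cadence": float(rng.uniform(0.9, 1.1)),
        "phase": float(rng.uniform(0, 2 * np.pi)),
        "tilt_roll": float(rng.normal(0.0, 3.0)),
        "tilt_pitch": float(rng.normal(0.0, 3.0)),
    }


def _gait(
    t: np.ndarray,
    f0: float,
    vert_amp: float,
    horiz_amp: float,
    gyro_amp: float,
    phase: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Periodic gait harmonics: (accel additive (g), gyro additive (deg/s))."""
    n = len(t)
    accel = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    w = 2 * np.pi * f0
    accel[:, 2] = vert_amp * np.sin(w * t + phase) + 0.3 * vert_amp * np.sin(
        2 * w * t + 1.7 * phase
    )
    accel[:, 0] = horiz_amp * np.sin(0.5 * w * t + phase)
    accel[:, 1] = 0.8 * horiz_amp * np.sin(0.5 * w * t + phase + 1.1)
    gyro[:, 0] = gyro_amp * np.sin(0.5 * w * t + phase + 0.4)
    gyro[:, 1] = 0.8 * gyro_amp * np.sin(w * t + phase)
    gyro[:, 2] = 0.5 * gyro_amp * np.sin(0.5 * w * t + phase + 2.0)
    return accel, gyro


def _posture(
    t: np.ndarray,
    roll: float,
    pitch: float,
    fidget_amp: float,
    fidget_hz: float,
    gyro_amp: float,
    phase: float,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(t)
    accel = np.tile(gravity_body(roll, pitch), (n, 1))
    w = 2 * np.pi * fidget_hz
    accel[:, 2] += fidget_amp * np.sin(w * t + phase)
    accel[:, 1] += 0.6 * fidget_amp * np.sin(0.7 * w * t + phase + 0.9)
    gyro = np.zeros((n, 3))
    gyro[:, 0] = gyro_amp * np.sin(w * t + phase + 0.3)
    gyro[:, 1] = 0.7 * gyro_amp * np.sin(0.8 * w * t + phase)
    return accel, gyro


def _raised_cos_pulse(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    u = (t - t0) / width
    out = np.zeros_like(t)
    inside = (u >= 0) & (u <= 1)
    out[inside] = 0.5 * (1 - np.cos(2 * np.pi * u[inside]))
    return out


def _activity_clean(
    class_id: str, t: np.ndarray, style: dict
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free accel (g, incl. gravity) and gyro (deg/s) for one class."""
    amp = style["amp"]
    cad = style["cadence"]
    ph = style["phase"]
    n = len(t)
    level = gravity_body(style["tilt_roll"], style["tilt_pitch"])

    if class_id in ("W", "R", "Tl", "Tr"):
        if class_id == "R":
            f0, va, ha, ga = 2.8 * cad, 0.35 * amp, 0.15 * amp, 25.0 * amp
        elif class_id == "W":
            f0, va, ha, ga = 1.8 * cad, 0.12 * amp, 0.05 * amp, 8.0 * amp
        else:  # turning: slower, tighter gait plus constant yaw rate
            f0, va, ha, ga = 1.5 * cad, 0.09 * amp, 0.04 * amp, 7.0 * amp
        accel, gyro = _gait(t, f0, va, ha, ga, ph)
        accel += level
        if class_id in ("Tl", "Tr"):
            gyro[:, 2] += 25.0 * amp  # counter-clockwise walk-in-circle
            accel[:, 1] += 0.06 * amp  # centripetal component
        return accel, gyro

    if class_id == "J":
        accel = np.tile(level, (n, 1))
        gyro = np.zeros((n, 3))
        period = 1.0 / (1.1 * cad)
        t0 = 0.3 + (ph / (2 * np.pi)) * period
        while t0 < t[-1]:
            # free-fall dip followed by a landing impact
            accel[:, 2] -= 0.85 * _raised_cos_pulse(t, t0, 0.25 * period)
            accel[:, 2] += 2.2 * amp * _raised_cos_pulse(t, t0 + 0.28 * period, 0.12 * period)
            gyro[:, 1] += 30.0 * amp * _raised_cos_pulse(t, t0, 0.3 * period)
            t0 += period
        return accel, gyro

    if class_id == "St":
        a, g = _posture(t, style["tilt_roll"], style["tilt_pitch"], 0.035 * amp, 0.4 * cad, 2.0, ph)
        return a, g
    if class_id == "Si":
        a, g = _posture(
            t, style["tilt_roll"], -15.0 + style["tilt_pitch"], 0.08 * amp, 0.9 * cad, 5.0, ph
        )
        return a, g
    if class_id == "L":
        a, g = _posture(
            t, 80.0 + style["tilt_roll"], style["tilt_pitch"], 0.012 * amp, 0.25 * cad, 0.8, ph
        )
        return a, g

    if class_id == "F":
        # repeated fall-and-recover cycles, as in a fall-collection session:
        # stand briefly, free-fall + impact onto the sofa, lie, rise again
        accel = np.tile(level, (n, 1))
        gyro = np.zeros((n, 3))
        period = 8.0 / cad
        dur_ff, dur_imp = 0.45, 0.25
        t_stand, t_lie_end = 2.5 / cad, 6.5 / cad
        cycle = 0
        while cycle * period < t[-1]:
            t0 = cycle * period
            t_fall = t0 + t_stand
            lying = (t >= t_fall + dur_ff + dur_imp) & (t < t0 + t_lie_end)
            upright = ~lying & (t >= t0) & (t < t0 + period)
            accel[lying] = gravity_body(85.0 + style["tilt_roll"], style["tilt_pitch"])
            accel[:, 2] -= 0.95 * _raised_cos_pulse(t, t_fall, dur_ff) * upright
            accel[:, 2] += 3.0 * amp * _raised_cos_pulse(t, t_fall + dur_ff, dur_imp) * upright
            accel[:, 1] += 0.8 * amp * _raised_cos_pulse(t, t_fall + dur_ff, dur_imp) * upright
            gyro[:, 0] += 180.0 * amp * _raised_cos_pulse(t, t_fall, dur_ff + dur_imp)
            gyro[:, 1] += 60.0 * amp * _raised_cos_pulse(t, t_fall + 0.1, dur_ff)
            # getting back up: slower, lower-magnitude counter-rotation
            t_rise = t0 + t_lie_end
            gyro[:, 0] -= 90.0 * amp * _raised_cos_pulse(t, t_rise, 1.0)
            accel[:, 2] += 0.5 * amp * _raised_cos_pulse(t, t_rise, 1.0)
            cycle += 1
        return accel, gyro

    raise ValueError(f"unknown activity class {class_id!r}")


def simulate_activity(
    spec: ActivitySpec, noise: NoiseSpec = NoiseSpec(), fs: float = 100.0
) -> ImuTrace:
    """Generate one labeled activity trace.

    Turning right is the exact gyro-z sign mirror of turning left under the
    same style and seed; all randomness is a pure function of ``spec.seed``.
    """
    class_id = spec.class_id
    mirror = class_id == "Tr"
    gen_class = "Tl" if mirror else class_id

    rng = np.random.default_rng(spec.seed)
    style = spec.participant_style or default_participant_style(rng)
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs

    accel_clean, gyro_clean = _activity_clean(gen_class, t, style)
    accel_clean += _linear_artifact(n, fs, noise.linear_accel_sd, rng)
    gyro_err, accel_white = _sensor_noise(n, fs, noise, rng)
    gains = np.asarray(noise.accel_gain, float)
    biases = np.asarray(noise.accel_bias, float)
    accel = accel_clean * gains + biases + accel_white
    gyro = gyro_clean + gyro_err
    if mirror:
        gyro[:, 2] = -gyro[:, 2]
    return ImuTrace(accel=accel, gyro=gyro, fs=fs, t=t, label=class_id)


def simulate_dataset(
    n_participants: int,
    per_class_duration_s: float = 25.0,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    fs: float = 100.0,
    classes: Sequence[str] = ACTIVITY_CLASSES,
) -> list[ImuTrace]:
    """Simulate a labeled multi-participant activity dataset.

    Style parameters and per-participant sensor imperfections (static gyro
    bias up to 2 deg/s, accel gain/bias errors) are drawn once per
    participant. Identical seeds yield identical datasets.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    traces: list[ImuTrace] = []
    for pid in range(n_participants):
        style = default_participant_style(rng)
        p_noise = NoiseSpec(
            gyro_bias=tuple(rng.uniform(-2.0, 2.0, 3)),
            gyro_noise_sd=noise.gyro_noise_sd,
            gyro_drift_rw_sd=noise.gyro_drift_rw_sd,
            accel_noise_sd=noise.accel_noise_sd,
            accel_gain=tuple(rng.uniform(0.97, 1.03, 3)),
            accel_bias=tuple(rng.uniform(-0.03, 0.03, 3)),
            linear_accel_sd=noise.linear_accel_sd,
        )
        for class_id in classes:
            trace_seed = int(rng.integers(0, 2**31 - 1))
            spec = ActivitySpec(
                class_id=class_id,
                duration_s=per_class_duration_s,
                participant_style=style,
                seed=trace_seed,
            )
            trace = simulate_activity(spec, p_noise, fs=fs)
            trace.participant_id = pid
            traces.append(trace)
    return traces


def write_dataset(
    traces: Sequence[ImuTrace], out_dir: str | Path, manifest_extra: dict | None = None
) -> Path:
    """Write one CSV per trace plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, trace in enumerate(traces):
        name = f"trace_{i:04d}_p{trace.participant_id}_{trace.label}.csv"
        write_trace_csv(trace, out / name)
        entries.append(
            {
                "file": name,
                "label": trace.label,
                "participant_id": trace.participant_id,
                "fs": trace.fs,
                "n_samples": len(trace),
            }
        )
    manifest = {"traces": entries}
    if manifest_extra:
        manifest.update(manifest_extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
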