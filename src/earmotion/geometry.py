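"""Rotation utilities shared by the simulator and the orientation filters.

Convention: intrinsic Z-Y-X Euler angles (yaw psi, pitch theta, roll phi),
right-handed, in degrees at module boundaries. The body-to-world rotation is
R = Rz(psi) @ Ry(theta) @ Rx(phi). Gravity reads +1 g along body z when the
sensor is level (accelerometers measure specific force).

Quaternions are scalar-first (w, x, y, z) unit quaternions encoding the
body-to-world rotation.
"""

from __future__ import annotations

import numpy as np

DEG = np.pi / 180.0


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q)


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_from_axis_angle(axis_angle_rad: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (rad) -> unit quaternion."""
    v = np.asarray(axis_angle_rad, dtype=float)
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return quat_normalize(np.array([1.0, *(0.5 * v)]))
    axis = v / angle
    return np.array([np.cos(angle / 2), *(np.sin(angle / 2) * axis)])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = quat_normalize(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def euler_zyx_to_matrix(roll_deg: float, pitch_deg: float, yaw_deg: float) -> np.ndarray:
    """Body-to-world DCM from intrinsic Z-Y-X Euler angles (degrees)."""
    r, p, y = roll_deg * DEG, pitch_deg * DEG, yaw_deg * DEG
    cr, sr = np.cos(r), np.sin(r)
    cp, sp = np.cos(p), np.sin(p)
    cy, sy = np.cos(y), np.sin(y)
    return np.array(
        [
            [cy * cp, cy * sp * sr - sy * cr, cy * sp * cr + sy * sr],
            [sy * cp, sy * sp * sr + cy * cr, sy * sp * cr - cy * sr],
            [-sp, cp * sr, cp * cr],
        ]
    )


def euler_zyx_to_quat(roll_deg: float, pitch_deg: float, yaw_deg: float) -> np.ndarray:
    hr, hp, hy = 0.5 * roll_deg * DEG, 0.5 * pitch_deg * DEG, 0.5 * yaw_deg * DEG
    cr, sr = np.cos(hr), np.sin(hr)
    cp, sp = np.cos(hp), np.sin(hp)
    cy, sy = np.cos(hy), np.sin(hy)
    return np.array(
        [
            cy * cp * cr + sy * sp * sr,
            cy * cp * sr - sy * sp * cr,
            cy * sp * cr + sy * cp * sr,
            sy * cp * cr - cy * sp * sr,
        ]
    )


def quat_to_euler_zyx(q: np.ndarray) -> tuple[float, float, float]:
    """Unit quaternion -> (roll, pitch, yaw) in degrees."""
    w, x, y, z = quat_normalize(q)
    roll = np.arctan2(2 * (w * x + y * z), 1 - 2 * (x * x + y * y))
    sp = np.clip(2 * (w * y - z * x), -1.0, 1.0)
    pitch = np.arcsin(sp)
    yaw = np.arctan2(2 * (w * z + x * y), 1 - 2 * (y * y + z * z))
    return roll / DEG, pitch / DEG, yaw / DEG


def gravity_body(roll_deg: float, pitch_deg: float) -> np.ndarray:
    """Gravity direction (unit, in g) seen in the body frame, level = (0,0,1)."""
    r, p = roll_deg * DEG, pitch_deg * DEG
    return np.array([-np.sin(p), np.cos(p) * np.sin(r), np.cos(p) * np.cos(r)])


def euler_rates_to_body_rates(
    roll_deg: float, pitch_deg: float, droll: float, dpitch: float, dyaw: float
) -> np.ndarray:
    """Exact kinematic map from Z-Y-X Euler-angle rates to body rates (deg/s).

    p = droll  - dyaw * sin(pitch)
    q = dpitch * cos(roll) + dyaw * cos(pitch) * sin(roll)
    r = -dpitch * sin(roll) + dyaw * cos(pitch) * cos(roll)
    """
    r, p = roll_deg * DEG, pitch_deg * DEG
    cr, sr = np.cos(r), np.sin(r)
    cp, sp = np.cos(p), np.sin(p)
    wx = droll - dyaw * sp
    wy = dpitch * cr + dyaw * cp * sr
    wz = -dpitch * sr + dyaw * cp * cr
    return np.array([wx, wy, wz])


def wrap_angle_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float
    )
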