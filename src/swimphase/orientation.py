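"""Sensor-frame IMU data → calibrated global-frame signals and Euler angles.

Pipeline: intrinsic + functional calibration (sensor → anatomical frame),
initial orientation from a quasi-static window, gradient-descent
accelerometer-corrected gyroscope integration (Madgwick-style IMU filter,
no magnetometer), quaternion rotation into the pool frame and gravity
removal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np

from . import quaternion as quat
from .types import GRAVITY, CalibrationParams, ImuRecording, OrientationTrace

__all__ = [
    "apply_calibration",
    "estimate_functional_alignment",
    "estimate_initial_orientation",
    "fuse_orientation",
    "rotate_to_global",
    "quaternion_to_euler",
]


def apply_calibration(raw: ImuRecording, cal: CalibrationParams) -> ImuRecording:
    """Correct offset/scale/non-orthogonality and rotate into the anatomical frame.

    Per sample: ``v_anatomical = R @ S @ (v_sensor - bias)`` for each sensor.
    """
    if raw.frame != "sensor":
        raise ValueError(f"expected a sensor-frame recording, got {raw.frame!r}")
    R = cal.R_sensor_to_anatomical
    acc = (raw.acc - cal.acc_bias) @ cal.acc_scale.T @ R.T
    gyr = (raw.gyr - cal.gyr_bias) @ cal.gyr_scale.T @ R.T
    return replace(raw, acc=acc, gyr=gyr, frame="anatomical")


def invert_calibration(rec: ImuRecording, cal: CalibrationParams) -> ImuRecording:
    """Inverse of :func:`apply_calibration` (used by the simulator and tests)."""
    if rec.frame != "anatomical":
        raise ValueError("expected an anatomical-frame recording")
    R = cal.R_sensor_to_anatomical
    acc = rec.acc @ R @ np.linalg.inv(cal.acc_scale).T + cal.acc_bias
    gyr = rec.gyr @ R @ np.linalg.inv(cal.gyr_scale).T + cal.gyr_bias
    return replace(rec, acc=acc, gyr=gyr, frame="sensor")


def estimate_functional_alignment(
    standing: ImuRecording, squats: ImuRecording, *, min_axis_angle_deg: float = 10.0
) -> np.ndarray:
    """Sensor→anatomical rotation from on-land reference movements.

    The longitudinal axis is the mean specific-force (gravity reaction)
    direction while standing upright (cranial positive); the mediolateral
    axis is the dominant gyroscope rotation axis during squats,
    orthogonalized against the longitudinal axis; the anterior-posterior
    axis completes the right-handed triad (x = AP, y = longitudinal,
    z = ML).

    Returns the 3x3 rotation whose rows are the anatomical axes expressed
    in sensor coordinates, i.e. ``v_anatomical = R @ v_sensor``.
    """
    if standing.t[-1] - standing.t[0] < 2.0 - 1e-9:
        raise ValueError("standing window must cover at least 2 s")
    g_vec = standing.acc.mean(axis=0)
    g_norm = np.linalg.norm(g_vec)
    if not (9.3 <= g_norm <= 10.3):
        raise ValueError(
            f"standing window is not static: mean specific force {g_norm:.2f} m/s^2 "
            "outside [9.3, 10.3]"
        )
    longitudinal = g_vec / g_norm

    # dominant rotation axis during squats = principal axis of the gyro cloud
    w = squats.gyr - squats.gyr.mean(axis=0)
    cov = w.T @ w
    eigval, eigvec = np.linalg.eigh(cov)
    axis = eigvec[:, np.argmax(eigval)]
    # deterministic sign: largest-magnitude component positive
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    angle = np.degrees(np.arccos(np.clip(abs(axis @ longitudinal), 0.0, 1.0)))
    if angle < min_axis_angle_deg:
        raise ValueError(
            "squat rotation axis is within "
            f"{min_axis_angle_deg:.0f} deg of the longitudinal axis (degenerate)"
        )
    ml = axis - (axis @ longitudinal) * longitudinal
    ml /= np.linalg.norm(ml)
    ap = np.cross(longitudinal, ml)  # y × z = x, right-handed triad
    R = np.vstack([ap, longitudinal, ml])
    return R


def estimate_initial_orientation(
    static: ImuRecording, *, gyro_rms_threshold: float = 0.2
) -> np.ndarray:
    """Initial anatomical→global quaternion from a quasi-static window.

    Returns the minimal rotation aligning the mean accelerometer direction
    with global vertical (+Z); the minimal rotation carries no twist about
    the vertical, so the initial yaw is zero by construction — the pool's
    swimming direction is the yaw reference.
    """
    if static.frame != "anatomical":
        raise ValueError("expected an anatomical-frame recording")
    if len(static) == 0:
        raise ValueError("empty static window")
    gyro_rms = float(np.sqrt(np.mean(static.gyr**2)))
    if gyro_rms > gyro_rms_threshold:
        warnings.warn(
            f"static window gyro RMS {gyro_rms:.3f} rad/s exceeds "
            f"{gyro_rms_threshold}; proceeding with the mean accelerometer vector",
            RuntimeWarning,
        )
    a = static.acc.mean(axis=0)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(a @ z, -1.0, 1.0))
    axis = np.cross(a, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        # antipodal: 180 deg about any horizontal axis; pick X
        return np.array([0.0, 1.0, 0.0, 0.0])
    return quat.from_axis_angle(axis / s, np.arctan2(s, c))


def fuse_orientation(
    rec: ImuRecording,
    q0: np.ndarray,
    gain: float = 0.1,
    accel_gate: float | None = 0.5,
) -> OrientationTrace:
    """Gradient-descent accelerometer-corrected gyroscope integration.

    IMU variant (no magnetometer): each step integrates the quaternion rate
    from the gyroscope and subtracts ``gain`` times the normalized gradient
    of the gravity-alignment objective
    ``f(q) = R(q)^T e_z - acc/||acc||``.  The accelerometer therefore
    corrects roll/pitch drift while yaw is governed by integration alone.

    Parameters
    ----------
    gain : filter gain β (rad/s), trades gyroscope trust against
        accelerometer trust; default 0.1.
    accel_gate : if not None, the accelerometer correction is applied only
        when the specific-force magnitude is within this tolerance (m/s^2)
        of gravity; samples dominated by motion acceleration (push burst,
        strong strokes) would otherwise pull the gravity estimate away
        from the vertical.
    """
    if rec.frame != "anatomical":
        raise ValueError("expected an anatomical-frame recording")
    if len(rec) == 0:
        raise ValueError("empty recording")
    if not (np.all(np.isfinite(rec.acc)) and np.all(np.isfinite(rec.gyr))):
        raise ValueError("recording contains NaN/Inf samples")
    if gain < 0:
        raise ValueError("gain must be non-negative (0 = gyroscope strapdown)")

    dt = 1.0 / rec.fs
    n = len(rec)
    out = np.empty((n, 4))
    w, x, y, z = (float(v) for v in quat.normalize(np.asarray(q0, dtype=float)))
    acc = rec.acc
    gyr = rec.gyr
    beta = float(gain)
    for i in range(n):
        gx, gy, gz = gyr[i, 0], gyr[i, 1], gyr[i, 2]
        # exact exponential-map gyroscope step: q ← q ⊗ (cos θ/2, sin θ/2 ω̂);
        # first-order Euler integration would drift measurably at stroke-rate
        # angular velocities over a full lap
        th = (gx * gx + gy * gy + gz * gz) ** 0.5 * dt
        if th > 1e-12:
            c = math.cos(0.5 * th)
            s = math.sin(0.5 * th) / (th / dt)
            dw, dx, dy, dz = c, s * gx, s * gy, s * gz
            w, x, y, z = (
                w * dw - x * dx - y * dy - z * dz,
                w * dx + x * dw + y * dz - z * dy,
                w * dy - x * dz + y * dw + z * dx,
                w * dz + x * dy - y * dx + z * dw,
            )

        ax, ay, az = acc[i, 0], acc[i, 1], acc[i, 2]
        an = (ax * ax + ay * ay + az * az) ** 0.5
        if beta > 0 and an > 1e-9 and (accel_gate is None or abs(an - GRAVITY) <= accel_gate):
            ax, ay, az = ax / an, ay / an, az / an
            f1 = 2.0 * (x * z - w * y) - ax
            f2 = 2.0 * (w * x + y * z) - ay
            f3 = 1.0 - 2.0 * (x * x + y * y) - az
            # gradient J^T f of the gravity objective
            sw = -2.0 * y * f1 + 2.0 * x * f2
            sx = 2.0 * z * f1 + 2.0 * w * f2 - 4.0 * x * f3
            sy = -2.0 * w * f1 + 2.0 * z * f2 - 4.0 * y * f3
            sz = 2.0 * x * f1 + 2.0 * y * f2
            sn = (sw * sw + sx * sx + sy * sy + sz * sz) ** 0.5
            if sn > 1e-12:
                k = beta * dt / sn
                w -= k * sw
                x -= k * sx
                y -= k * sy
                z -= k * sz

        norm = (w * w + x * x + y * y + z * z) ** 0.5
        w, x, y, z = w / norm, x / norm, y / norm, z / norm
        out[i] = (w, x, y, z)

    return OrientationTrace(t=rec.t.copy(), q=out, euler=quat.to_euler(out))


def rotate_to_global(
    rec: ImuRecording, trace: OrientationTrace, *, subtract_gravity: bool = True
) -> ImuRecording:
    """Express a calibrated recording in the pool frame.

    Acc_G = q ⊗ [0, Acc_A] ⊗ q* per sample, likewise for the gyroscope;
    gravity (9.81 m/s^2) is then removed from the vertical channel so all
    three acceleration channels are motion accelerations.
    """
    if rec.frame != "anatomical":
        raise ValueError("expected an anatomical-frame recording")
    if len(rec) != len(trace):
        raise ValueError("recording and orientation trace lengths differ")
    acc = quat.rotate_vector(trace.q, rec.acc)
    gyr = quat.rotate_vector(trace.q, rec.gyr)
    if subtract_gravity:
        acc = acc - np.array([0.0, 0.0, GRAVITY])
    return replace(rec, acc=acc, gyr=gyr, frame="global")


def quaternion_to_euler(q: np.ndarray) -> np.ndarray:
    """(ψ yaw, θ roll, φ pitch) in radians; see :func:`swimphase.quaternion.to_euler`."""
    return quat.to_euler(quat.normalize(q))
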