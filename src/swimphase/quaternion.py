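"""Unit-quaternion algebra for orientation handling.

Quaternions are stored scalar-first, ``q = (q1, q2, q3, q4)`` with ``q1``
the scalar part, Hamilton multiplication convention.  A quaternion ``q``
maps a vector ``v`` expressed in the body (anatomical) frame to the global
frame through the sandwich product ``q ⊗ [0, v] ⊗ q*`` (for unit
quaternions the conjugate equals the inverse, so the "transposed"
quaternion in the sandwich is implemented as the conjugate).

All functions are vectorized over a leading axis: quaternion arguments may
be shape ``(4,)`` or ``(n, 4)``, vectors ``(3,)`` or ``(n, 3)``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "normalize",
    "multiply",
    "conjugate",
    "rotate_vector",
    "to_rotation_matrix",
    "from_axis_angle",
    "from_rotvec",
    "to_rotvec",
    "to_euler",
    "from_euler",
    "geodesic_angle",
]


def normalize(q: np.ndarray) -> np.ndarray:
    """Return ``q / ||q||``; raises on (near-)zero norm."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero-norm quaternion")
    return q / n


def multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product ``p ⊗ q``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p1, p2, p3, p4 = np.moveaxis(p, -1, 0)
    q1, q2, q3, q4 = np.moveaxis(q, -1, 0)
    return np.stack(
        [
            p1 * q1 - p2 * q2 - p3 * q3 - p4 * q4,
            p1 * q2 + p2 * q1 + p3 * q4 - p4 * q3,
            p1 * q3 - p2 * q4 + p3 * q1 + p4 * q2,
            p1 * q4 + p2 * q3 - p3 * q2 + p4 * q1,
        ],
        axis=-1,
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate body-frame vector(s) into the global frame.

    Implements the sandwich product ``q ⊗ [0, v] ⊗ q*`` literally rather
    than through a rotation matrix, so it can be cross-checked against the
    matrix route in tests.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    vq = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    out = multiply(multiply(q, vq), conjugate(q))
    return out[..., 1:]


def to_rotation_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix (body → global) of a unit quaternion."""
    w, x, y, z = np.moveaxis(np.asarray(q, dtype=float), -1, 0)
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=-2,
    )


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * float(angle)
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def from_rotvec(r: np.ndarray) -> np.ndarray:
    """Quaternion of a rotation vector (axis * angle, radians)."""
    r = np.asarray(r, dtype=float)
    angle = np.linalg.norm(r, axis=-1, keepdims=True)
    half = 0.5 * angle
    # sin(x)/x with the series limit at 0
    small = angle < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(small, 0.5, np.sin(half) / np.where(small, 1.0, angle))
    return np.concatenate([np.cos(half), k * r], axis=-1)


def to_rotvec(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    # force the short rotation (positive scalar part)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    q = q * sign
    vec = q[..., 1:]
    sin_half = np.linalg.norm(vec, axis=-1, keepdims=True)
    angle = 2.0 * np.arctan2(sin_half[..., 0], q[..., 0])[..., None]
    small = sin_half < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(small, 2.0, angle / np.where(small, 1.0, sin_half))
    return k * vec


def to_euler(q: np.ndarray, *, warn_on_clip: bool = True) -> np.ndarray:
    """Euler angles ``(ψ, θ, φ)`` = (yaw, roll, pitch) in radians.

    The three closed-form expressions below are the package's angle
    convention.  ``θ`` uses an arcsine whose argument is clipped to
    [-1, 1] at the numerical gimbal-lock boundary (a warning is emitted
    when clipping actually changes the value).

    ψ = atan2(2 q2 q3 − 2 q1 q4, 2 q1² + 2 q2² − 1)
    θ = −asin(2 q2 q4 + 2 q1 q3)
    φ = atan2(2 q3 q4 − 2 q1 q2, 2 q1² + 2 q4² − 1)
    """
    q = np.asarray(q, dtype=float)
    q1, q2, q3, q4 = np.moveaxis(q, -1, 0)
    psi = np.arctan2(2 * q2 * q3 - 2 * q1 * q4, 2 * q1 * q1 + 2 * q2 * q2 - 1)
    arg = 2 * q2 * q4 + 2 * q1 * q3
    if np.any(np.abs(arg) > 1.0):
        if warn_on_clip and np.any(np.abs(arg) > 1.0 + 1e-9):
            warnings.warn("gimbal-lock arcsine argument clipped to ±1", RuntimeWarning)
        arg = np.clip(arg, -1.0, 1.0)
    theta = -np.arcsin(arg)
    phi = np.arctan2(2 * q3 * q4 - 2 * q1 * q2, 2 * q1 * q1 + 2 * q4 * q4 - 1)
    return np.stack([psi, theta, phi], axis=-1)


def _axis_quat(axis_index: int, angle: np.ndarray) -> np.ndarray:
    angle = np.asarray(angle, dtype=float)
    half = 0.5 * angle
    q = np.zeros(angle.shape + (4,))
    q[..., 0] = np.cos(half)
    q[..., axis_index + 1] = np.sin(half)
    return q


def from_euler(psi: float, theta: float, phi: float) -> np.ndarray:
    """Exact inverse of :func:`to_euler`.

    The printed angle formulas coincide with a Z-Y-X factorization of the
    *conjugate* quaternion, so the inverse composes axis rotations in that
    order and conjugates back; round-trip identity away from gimbal lock
    is enforced by tests.
    """
    qc = multiply(multiply(_axis_quat(2, psi), _axis_quat(1, theta)), _axis_quat(0, phi))
    return conjugate(qc)


def geodesic_angle(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Angle (radians) of the relative rotation between two unit quaternions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    dot = np.abs(np.sum(p * q, axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))
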