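"""Core data containers shared across the pipeline.

Frames
------
sensor      raw device axes as mounted on the sacrum
anatomical  body axes: x anterior-posterior, y longitudinal (cranial +),
            z mediolateral
global      pool axes: X lateral, Y swimming direction, Z vertical up

The canonical resting posture for this pipeline is the streamlined glide
(prone, head toward the far wall): there the anatomical axes coincide with
the pool axes and the orientation quaternion is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

GRAVITY = 9.81  # m/s^2

FRAMES = ("sensor", "anatomical", "global")
PHASES = ("Push", "Glid", "StPr", "Swim")
TECHNIQUES = ("front_crawl", "breaststroke", "butterfly", "backstroke")

#: anatomical gyroscope channel carrying the stroke cycle, per technique:
#: longitudinal (y) for alternating techniques, mediolateral (z) for the
#: simultaneous ones.
CYCLE_CHANNEL = {
    "front_crawl": 1,
    "backstroke": 1,
    "breaststroke": 2,
    "butterfly": 2,
}


@dataclass
class ImuRecording:
    """Uniformly sampled 6-axis inertial time series.

    t    (n,) seconds, strictly increasing at rate ``fs``
    acc  (n, 3) accelerometer specific force, m/s^2
    gyr  (n, 3) angular velocity, rad/s
    """

    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    fs: float
    frame: str = "sensor"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.frame not in FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = len(self.t)
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise ValueError("t, acc and gyr lengths must match (acc/gyr shape (n, 3))")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) > 1e-6):
                raise ValueError("t must increase uniformly at 1/fs")

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, t_on: float, t_off: float) -> "ImuRecording":
        """Samples with ``t_on <= t < t_off`` (half-open)."""
        m = (self.t >= t_on) & (self.t < t_off)
        return replace(self, t=self.t[m], acc=self.acc[m], gyr=self.gyr[m])


@dataclass
class CalibrationParams:
    """Intrinsic + functional calibration applied to a sensor-frame recording.

    Each sensor vector v is mapped as ``R @ S @ (v - bias)`` where S fixes
    scale/non-orthogonality and R rotates sensor axes onto anatomical axes.
    """

    acc_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyr_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    acc_scale: np.ndarray = field(default_factory=lambda: np.eye(3))
    gyr_scale: np.ndarray = field(default_factory=lambda: np.eye(3))
    R_sensor_to_anatomical: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.acc_bias = np.asarray(self.acc_bias, dtype=float)
        self.gyr_bias = np.asarray(self.gyr_bias, dtype=float)
        self.acc_scale = np.asarray(self.acc_scale, dtype=float)
        self.gyr_scale = np.asarray(self.gyr_scale, dtype=float)
        self.R_sensor_to_anatomical = np.asarray(self.R_sensor_to_anatomical, dtype=float)
        R = self.R_sensor_to_anatomical
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise ValueError("R_sensor_to_anatomical must be a proper rotation")
        for name, S in (("acc_scale", self.acc_scale), ("gyr_scale", self.gyr_scale)):
            if abs(np.linalg.det(S)) < 1e-12:
                raise ValueError(f"{name} matrix is not invertible")


@dataclass
class OrientationTrace:
    """Per-sample unit quaternion (anatomical → global) with Euler angles.

    ``euler`` columns are (ψ yaw, θ roll, φ pitch) in radians.
    """

    t: np.ndarray
    q: np.ndarray
    euler: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.euler = np.asarray(self.euler, dtype=float)
        if self.q.shape != (len(self.t), 4) or self.euler.shape != (len(self.t), 3):
            raise ValueError("q must be (n, 4) and euler (n, 3)")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class PhaseAnnotation:
    """Lap bounds plus ordered Push/Glid/StPr/Swim sub-intervals.

    Intervals are half-open ``[on, off)`` seconds; consecutive phases share
    their boundary so the four phases partition the lap exactly.
    """

    lap: tuple[float, float]
    phases: dict[str, tuple[float, float]]
    source: str = "imu"

    def __post_init__(self) -> None:
        if self.source not in ("camera", "imu", "synthetic"):
            raise ValueError(f"unknown annotation source {self.source!r}")
        self.validate()

    def validate(self) -> None:
        if set(self.phases) != set(PHASES):
            raise ValueError(f"phases must be exactly {PHASES}")
        t0, t1 = self.lap
        prev_off = t0
        for name in PHASES:
            on, off = self.phases[name]
            if not np.isclose(on, prev_off, atol=1e-9):
                raise ValueError(f"phase {name} is not contiguous with its predecessor")
            if off <= on:
                raise ValueError(f"phase {name} has non-positive duration")
            prev_off = off
        if not np.isclose(prev_off, t1, atol=1e-9):
            raise ValueError("Swim must end at the lap end")

    def duration(self, phase: str) -> float:
        on, off = self.phases[phase]
        return off - on


@dataclass
class CycleSet:
    """Stroke-cycle boundaries (seconds) inside the Swim interval."""

    boundaries: np.ndarray
    technique: str

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        if len(self.boundaries) < 2:
            raise ValueError("need at least 2 boundaries (1 cycle)")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("cycle boundaries must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    def intervals(self) -> list[tuple[float, float]]:
        b = self.boundaries
        return [(b[i], b[i + 1]) for i in range(len(b) - 1)]


@dataclass
class ReferenceTrace:
    """Velocity/displacement trace of a tethered-speedometer emulation."""

    t: np.ndarray
    v: np.ndarray
    d: np.ndarray
    fr: float = 100.0
    corrected: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if not (len(self.t) == len(self.v) == len(self.d)):
            raise ValueError("t, v, d lengths must match")


GOAL_METRIC_NAMES = (
    "push_vmax",
    "glid_vend",
    "stpr_vavg",
    "swim_vavg_cycle",
    "swim_vavg_phase",
    "T5m",
    "T15m",
    "lap_vavg",
)


@dataclass
class GoalMetricSet:
    """The eight per-lap reference performance scalars.

    ``swim_vavg_cycle`` is a list (one mean velocity per stroke cycle);
    the other seven are scalars.
    """

    push_vmax: float
    glid_vend: float
    stpr_vavg: float
    swim_vavg_cycle: np.ndarray
    swim_vavg_phase: float
    T5m: float
    T15m: float
    lap_vavg: float

    def __post_init__(self) -> None:
        self.swim_vavg_cycle = np.asarray(self.swim_vavg_cycle, dtype=float)
        if self.push_vmax < self.glid_vend - 1e-9:
            raise ValueError("push_vmax must be >= glid_vend")
        if not (self.T15m > self.T5m > 0):
            raise ValueError("need T15m > T5m > 0")
        if self.lap_vavg <= 0:
            raise ValueError("lap_vavg must be positive")

    def scalars(self) -> dict[str, float]:
        return {
            "push_vmax": self.push_vmax,
            "glid_vend": self.glid_vend,
            "stpr_vavg": self.stpr_vavg,
            "swim_vavg_phase": self.swim_vavg_phase,
            "T5m": self.T5m,
            "T15m": self.T15m,
            "lap_vavg": self.lap_vavg,
        }


CATEGORIES = ("propulsion", "posture", "efficiency", "duration_rate")


@dataclass
class SelectionResult:
    """LASSO variable-selection outcome for one goal metric."""

    weights: dict[str, float]          # relative weight in %, nonzero support
    selected: list[str]                # weight >= threshold (default 5%)
    category_contrib: dict[str, float]         # over the selected set, raw
    category_contrib_renorm: dict[str, float]  # renormalized to 100%
    alpha: float
    threshold_pct: float = 5.0


@dataclass
class RegressionReport:
    """Cross-validated goodness of fit for one goal metric."""

    target: str
    r2: float
    rmse: float
    rel_rmse: float  # percent of mean(y)
    n_obs: int
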