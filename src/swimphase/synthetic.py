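"""Ground-truthed synthetic swimming laps and planted regression datasets.

The lap generator builds a piecewise forward-velocity model of a 25 m lap
started with an in-water wall push-off:

* ``Push``  — half-cosine rise from rest to the push peak velocity;
* ``Glid``  — exponential drag decay ``v(t) = v_peak * exp(-k t)``;
* ``StPr``  — smooth recovery toward the steady swim velocity with a
  kick-frequency modulation;
* ``Swim``  — cyclic steady state with intra-cycle velocity modulation,
  ending when the displacement reaches the pool length.

From the velocity profile it derives global-frame accelerations, composes
a technique-specific orientation trajectory (stroke-cycle body roll for
front crawl/backstroke, mediolateral stroke rotation for breaststroke/
butterfly, kick oscillations during StPr, a slow pitch posture wobble),
maps everything into the sensor frame through the inverse orientation plus
gravity, adds white sensor noise, and emits the matched ground-truth
reference trace, phase annotation, cycle boundaries and goal metrics.

It reproduces the statistical and kinematic structure the pipeline
assumes, not swimming hydrodynamics.  In particular the orientation
trajectory is parameterized as a rotation-vector deviation from the
streamlined glide posture (where anatomical and pool axes coincide), which
keeps the Euler angles of the printed convention far from gimbal lock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import quaternion as quat
from .orientation import invert_calibration
from .types import (
    GRAVITY,
    TECHNIQUES,
    CalibrationParams,
    CycleSet,
    GoalMetricSet,
    ImuRecording,
    OrientationTrace,
    PhaseAnnotation,
    ReferenceTrace,
)

__all__ = [
    "LapScenario",
    "SyntheticLap",
    "simulate_lap",
    "simulate_cohort",
    "simulate_feature_goal_dataset",
    "simulate_tumble",
]


@dataclass
class LapScenario:
    """Parameters of one simulated lap.

    Defaults describe a competitive front-crawl lap at full pace: push to
    ~2.5 m/s, drag decay 0.4 1/s, steady swim at 1.6 m/s with a 0.75 Hz
    stroke rate and 2.2 Hz preparatory kicks.  Sensor noise defaults are
    additive white Gaussian, 0.05 m/s^2 (accelerometer) and 0.01 rad/s
    (gyroscope).
    """

    technique: str = "front_crawl"
    pool_length: float = 25.0
    fs: float = 500.0
    fr: float = 100.0
    # phase durations, s
    push_duration: float = 0.8
    glide_duration: float = 1.5
    stpr_duration: float = 2.0
    # forward kinematics
    push_peak_velocity: float = 2.5     # m/s, v at the end of Push
    glide_decay: float = 0.4            # 1/s
    swim_velocity: float = 1.6          # m/s, Swim-phase mean
    stroke_rate: float = 0.75           # Hz
    kick_rate: float = 2.2              # Hz
    intracycle_modulation: float = 0.08  # fraction of swim_velocity
    kick_velocity_modulation: float = 0.05
    push_ripple: float = 0.08           # fraction of v_peak; zero-mean velocity
                                        # ripple mid-push (leg-extension dynamics)
    push_ripple_freq: float = 5.0       # Hz
    # orientation trajectory, rad
    roll_amplitude: float = 0.5         # stroke roll about y (front crawl/backstroke)
    sim_cycle_amplitude: float = 0.6    # stroke rotation about z (breaststroke/butterfly)
    kick_rot_amplitude: float = 0.04    # StPr kick oscillation about z
    pitch_mean: float = 0.08            # mean tilt about x
    pitch_amplitude: float = 0.10       # slow posture oscillation about x
    pitch_freq: float = 0.3             # Hz
    # off-axis motion acceleration, m/s^2
    lateral_acc_amplitude: float = 0.5
    vertical_acc_amplitude: float = 0.8
    # recording pads, s
    pre_static: float = 6.0
    post_static: float = 3.0
    # sensor noise
    acc_noise: float = 0.05             # m/s^2
    gyr_noise: float = 0.01             # rad/s
    pace: float = 1.0                   # fraction of full effort, bookkeeping only
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        for name in ("push_duration", "glide_duration", "stpr_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.swim_velocity < self.push_peak_velocity):
            raise ValueError("need 0 < swim_velocity < push_peak_velocity")
        if self.glide_decay <= 0 or self.stroke_rate <= 0 or self.kick_rate <= 0:
            raise ValueError("rates and decay must be positive")
        vge = self.push_peak_velocity * np.exp(-self.glide_decay * self.glide_duration)
        if vge <= 0.1:
            raise ValueError("glide end velocity collapses; shorten the glide or the decay")


@dataclass
class SyntheticLap:
    """One generated lap with every ground-truth object the pipeline can meet."""

    scenario: LapScenario
    imu_sensor: ImuRecording
    imu_anatomical: ImuRecording
    reference: ReferenceTrace
    annotation: PhaseAnnotation
    cycles_true: CycleSet
    goals_true: GoalMetricSet
    orientation_true: OrientationTrace
    calibration: CalibrationParams
    #: column names the generator couples most strongly to performance
    features_influential: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _window(t: np.ndarray, on: float, off: float, ramp: float) -> np.ndarray:
    """Smooth 0→1→0 window over [on, off] with the given ramp time."""
    up = _smoothstep((t - on) / ramp)
    down = _smoothstep((off - t) / ramp)
    return up * down


def _velocity_profile(sc: LapScenario, tau: np.ndarray) -> np.ndarray:
    """Forward velocity on lap-relative time tau >= 0 (before the final stop)."""
    vp = sc.push_peak_velocity
    k = sc.glide_decay
    tp, tg, ts = sc.push_duration, sc.glide_duration, sc.stpr_duration
    vge = vp * np.exp(-k * tg)
    vs = sc.swim_velocity

    v = np.zeros_like(tau)
    m_push = tau < tp
    # leg-extension dynamics: zero-mean velocity ripple windowed mid-push, so
    # the burst carries genuine braking sub-intervals while v(0) = 0 and
    # v(tp) = v_peak are preserved
    ripple = (
        sc.push_ripple
        * vp
        * np.sin(2 * np.pi * sc.push_ripple_freq * tau[m_push])
        * _window(tau[m_push], 0.25 * tp, 0.9 * tp, 0.15 * tp)
    )
    v[m_push] = vp * 0.5 * (1 - np.cos(np.pi * tau[m_push] / tp)) + ripple
    m_glid = (tau >= tp) & (tau < tp + tg)
    v[m_glid] = vp * np.exp(-k * (tau[m_glid] - tp))
    m_stpr = (tau >= tp + tg) & (tau < tp + tg + ts)
    u = tau[m_stpr] - (tp + tg)
    base = vge + (vs - vge) * 0.5 * (1 - np.cos(np.pi * u / ts))
    kick = (
        sc.kick_velocity_modulation
        * vs
        * np.sin(2 * np.pi * sc.kick_rate * u)
        * _window(u, 0.0, ts, 0.25)
    )
    v[m_stpr] = base + kick
    m_swim = tau >= tp + tg + ts
    w = tau[m_swim] - (tp + tg + ts)
    ramp = _smoothstep(w / 0.4)
    v[m_swim] = vs * (1 + sc.intracycle_modulation * np.sin(2 * np.pi * sc.stroke_rate * w) * ramp)
    return v


def _first_crossing(t: np.ndarray, x: np.ndarray, level: float) -> float:
    """Linearly interpolated first up-crossing time of ``x`` through ``level``."""
    above = x >= level
    if not above.any():
        raise ValueError(f"signal never reaches {level}")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (level - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def simulate_lap(sc: LapScenario) -> SyntheticLap:
    """Generate one fully ground-truthed lap; bit-reproducible for a given seed."""
    rng = np.random.default_rng(sc.seed)
    fs = sc.fs
    dt = 1.0 / fs
    tp, tg, ts = sc.push_duration, sc.glide_duration, sc.stpr_duration
    t_wall = sc.pre_static
    swim_on_rel = tp + tg + ts

    # --- forward velocity on a lap-relative grid, long enough to cover the pool
    d_known = (
        sc.push_peak_velocity * tp / 2
        + sc.push_peak_velocity * (1 - np.exp(-sc.glide_decay * tg)) / sc.glide_decay
    )
    t_swim_max = (sc.pool_length - d_known) / (0.9 * sc.swim_velocity) + 5.0
    n_lap = int(np.ceil((swim_on_rel + t_swim_max) * fs))
    tau = np.arange(n_lap) * dt
    v_lap = _velocity_profile(sc, tau)
    d_lap = cumulative_trapezoid(v_lap, tau, initial=0.0)
    if d_lap[-1] < sc.pool_length:
        raise ValueError("scenario never reaches the pool length")
    t_end_rel = _first_crossing(tau, d_lap, sc.pool_length)
    if t_end_rel <= swim_on_rel + 1.0:
        raise ValueError("Swim phase shorter than 1 s; scenario rejected")

    # --- full recording time base with static pads; stop ramp after the wall touch
    stop_T = 1.0
    total_T = t_wall + t_end_rel + sc.post_static + stop_T
    n = int(np.ceil(total_T * fs))
    t = np.arange(n) * dt
    tau_full = t - t_wall
    v = np.zeros(n)
    in_lap = (tau_full >= 0) & (tau_full < t_end_rel)
    v[in_lap] = _velocity_profile(sc, tau_full[in_lap])
    v_touch = float(_velocity_profile(sc, np.array([t_end_rel]))[0])
    m_stop = (tau_full >= t_end_rel) & (tau_full < t_end_rel + stop_T)
    v[m_stop] = v_touch * 0.5 * (1 + np.cos(np.pi * (tau_full[m_stop] - t_end_rel) / stop_T))

    acc_y = np.gradient(v, dt)
    # off-axis motion accelerations during StPr (kick frequency) and Swim (stroke frequency)
    u = tau_full - (tp + tg)
    w = tau_full - swim_on_rel
    stpr_win = _window(tau_full, tp + tg, swim_on_rel, 0.25)
    swim_win = _window(tau_full, swim_on_rel, t_end_rel, 0.4)
    acc_x = 0.4 * sc.lateral_acc_amplitude * np.sin(2 * np.pi * sc.kick_rate * u + 0.7) * stpr_win
    acc_x += sc.lateral_acc_amplitude * np.sin(2 * np.pi * sc.stroke_rate * w + 0.9) * swim_win
    acc_z = 0.5 * sc.vertical_acc_amplitude * np.sin(2 * np.pi * sc.kick_rate * u + 1.9) * stpr_win
    acc_z += sc.vertical_acc_amplitude * np.sin(2 * np.pi * 2 * sc.stroke_rate * w + 2.3) * swim_win
    acc_global = np.stack([acc_x, acc_y, acc_z], axis=1)

    # --- orientation trajectory as a rotation vector (deviation from glide posture)
    f_s, f_k = sc.stroke_rate, sc.kick_rate
    rx = sc.pitch_mean + sc.pitch_amplitude * np.sin(
        2 * np.pi * sc.pitch_freq * tau_full + 0.5
    ) * _window(tau_full, 0.0, t_end_rel, 0.5)
    ry = np.zeros(n)
    rz = sc.kick_rot_amplitude * np.sin(2 * np.pi * f_k * u) * stpr_win
    cycle_phase = 2 * np.pi * f_s * w
    if sc.technique in ("front_crawl", "backstroke"):
        ry = -sc.roll_amplitude * np.cos(cycle_phase) * swim_win
        cycle_gyro_amp = sc.roll_amplitude * 2 * np.pi * f_s
    else:
        rz = rz - sc.sim_cycle_amplitude * np.cos(cycle_phase) * swim_win
        cycle_gyro_amp = sc.sim_cycle_amplitude * 2 * np.pi * f_s
    q_true = quat.from_rotvec(np.stack([rx, ry, rz], axis=1))

    # body rates consistent with the quaternion trajectory
    dq = quat.multiply(quat.conjugate(q_true[:-1]), q_true[1:])
    gyr = quat.to_rotvec(dq) * fs
    gyr = np.vstack([gyr, gyr[-1]])

    # anatomical-frame specific force: R(q)^T (a_motion + g e_z)
    Rm = quat.to_rotation_matrix(q_true)
    f_global = acc_global + np.array([0.0, 0.0, GRAVITY])
    acc_anat = np.einsum("nji,nj->ni", Rm, f_global)

    acc_noisy = acc_anat + rng.normal(0.0, sc.acc_noise, acc_anat.shape)
    gyr_noisy = gyr + rng.normal(0.0, sc.gyr_noise, gyr.shape)
    imu_anat = ImuRecording(t=t, acc=acc_noisy, gyr=gyr_noisy, fs=fs, frame="anatomical")
    imu_sensor = invert_calibration(imu_anat, sc.calibration)

    # --- ground-truth annotation, cycles, reference trace, goal metrics
    annotation = PhaseAnnotation(
        lap=(t_wall, t_wall + t_end_rel),
        phases={
            "Push": (t_wall, t_wall + tp),
            "Glid": (t_wall + tp, t_wall + tp + tg),
            "StPr": (t_wall + tp + tg, t_wall + swim_on_rel),
            "Swim": (t_wall + swim_on_rel, t_wall + t_end_rel),
        },
        source="synthetic",
    )
    # generator-exact cycle boundaries: positive peaks of the noise-free
    # cycle-channel angular velocity inside the Swim interval
    from scipy.signal import find_peaks

    cyc_ch = 1 if sc.technique in ("front_crawl", "backstroke") else 2
    m_swim_t = (t >= t_wall + swim_on_rel) & (t < t_wall + t_end_rel)
    x_cyc = gyr[m_swim_t, cyc_ch]
    pk, _ = find_peaks(x_cyc, height=0.3 * cycle_gyro_amp)
    peaks = t[m_swim_t][pk]
    if len(peaks) < 2:
        raise ValueError("Swim phase too short for stroke cycles")
    cycles_true = CycleSet(boundaries=peaks, technique=sc.technique)

    n_ref = int(np.floor((t_end_rel + 1.0) * sc.fr)) + 1
    t_ref = np.arange(n_ref) / sc.fr
    v_ref = np.interp(t_ref, tau_full, v)
    d_ref = cumulative_trapezoid(v_ref, t_ref, initial=0.0)
    reference = ReferenceTrace(t=t_ref, v=v_ref, d=d_ref, fr=sc.fr, corrected=True)

    vge = sc.push_peak_velocity * np.exp(-sc.glide_decay * tg)
    stpr_mask = (tau >= tp + tg) & (tau <= swim_on_rel)
    stpr_vavg = float(np.trapezoid(v_lap[stpr_mask], tau[stpr_mask]) / ts)
    cyc_rel = peaks - t_wall
    cyc_avgs = []
    for a, b in zip(cyc_rel[:-1], cyc_rel[1:]):
        m = (tau >= a) & (tau <= b)
        cyc_avgs.append(float(np.trapezoid(v_lap[m], tau[m]) / (b - a)))
    swim_mask = (tau >= swim_on_rel) & (tau <= t_end_rel)
    swim_vavg = float(
        np.trapezoid(v_lap[swim_mask], tau[swim_mask]) / (t_end_rel - swim_on_rel)
    )
    goals_true = GoalMetricSet(
        push_vmax=float(np.max(v_lap[tau < tp])),
        glid_vend=float(vge),
        stpr_vavg=stpr_vavg,
        swim_vavg_cycle=np.array(cyc_avgs),
        swim_vavg_phase=swim_vavg,
        T5m=_first_crossing(tau, d_lap, 5.0),
        T15m=_first_crossing(tau, d_lap, 15.0),
        lap_vavg=sc.pool_length / t_end_rel,
    )
    orientation_true = OrientationTrace(t=t, q=q_true, euler=quat.to_euler(q_true))

    return SyntheticLap(
        scenario=sc,
        imu_sensor=imu_sensor,
        imu_anatomical=imu_anat,
        reference=reference,
        annotation=annotation,
        cycles_true=cycles_true,
        goals_true=goals_true,
        orientation_true=orientation_true,
        calibration=sc.calibration,
        features_influential=[
            "Swim.StrokeRate",
            "Swim.StrokeCount",
            "Push.Max(AccY)",
            "Glid.Duration",
            "Swim.MeanCycleDuration",
        ],
        meta={"seed": sc.seed, "pace": sc.pace, "cycle_gyro_amp": cycle_gyro_amp},
    )


# velocity multipliers per technique, relative to front crawl
_TECH_SPEED = {"front_crawl": 1.0, "breaststroke": 0.78, "butterfly": 0.92, "backstroke": 0.88}
_TECH_STROKE_RATE = {"front_crawl": 0.75, "breaststroke": 0.55, "butterfly": 0.65, "backstroke": 0.70}

PACES = (0.7, 0.8, 0.9, 1.0)


def simulate_cohort(
    n_swimmers: int = 19,
    techniques: Sequence[str] = ("front_crawl",),
    paces: Sequence[float] = PACES,
    ability_spread: float = 1.0,
    noise: Optional[dict] = None,
    seed: int = 0,
) -> tuple[list[SyntheticLap], np.ndarray]:
    """Simulate a cohort of swimmers, one lap per technique and pace.

    A latent per-swimmer ability (standard normal, scaled by
    ``ability_spread``) shifts push peak velocity, steady swim velocity,
    glide drag decay, stroke rate and posture quality coherently, so that
    the kinematic micro-variables carry real information about the goal
    metrics.  Pace scales the velocity targets (push less than swim, as
    push-off is less pace-sensitive).  Small per-trial Gaussian jitter
    emulates trial-to-trial variability.

    Returns the laps and a structured latent table (one row per lap).
    """
    if n_swimmers < 2:
        raise ValueError("need at least 2 swimmers")
    rng = np.random.default_rng(seed)
    noise = noise or {}
    laps: list[SyntheticLap] = []
    latent_rows = []
    for s in range(n_swimmers):
        a = float(rng.normal(0.0, ability_spread))
        vp_base = 2.45 + 0.18 * a
        k_base = max(0.25, 0.40 - 0.04 * a)
        pitch_mean = max(0.02, 0.08 - 0.02 * a)
        pitch_amp = max(0.03, 0.10 - 0.015 * a)
        for tech in techniques:
            vs_base = (1.60 + 0.13 * a) * _TECH_SPEED[tech]
            f_base = _TECH_STROKE_RATE[tech]
            for p in paces:
                vs = vs_base * p * (1 + rng.normal(0.0, 0.02))
                vp = max(vs + 0.35, vp_base * p**0.6 * (1 + rng.normal(0.0, 0.02)))
                f_s = f_base * (vs / (1.60 * _TECH_SPEED[tech])) ** 0.7 * (
                    1 + rng.normal(0.0, 0.02)
                )
                sc = LapScenario(
                    technique=tech,
                    push_peak_velocity=vp,
                    glide_decay=k_base * (1 + rng.normal(0.0, 0.03)),
                    swim_velocity=vs,
                    stroke_rate=f_s,
                    kick_rate=2.2 + 0.1 * a + rng.normal(0.0, 0.05),
                    push_duration=0.8 + rng.normal(0.0, 0.04),
                    glide_duration=max(0.8, 1.5 + rng.normal(0.0, 0.12) - 0.3 * (p - 0.85)),
                    stpr_duration=max(1.2, 2.0 + rng.normal(0.0, 0.15)),
                    pitch_mean=pitch_mean,
                    pitch_amplitude=pitch_amp,
                    pace=p,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    **noise,
                )
                laps.append(simulate_lap(sc))
                latent_rows.append((s, tech, p, a, vp, vs, f_s))
    latent = np.array(
        latent_rows,
        dtype=[
            ("swimmer", int),
            ("technique", "U16"),
            ("pace", float),
            ("ability", float),
            ("push_peak_velocity", float),
            ("swim_velocity", float),
            ("stroke_rate", float),
        ],
    )
    return laps, latent


def simulate_feature_goal_dataset(
    n: int,
    p: int,
    support: int,
    coefs: Optional[np.ndarray] = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    collinear_block: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted sparse linear dataset for the selection/regression engine.

    X ~ N(0, 1) i.i.d. (optionally the last column is made a near-exact sum
    of the first two, to exercise the VIF filter); y = X beta + eps with
    beta supported on the first ``support`` columns.

    Returns ``(X, y, true_support_indices)``.
    """
    if not (0 < support <= p):
        raise ValueError("need 0 < support <= p")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if collinear_block:
        X[:, -1] = X[:, 0] + X[:, 1] + rng.normal(0.0, 1e-3, size=n)
    beta = np.zeros(p)
    if coefs is None:
        beta[:support] = 1.0
    else:
        beta[:support] = np.asarray(coefs, dtype=float)
    y = X @ beta + rng.normal(0.0, noise_sd, size=n)
    return X, y, np.arange(support)


def simulate_tumble(
    T: float = 10.0,
    fs: float = 500.0,
    amplitudes: tuple[float, float, float] = (0.3, 0.25, 0.2),
    freqs: tuple[float, float, float] = (0.2, 0.15, 0.1),
    acc_noise: float = 0.0,
    gyr_noise: float = 0.0,
    seed: int = 0,
) -> tuple[ImuRecording, np.ndarray]:
    """Slow multi-axis tumble under gravity only, for fusion validation.

    Returns the anatomical-frame recording and the true quaternion trace.
    """
    rng = np.random.default_rng(seed)
    n = int(T * fs)
    t = np.arange(n) / fs
    r = np.stack(
        [a * np.sin(2 * np.pi * f * t + i) for i, (a, f) in enumerate(zip(amplitudes, freqs))],
        axis=1,
    )
    qs = quat.from_rotvec(r)
    dq = quat.multiply(quat.conjugate(qs[:-1]), qs[1:])
    w = quat.to_rotvec(dq) * fs
    w = np.vstack([w, w[-1]])
    Rm = quat.to_rotation_matrix(qs)
    acc = np.einsum("nji,j->ni", Rm, np.array([0.0, 0.0, GRAVITY]))
    acc = acc + rng.normal(0.0, acc_noise, acc.shape)
    w = w + rng.normal(0.0, gyr_noise, w.shape)
    rec = ImuRecording(t=t, acc=acc, gyr=w, fs=fs, frame="anatomical")
    return rec, qs
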