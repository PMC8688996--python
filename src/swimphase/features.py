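"""Phase-based kinematic micro-variables from global-frame signals.

Per phase the catalogue comprises four categories:

propulsion     Mean/Range/SD of AccX, AccY, AccZ; Max, Int (net time
               integral) and Momentum (propulsive impulse per unit mass,
               the positive-part integral) of AccY
posture        Mean/Range/SD of the roll (θ) and pitch (φ) angles
efficiency     Eff   = ∫max(AccY,0)dt / ∫max(−AccY,0)dt
               Eff_dir = ∫max(AccY,0)dt / ∫‖Acc‖dt
               DPS (Swim only): forward displacement per stroke cycle
duration_rate  Mean/Range/SD of GyrX/GyrY/GyrZ; phase duration; kick rate
               and count (StPr); stroke rate and count, mean cycle
               duration (Swim)

Ratios use time integrals rather than sample counts so they are invariant
to the sampling rate.  Rates are reported in 1/min, durations in s.
Column names follow ``<Phase>.<Func>(<Signal>)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .types import (
    PHASES,
    CycleSet,
    ImuRecording,
    OrientationTrace,
    PhaseAnnotation,
    ReferenceTrace,
)

log = logging.getLogger(__name__)

__all__ = [
    "signal_stats",
    "integral_and_momentum",
    "efficiency_ratios",
    "distance_per_stroke",
    "swim_velocity_profile",
    "extract_micro_variables",
    "catalogue_columns",
    "category_of",
    "UndefinedFeature",
]

ACC_NAMES = ("AccX", "AccY", "AccZ")
GYR_NAMES = ("GyrX", "GyrY", "GyrZ")
ANGLE_NAMES = ("Theta", "Phi")  # roll, pitch


class UndefinedFeature(ValueError):
    """A micro-variable is undefined for this observation (e.g. 0/0 ratio)."""


def _interval_mask(t: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    m = (t >= interval[0]) & (t < interval[1])
    if not m.any():
        raise ValueError(f"empty interval {interval}")
    return m


def signal_stats(t: np.ndarray, x: np.ndarray, interval: tuple[float, float]) -> dict[str, float]:
    """Mean, range (max−min), population SD and max over a half-open interval."""
    xi = x[_interval_mask(t, interval)]
    return {
        "mean": float(np.mean(xi)),
        "range": float(np.max(xi) - np.min(xi)),
        "sd": float(np.std(xi)),
        "max": float(np.max(xi)),
    }


def integral_and_momentum(
    t: np.ndarray, acc_y: np.ndarray, interval: tuple[float, float]
) -> dict[str, float]:
    """Net trapezoidal integral of AccY and its positive-part (propulsive) integral, m/s."""
    m = _interval_mask(t, interval)
    ti, ai = t[m], acc_y[m]
    return {
        "int": float(np.trapezoid(ai, ti)),
        "momentum": float(np.trapezoid(np.maximum(ai, 0.0), ti)),
    }


def efficiency_ratios(
    t: np.ndarray, acc: np.ndarray, interval: tuple[float, float]
) -> dict[str, float]:
    """Eff and Eff_dir over the interval; raises :class:`UndefinedFeature` on 0/0."""
    m = _interval_mask(t, interval)
    ti = t[m]
    ay = acc[m, 1]
    pos = float(np.trapezoid(np.maximum(ay, 0.0), ti))
    neg = float(np.trapezoid(np.maximum(-ay, 0.0), ti))
    norm = float(np.trapezoid(np.linalg.norm(acc[m], axis=1), ti))
    out: dict[str, float] = {}
    if neg <= 0.0:
        raise UndefinedFeature("Eff undefined: no negative forward acceleration in interval")
    out["eff"] = pos / neg
    if norm <= 0.0:
        raise UndefinedFeature("Eff_dir undefined: zero acceleration norm integral")
    out["eff_dir"] = pos / norm
    return out


def swim_velocity_profile(
    rec_global: ImuRecording,
    ann: PhaseAnnotation,
    reference: ReferenceTrace | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward velocity over the Swim phase, (t, v).

    Default (IMU-only) path: integrate the global forward acceleration from
    the lap start (v = 0 at wall contact), then remove a linear drift over
    the Swim phase so the steady-state zero-net-acceleration constraint
    holds.  The drift line pivots around the phase entry, where the
    integral is still anchored by the wall (the leading error mode is a
    slow orientation-leak ramp that grows with time-in-phase).  If a
    reference trace is supplied its velocity is interpolated instead.
    """
    t0, _ = ann.lap
    swim = ann.phases["Swim"]
    if reference is not None:
        tt = rec_global.t[_interval_mask(rec_global.t, swim)]
        return tt, np.interp(tt - t0, reference.t, reference.v)
    m_lap = (rec_global.t >= t0) & (rec_global.t < ann.lap[1])
    tl = rec_global.t[m_lap]
    v = cumulative_trapezoid(rec_global.acc[m_lap, 1], tl, initial=0.0)
    m_swim = (tl >= swim[0]) & (tl < swim[1])
    ts, vs = tl[m_swim], v[m_swim]
    # de-drift: remove the fitted linear slope, pivoting at the phase entry
    slope, _ = np.polyfit(ts - ts.mean(), vs, 1)
    k = max(1, int(0.15 * len(ts)))
    vs = vs - slope * (ts - ts[:k].mean())
    return ts, vs


def distance_per_stroke(
    t: np.ndarray, v: np.ndarray, cycle: tuple[float, float]
) -> float:
    """Displacement ∫v dt over one stroke cycle, m."""
    if cycle[1] - cycle[0] < 0.3:
        warnings.warn(f"cycle shorter than 0.3 s: {cycle}", RuntimeWarning)
    m = _interval_mask(t, cycle)
    return float(np.trapezoid(v[m], t[m]))


def _count_kicks(
    rec_anatomical: ImuRecording, interval: tuple[float, float], prominence: float = 0.5
) -> int:
    """Kick events: prominent peaks of the mediolateral angular velocity."""
    m = _interval_mask(rec_anatomical.t, interval)
    x = rec_anatomical.gyr[m, 2]
    peaks, _ = sps.find_peaks(x, prominence=prominence)
    return int(len(peaks))


def catalogue_columns() -> dict[str, str]:
    """The full lap-level column catalogue: name → category."""
    cols: dict[str, str] = {}
    for ph in PHASES:
        for sig in ACC_NAMES:
            for fn in ("Mean", "Range", "SD"):
                cols[f"{ph}.{fn}({sig})"] = "propulsion"
        for fn in ("Max", "Int", "Momentum"):
            cols[f"{ph}.{fn}(AccY)"] = "propulsion"
        for ang in ANGLE_NAMES:
            for fn in ("Mean", "Range", "SD"):
                cols[f"{ph}.{fn}({ang})"] = "posture"
        cols[f"{ph}.Eff(AccY)"] = "efficiency"
        cols[f"{ph}.Eff_dir(AccY)"] = "efficiency"
        for sig in GYR_NAMES:
            for fn in ("Mean", "Range", "SD"):
                cols[f"{ph}.{fn}({sig})"] = "duration_rate"
        cols[f"{ph}.Duration"] = "duration_rate"
    cols["Swim.DPS"] = "efficiency"
    cols["StPr.KickRate"] = "duration_rate"
    cols["StPr.KickCount"] = "duration_rate"
    cols["Swim.StrokeRate"] = "duration_rate"
    cols["Swim.StrokeCount"] = "duration_rate"
    cols["Swim.MeanCycleDuration"] = "duration_rate"
    return cols


CYCLE_COLUMNS: dict[str, str] = {
    "Cycle.Duration": "duration_rate",
    "Cycle.DPS": "efficiency",
    "Cycle.Mean(Phi)": "posture",
    "Cycle.Range(Phi)": "posture",
    "Cycle.Mean(Theta)": "posture",
    "Cycle.Range(Theta)": "posture",
    "Cycle.Mean(AccY)": "propulsion",
    "Cycle.SD(AccY)": "propulsion",
    "Cycle.Eff(AccY)": "efficiency",
    "Cycle.Eff_dir(AccY)": "efficiency",
}


def category_of(name: str) -> str:
    cat = catalogue_columns().get(name) or CYCLE_COLUMNS.get(name)
    if cat is None:
        raise KeyError(f"unknown micro-variable {name!r}")
    return cat


@dataclass
class FeatureExtraction:
    """Lap-level row plus per-cycle rows for one lap."""

    lap_row: pd.Series
    cycle_rows: pd.DataFrame
    categories: dict[str, str] = field(default_factory=catalogue_columns)


def extract_micro_variables(
    rec_global: ImuRecording,
    rec_anatomical: ImuRecording,
    trace: OrientationTrace,
    ann: PhaseAnnotation,
    cycles: CycleSet,
    technique: str,
    reference: ReferenceTrace | None = None,
    rec_global_velocity: ImuRecording | None = None,
) -> FeatureExtraction:
    """Compute the full micro-variable catalogue for one annotated lap.

    ``rec_global_velocity`` optionally supplies a drift-controlled
    global-frame recording (e.g. gyroscope-strapdown within the lap) used
    only for the velocity integration behind DPS; the fused recording is
    used for everything else.  Raises :class:`UndefinedFeature` if any
    catalogue entry is undefined for this lap (the caller drops the
    observation and logs the reason).
    """
    t = rec_global.t
    acc = rec_global.acc
    gyr = rec_global.gyr
    euler_deg = np.degrees(trace.euler)  # angles reported in degrees
    row: dict[str, float] = {}
    for ph in PHASES:
        iv = ann.phases[ph]
        for j, sig in enumerate(ACC_NAMES):
            st = signal_stats(t, acc[:, j], iv)
            row[f"{ph}.Mean({sig})"] = st["mean"]
            row[f"{ph}.Range({sig})"] = st["range"]
            row[f"{ph}.SD({sig})"] = st["sd"]
        st = signal_stats(t, acc[:, 1], iv)
        row[f"{ph}.Max(AccY)"] = st["max"]
        im = integral_and_momentum(t, acc[:, 1], iv)
        row[f"{ph}.Int(AccY)"] = im["int"]
        row[f"{ph}.Momentum(AccY)"] = im["momentum"]
        for ang, col in (("Theta", 1), ("Phi", 2)):
            st = signal_stats(trace.t, euler_deg[:, col], iv)
            row[f"{ph}.Mean({ang})"] = st["mean"]
            row[f"{ph}.Range({ang})"] = st["range"]
            row[f"{ph}.SD({ang})"] = st["sd"]
        eff = efficiency_ratios(t, acc, iv)
        row[f"{ph}.Eff(AccY)"] = eff["eff"]
        row[f"{ph}.Eff_dir(AccY)"] = eff["eff_dir"]
        for j, sig in enumerate(GYR_NAMES):
            st = signal_stats(t, gyr[:, j], iv)
            row[f"{ph}.Mean({sig})"] = st["mean"]
            row[f"{ph}.Range({sig})"] = st["range"]
            row[f"{ph}.SD({sig})"] = st["sd"]
        row[f"{ph}.Duration"] = ann.duration(ph)

    # kick and stroke rates/counts (rates in 1/min)
    stpr = ann.phases["StPr"]
    n_kicks = _count_kicks(rec_anatomical, stpr)
    row["StPr.KickCount"] = float(n_kicks)
    row["StPr.KickRate"] = 60.0 * n_kicks / ann.duration("StPr")
    n_strokes = cycles.n_cycles
    row["Swim.StrokeCount"] = float(n_strokes)
    row["Swim.StrokeRate"] = 60.0 * n_strokes / ann.duration("Swim")
    durations = np.diff(cycles.boundaries)
    row["Swim.MeanCycleDuration"] = float(np.mean(durations))

    ts, vs = swim_velocity_profile(rec_global_velocity or rec_global, ann, reference)
    dps = [distance_per_stroke(ts, vs, c) for c in cycles.intervals()]
    row["Swim.DPS"] = float(np.mean(dps))

    missing = [k for k, v in row.items() if not np.isfinite(v)]
    if missing:
        raise UndefinedFeature(f"non-finite micro-variables: {missing}")

    # per-cycle rows
    cyc_rows = []
    for i, c in enumerate(cycles.intervals()):
        r: dict[str, float] = {"cycle_index": float(i)}
        r["Cycle.Duration"] = c[1] - c[0]
        r["Cycle.DPS"] = dps[i]
        for ang, col in (("Theta", 1), ("Phi", 2)):
            st = signal_stats(trace.t, euler_deg[:, col], c)
            r[f"Cycle.Mean({ang})"] = st["mean"]
            r[f"Cycle.Range({ang})"] = st["range"]
        st = signal_stats(t, acc[:, 1], c)
        r["Cycle.Mean(AccY)"] = st["mean"]
        r["Cycle.SD(AccY)"] = st["sd"]
        try:
            eff = efficiency_ratios(t, acc, c)
        except UndefinedFeature:
            log.warning("cycle %d dropped: undefined efficiency ratio", i)
            continue
        r["Cycle.Eff(AccY)"] = eff["eff"]
        r["Cycle.Eff_dir(AccY)"] = eff["eff_dir"]
        cyc_rows.append(r)
    cycle_df = pd.DataFrame(cyc_rows, columns=["cycle_index", *CYCLE_COLUMNS])

    expected = set(catalogue_columns())
    got = set(row)
    if got != expected:  # pragma: no cover - defensive
        raise RuntimeError(f"catalogue mismatch: {got ^ expected}")
    return FeatureExtraction(lap_row=pd.Series(row), cycle_rows=cycle_df)
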