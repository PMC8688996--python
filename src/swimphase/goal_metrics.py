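"""Reference goal metrics from a velocity/displacement trace.

Eight per-lap targets: Push maximum velocity, Glid end velocity, StPr
average velocity, Swim average velocity per cycle and over the whole
phase, the 5 m and 15 m times from the wall, and the lap average velocity
(pool length over lap time).  The trace emulates a tethered speedometer
mounted above the water level, so a parallax correction maps line-of-cable
velocity onto the swimming direction before any metric is read.

Time conventions: displacement is 0 at wall contact at lap start; the
trace time axis is lap-relative (t = 0 at the wall); phase annotations are
in recording time, so the lap start offset is removed internally.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .types import CycleSet, GoalMetricSet, PhaseAnnotation, ReferenceTrace

__all__ = ["correct_parallax", "compute_goal_metrics"]


def correct_parallax(raw: ReferenceTrace, h: float, d0: float) -> ReferenceTrace:
    """Project line-of-cable velocity onto the swimming direction.

    The device sits ``h`` metres above still water, ``d0`` metres
    horizontally from the start wall.  With cable length
    ``L(t) = sqrt(d0² + h²) + d_cable(t)`` the swimmer's horizontal
    distance is ``x = sqrt(L² − h²)`` and the forward velocity is
    ``v_f = v_cable · L / x`` (i.e. ``v_cable / cos α``); the forward
    displacement is recomputed by integrating ``v_f``.
    """
    if h < 0:
        raise ValueError("h must be non-negative")
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if h == 0.0:
        return replace(raw, corrected=True)
    L = np.hypot(d0, h) + raw.d
    if np.any(L < h):
        raise ValueError("impossible geometry: cable shorter than the device height")
    x = np.sqrt(L**2 - h**2)
    v_f = raw.v * L / np.maximum(x, 1e-9)
    d_f = cumulative_trapezoid(v_f, raw.t, initial=0.0)
    return replace(raw, v=v_f, d=d_f, corrected=True)


def _crossing_time(t: np.ndarray, d: np.ndarray, level: float) -> float:
    above = d >= level
    if not above.any():
        raise ValueError(f"displacement never reaches {level} m")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (level - d[i - 1]) / (d[i] - d[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _interval_mean(t: np.ndarray, v: np.ndarray, a: float, b: float) -> float:
    """Time-averaged velocity over [a, b] via trapezoidal integration with
    linear interpolation at both endpoints."""
    if b <= a:
        raise ValueError("empty interval")
    grid = np.concatenate([[a], t[(t > a) & (t < b)], [b]])
    return float(np.trapezoid(np.interp(grid, t, v), grid) / (b - a))


def compute_goal_metrics(
    trace: ReferenceTrace,
    ann: PhaseAnnotation,
    cycles: CycleSet | None,
    pool_length: float = 25.0,
) -> GoalMetricSet:
    """Extract the eight goal metrics for one lap.

    ``trace`` must be parallax-corrected and lap-relative (d = 0 at the
    wall); ``ann`` and ``cycles`` may be in recording time — the lap start
    is subtracted.
    """
    if not trace.corrected:
        raise ValueError("reference trace must be parallax-corrected first")
    t0, t1 = ann.lap
    lap_T = t1 - t0

    def rel(iv: tuple[float, float]) -> tuple[float, float]:
        return iv[0] - t0, iv[1] - t0

    t, v, d = trace.t, trace.v, trace.d
    push_on, push_off = rel(ann.phases["Push"])
    m_push = (t >= push_on) & (t < push_off)
    if not m_push.any():
        raise ValueError("trace does not cover the Push phase")
    push_vmax = float(np.max(v[m_push]))
    glid_vend = float(np.interp(rel(ann.phases["Glid"])[1], t, v))
    stpr_vavg = _interval_mean(t, v, *rel(ann.phases["StPr"]))
    swim_vavg_phase = _interval_mean(t, v, *rel(ann.phases["Swim"]))
    if cycles is not None:
        cyc = [ _interval_mean(t, v, a - t0, b - t0) for a, b in cycles.intervals() ]
    else:
        warnings.warn("no cycles supplied; per-cycle velocities empty", RuntimeWarning)
        cyc = []
    return GoalMetricSet(
        push_vmax=push_vmax,
        glid_vend=glid_vend,
        stpr_vavg=stpr_vavg,
        swim_vavg_cycle=np.asarray(cyc),
        swim_vavg_phase=swim_vavg_phase,
        T5m=_crossing_time(t, d, 5.0),
        T15m=_crossing_time(t, d, 15.0),
        lap_vavg=pool_length / lap_T,
    )
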