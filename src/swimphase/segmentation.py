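"""Lap delimitation, Push/Glid/StPr/Swim phase boundaries, stroke cycles.

The phase detector is a documented heuristic built on three events:

1. the end of the forward-acceleration push burst (``Push`` → ``Glid``),
   refined to the zero-crossing of the smoothed forward acceleration;
2. the onset of kicking, seen as the 1–4 Hz band envelope of the
   mediolateral gyroscope channel rising above the gliding baseline
   (``Glid`` → ``StPr``);
3. the onset of the stroke-cycle oscillation: the technique's cycle
   channel envelope rising toward its steady swimming amplitude
   (``StPr`` → ``Swim``), which approximates the first stroke peak
   without the quarter-period bias a literal first-peak read carries.

Camera-style annotations, when available, are the reference path and are
passed through verbatim after invariant checks.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .types import CYCLE_CHANNEL, CycleSet, ImuRecording, PhaseAnnotation

__all__ = [
    "detect_lap_bounds",
    "segment_phases",
    "separate_cycles",
    "SegmentationThresholds",
]


class SegmentationThresholds:
    """Tunable detector thresholds (defaults justified on the simulator)."""

    def __init__(
        self,
        push_acc: float = 1.5,            # m/s^2, forward-acceleration burst level
        push_min_duration: float = 0.05,  # s, burst must persist this long
        kick_band: tuple[float, float] = (1.0, 4.0),  # Hz
        kick_power_factor: float = 5.0,   # kick onset at factor x gliding baseline power
        activity_gyro_rms: float = 0.3,   # rad/s, lap-activity envelope level
        stroke_onset_fraction: float = 0.5,  # of the steady cycle-channel envelope
        min_phase: float = 0.05,          # s, minimum phase width
    ) -> None:
        self.push_acc = push_acc
        self.push_min_duration = push_min_duration
        self.kick_band = kick_band
        self.kick_power_factor = kick_power_factor
        self.activity_gyro_rms = activity_gyro_rms
        self.stroke_onset_fraction = stroke_onset_fraction
        self.min_phase = min_phase


def _moving_rms(x: np.ndarray, win: int) -> np.ndarray:
    win = max(1, win)
    kernel = np.ones(win) / win
    return np.sqrt(np.convolve(x * x, kernel, mode="same"))


def _smooth(x: np.ndarray, win: int) -> np.ndarray:
    win = max(1, win)
    return np.convolve(x, np.ones(win) / win, mode="same")


def _sustained_onset(above: np.ndarray, need: int) -> int | None:
    """First index opening a run of `need` consecutive True samples."""
    run = np.convolve(above.astype(float), np.ones(need), mode="valid")
    hits = np.flatnonzero(run >= need)
    return int(hits[0]) if len(hits) else None


def detect_lap_bounds(
    rec: ImuRecording, thresholds: SegmentationThresholds | None = None
) -> tuple[float, float]:
    """Locate one lap inside a global-frame recording with static padding.

    The lap start is the onset of the push burst (forward acceleration
    above threshold for a sustained window), walked back to the preceding
    near-zero sample.  The lap end is the end of the sustained gyroscope
    activity region that follows the burst — the swimmer stops rolling and
    kicking at wall touch, while the accelerometer still sees the final
    deceleration.  If a second burst exists after that region, only the
    first lap is returned with a warning.
    """
    if rec.frame != "global":
        raise ValueError("expected a global-frame recording")
    th = thresholds or SegmentationThresholds()
    fs = rec.fs
    acc_y_s = _smooth(rec.acc[:, 1], int(0.02 * fs))

    need = int(round(th.push_min_duration * fs))
    i_burst = _sustained_onset(acc_y_s > th.push_acc, need)
    if i_burst is None:
        raise ValueError("no lap detected: no sustained push burst found")
    i0 = i_burst
    while i0 > 0 and acc_y_s[i0 - 1] > 0.1:
        i0 -= 1
    t_start = rec.t[i0]

    env = _moving_rms(np.linalg.norm(rec.gyr, axis=1), int(0.3 * fs))
    active = env > th.activity_gyro_rms
    gap = int(round(3.0 * fs))  # bridge quiet glides into one active region
    idx = np.flatnonzero(active)
    if len(idx) == 0:
        raise ValueError("no lap detected: no gyroscope activity")
    segments: list[list[int]] = []
    for i in idx:
        if segments and i - segments[-1][1] <= gap:
            segments[-1][1] = int(i)
        else:
            segments.append([int(i), int(i)])
    seg = next((s for s in segments if s[1] > i_burst), segments[-1])
    t_end = rec.t[seg[1]]
    if t_end - t_start < 2.0:
        raise ValueError("no lap detected: active region too short")

    after = acc_y_s[seg[1] + int(1.0 * fs) :]
    if len(after) and _sustained_onset(after > th.push_acc, need) is not None:
        warnings.warn("multiple laps found in recording; returning the first", RuntimeWarning)
    return float(t_start), float(t_end)


def _band_envelope(
    x: np.ndarray, fs: float, band: tuple[float, float], win_s: float = 0.2
) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    xf = signal.sosfiltfilt(sos, x)
    return _moving_rms(xf, int(round(win_s * fs)))


def segment_phases(
    rec_global: ImuRecording,
    lap: tuple[float, float],
    technique: str,
    rec_anatomical: ImuRecording | None = None,
    annotation: PhaseAnnotation | None = None,
    thresholds: SegmentationThresholds | None = None,
) -> PhaseAnnotation:
    """Split the lap into the four contiguous swimming phases.

    When a camera-style ``annotation`` is supplied it is validated and
    returned verbatim (the reference path).  The anatomical-frame
    recording provides the gyroscope channels for the kick/stroke onsets;
    the global-frame gyro is the fallback.
    """
    if annotation is not None:
        annotation.validate()
        return annotation
    th = thresholds or SegmentationThresholds()
    fs = rec_global.fs
    t0, t1 = lap
    if t1 <= t0:
        raise ValueError("invalid lap bounds")
    gyro_rec = rec_anatomical if rec_anatomical is not None else rec_global
    t = rec_global.t
    m_lap = (t >= t0) & (t < t1)
    tl = t[m_lap]
    acc_y = _smooth(rec_global.acc[:, 1], int(0.02 * fs))[m_lap]

    # --- Push end: first zero-crossing of forward acceleration after the burst
    # peak that is followed by sustained deceleration (the glide), so brief
    # braking ripples inside the burst are not mistaken for the phase end
    i_peak = int(np.argmax(acc_y[: int(min(3.0, t1 - t0) * fs)]))
    look = int(0.4 * fs)
    look_pos = int(0.25 * fs)
    push_off = None
    for c in np.flatnonzero(acc_y[i_peak:] <= 0.0):
        i = i_peak + int(c)
        sustained_decel = np.mean(acc_y[i : i + look]) < -0.1
        no_rebound = np.max(acc_y[i : i + look_pos]) < 0.5 * th.push_acc
        if sustained_decel and no_rebound:
            push_off = float(tl[i])
            break
    if push_off is None:
        raise ValueError("Push phase: forward acceleration never falls off")

    # --- Glid end: mediolateral-gyro kick-band envelope leaving the glide baseline
    gyr_ml = gyro_rec.gyr[m_lap, 2]
    env = _band_envelope(gyr_ml, fs, th.kick_band)
    m_after = tl >= push_off + 0.2
    base_win = m_after & (tl < push_off + 0.9)
    baseline = max(float(np.median(env[base_win])), 1e-4)
    amp_ref = float(np.percentile(env[m_after], 95))
    level = max(np.sqrt(th.kick_power_factor) * baseline, 0.3 * amp_ref)
    crossing = np.flatnonzero(m_after & (env > level))
    if len(crossing) == 0:
        raise ValueError("Glid phase: no kick onset found")
    i_kick = int(crossing[0])
    floor = max(1.5 * baseline, 0.15 * amp_ref)
    while i_kick > 0 and tl[i_kick - 1] > push_off and env[i_kick - 1] > floor:
        i_kick -= 1
    glid_off = float(tl[i_kick])

    # --- StPr end: cycle-channel envelope rising toward its steady amplitude
    cyc = gyro_rec.gyr[m_lap, CYCLE_CHANNEL[technique]]
    env_c = _moving_rms(cyc, int(0.3 * fs))
    late = env_c[tl > t0 + 0.6 * (t1 - t0)]
    steady = float(np.percentile(late, 90))
    m_after_glid = tl >= glid_off
    crossing = np.flatnonzero(m_after_glid & (env_c > th.stroke_onset_fraction * steady))
    if len(crossing) == 0:
        raise ValueError("StPr phase: no stroke onset found")
    # backtrack toward the oscillation foot; the floor sits above the StPr
    # kick amplitude so the walk stops at the kick/stroke transition when the
    # two share a channel (breaststroke, butterfly)
    i_sw = int(crossing[0])
    floor_c = 0.35 * steady
    while i_sw > 0 and tl[i_sw - 1] > glid_off and env_c[i_sw - 1] > floor_c:
        i_sw -= 1
    swim_on = float(tl[i_sw])

    # enforce ordering with a minimal width, warn on collapsed phases
    bounds = [float(t0), push_off, glid_off, swim_on, float(t1)]
    names = ["Push", "Glid", "StPr", "Swim"]
    for i in range(1, 4):
        if bounds[i] < bounds[i - 1] + th.min_phase:
            warnings.warn(f"phase {names[i - 1]} collapsed to minimum width", RuntimeWarning)
            bounds[i] = bounds[i - 1] + th.min_phase
    if bounds[3] >= t1:
        raise ValueError("phase boundary inversion: Swim has no room before lap end")
    return PhaseAnnotation(
        lap=(float(t0), float(t1)),
        phases={n: (bounds[i], bounds[i + 1]) for i, n in enumerate(names)},
        source="imu",
    )


def separate_cycles(
    rec_anatomical: ImuRecording,
    swim_interval: tuple[float, float],
    technique: str,
    prominence_factor: float = 0.3,
) -> CycleSet:
    """Stroke-cycle boundaries from successive positive peaks.

    Uses the longitudinal angular velocity (GyrY) for front crawl and
    backstroke, the mediolateral one (GyrZ) for breaststroke and
    butterfly.  Peaks are found in two passes: a liberal pass establishes
    the median inter-peak interval, a second pass enforces a minimum peak
    distance of half that interval.
    """
    t_on, t_off = swim_interval
    if t_off - t_on < 1.0:
        raise ValueError("Swim interval must cover at least 1 s")
    m = (rec_anatomical.t >= t_on) & (rec_anatomical.t < t_off)
    tt = rec_anatomical.t[m]
    # stroke rates sit well below ~1.5 Hz; a 0.15 s moving average suppresses
    # sensor noise without shifting the (symmetric) smoothing of the peaks
    x = _smooth(rec_anatomical.gyr[m, CYCLE_CHANNEL[technique]], int(0.15 * rec_anatomical.fs))
    amp = float(np.percentile(np.abs(x), 95))
    if amp < 1e-6:
        raise ValueError("no cycles detected: cycle channel is flat")
    prom = prominence_factor * amp
    peaks, _ = signal.find_peaks(x, prominence=prom, height=0.0)
    if len(peaks) >= 3:
        median_gap = float(np.median(np.diff(peaks)))
        peaks, _ = signal.find_peaks(
            x, prominence=prom, height=0.0, distance=max(1, int(0.5 * median_gap))
        )
    if len(peaks) < 2:
        raise ValueError("no cycles detected: fewer than 2 stroke peaks")
    return CycleSet(boundaries=tt[peaks], technique=technique)
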