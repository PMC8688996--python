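"""End-to-end orchestration: preparation → segmentation → features →
goal metrics → variable selection and goal-metric estimation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import goal_metrics as gm
from . import model as mdl
from . import orientation as ori
from . import segmentation as seg
from .features import UndefinedFeature, extract_micro_variables
from .segmentation import SegmentationThresholds
from .synthetic import SyntheticLap
from .types import (
    CalibrationParams,
    CycleSet,
    GoalMetricSet,
    ImuRecording,
    OrientationTrace,
    PhaseAnnotation,
    ReferenceTrace,
    RegressionReport,
    SelectionResult,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ProcessedLap", "process_lap", "run_cohort", "TargetReport"]


@dataclass
class PipelineConfig:
    technique: str = "front_crawl"
    pool_length: float = 25.0
    fusion_gain: float = 0.1            # Madgwick-style filter gain, rad/s
    accel_gate: float | None = 0.5      # m/s^2 tolerance around gravity
    static_window: tuple[float, float] = (0.5, 5.5)  # s, pre-lap window for q0
    phase_source: str = "imu"           # "imu" | "annotation"
    thresholds: SegmentationThresholds = field(default_factory=SegmentationThresholds)
    vif_threshold: float = 10.0
    weight_threshold_pct: float = 5.0
    lasso_cv: int = 10
    n_alphas: int = 100
    sync_offset: float = 0.0            # s, reference-trace vs IMU clock offset
    speedometer_height: float = 0.62    # m, device level above still water
    speedometer_distance: float = 6.0   # m, horizontal anchor distance at start
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_source not in ("imu", "annotation"):
            raise ValueError("phase_source must be 'imu' or 'annotation'")


@dataclass
class ProcessedLap:
    """Everything the pipeline derives from one lap recording."""

    lap_id: str
    rec_anatomical: ImuRecording
    rec_global: ImuRecording
    trace: OrientationTrace
    annotation: PhaseAnnotation
    cycles: CycleSet
    lap_row: pd.Series
    cycle_rows: pd.DataFrame
    goals: Optional[GoalMetricSet] = None


def _strapdown_global(
    rec_a: ImuRecording, trace: OrientationTrace, t_anchor: float
) -> ImuRecording:
    """Global-frame recording from gyroscope-only integration after ``t_anchor``.

    The fused orientation at the anchor (taken inside the pre-lap static
    span, where the filter is well converged) seeds a pure strapdown
    through the lap; over a sub-30 s lap the gyroscope random walk is far
    smaller than the gravity leakage the accelerometer correction causes
    during sustained horizontal decelerations (the glide).
    """
    i = max(0, int(np.searchsorted(rec_a.t, t_anchor)))
    sub = replace(rec_a, t=rec_a.t[i:], acc=rec_a.acc[i:], gyr=rec_a.gyr[i:])
    tr = ori.fuse_orientation(sub, trace.q[i], gain=0.0)
    return ori.rotate_to_global(sub, tr)


def process_lap(
    imu_sensor: ImuRecording,
    calibration: CalibrationParams,
    config: PipelineConfig,
    annotation: Optional[PhaseAnnotation] = None,
    reference: Optional[ReferenceTrace] = None,
    lap_id: str = "lap",
) -> ProcessedLap:
    """Run preparation, segmentation, feature extraction and (if a
    reference trace is given) goal-metric computation for one lap."""
    rec_a = ori.apply_calibration(imu_sensor, calibration)
    q0 = ori.estimate_initial_orientation(
        rec_a.slice(*config.static_window)
    )
    trace = ori.fuse_orientation(
        rec_a, q0, gain=config.fusion_gain, accel_gate=config.accel_gate
    )
    rec_g = ori.rotate_to_global(rec_a, trace)

    if config.phase_source == "annotation":
        if annotation is None:
            raise ValueError(f"{lap_id}: phase_source='annotation' but none supplied")
        ann = seg.segment_phases(
            rec_g, annotation.lap, config.technique, annotation=annotation
        )
    else:
        bounds = seg.detect_lap_bounds(rec_g, config.thresholds)
        ann = seg.segment_phases(
            rec_g, bounds, config.technique, rec_anatomical=rec_a,
            thresholds=config.thresholds,
        )
    cycles = seg.separate_cycles(rec_a, ann.phases["Swim"], config.technique)

    rec_gv = _strapdown_global(rec_a, trace, ann.lap[0] - 1.0)
    fx = extract_micro_variables(
        rec_g, rec_a, trace, ann, cycles, config.technique,
        rec_global_velocity=rec_gv,
    )

    goals = None
    if reference is not None:
        ref = reference
        if config.sync_offset:
            ref = replace(ref, t=ref.t + config.sync_offset)
        if not ref.corrected:
            ref = gm.correct_parallax(
                ref, config.speedometer_height, config.speedometer_distance
            )
        goals = gm.compute_goal_metrics(ref, ann, cycles, config.pool_length)
    return ProcessedLap(
        lap_id=lap_id,
        rec_anatomical=rec_a,
        rec_global=rec_g,
        trace=trace,
        annotation=ann,
        cycles=cycles,
        lap_row=fx.lap_row,
        cycle_rows=fx.cycle_rows,
        goals=goals,
    )


@dataclass
class TargetReport:
    target: str
    selection: SelectionResult
    regression: RegressionReport


def _goal_frame(processed: list[ProcessedLap]) -> pd.DataFrame:
    rows = {}
    for p in processed:
        if p.goals is not None:
            rows[p.lap_id] = p.goals.scalars()
    return pd.DataFrame.from_dict(rows, orient="index")


def run_cohort(
    laps: Sequence[SyntheticLap] | Sequence[dict],
    config: PipelineConfig,
    targets: Sequence[str] = tuple(mdl.TARGET_PHASES),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, TargetReport]]:
    """Process a cohort of laps and model every requested goal metric.

    ``laps`` may be :class:`~swimphase.synthetic.SyntheticLap` objects or
    dicts with keys ``imu_sensor``, ``calibration`` and optionally
    ``annotation``, ``reference``, ``lap_id``.  Returns the lap feature
    table, the per-cycle feature table, the goal-metric table and one
    report per target.  Laps whose extraction fails are dropped with a
    logged reason.
    """
    processed: list[ProcessedLap] = []
    for i, lap in enumerate(laps):
        if isinstance(lap, SyntheticLap):
            kw = dict(
                imu_sensor=lap.imu_sensor,
                calibration=lap.calibration,
                annotation=lap.annotation,
                reference=lap.reference,
                lap_id=f"lap_{i:03d}",
            )
        else:
            kw = {"lap_id": f"lap_{i:03d}", **lap}
        try:
            processed.append(process_lap(config=config, **kw))
        except (ValueError, UndefinedFeature) as exc:
            log.warning("%s dropped: %s", kw["lap_id"], exc)
    if not processed:
        raise ValueError("no lap survived processing")

    features = pd.DataFrame({p.lap_id: p.lap_row for p in processed}).T
    cycle_frames = []
    for p in processed:
        df = p.cycle_rows.copy()
        df.insert(0, "lap_id", p.lap_id)
        cycle_frames.append(df)
    cycle_features = pd.concat(cycle_frames, ignore_index=True)
    goals = _goal_frame(processed)

    # per-cycle target vector, aligned with the per-cycle feature rows
    cycle_y = []
    for p in processed:
        if p.goals is None:
            continue
        kept = p.cycle_rows["cycle_index"].astype(int).to_numpy()
        cycle_y.extend(np.asarray(p.goals.swim_vavg_cycle)[kept])

    reports: dict[str, TargetReport] = {}
    if goals.empty:
        log.info("no reference traces given; goal-metric modelling skipped")
        return features, cycle_features, goals, reports

    for target in targets:
        try:
            if target == "swim_vavg_cycle":
                X = cycle_features.drop(columns=["lap_id", "cycle_index"])
                y = np.asarray(cycle_y, dtype=float)
            else:
                X, y = mdl.assemble_design(features, target, goals)
            Xn = mdl.normalize_features(X)
            Xr, removed = mdl.vif_filter(Xn, config.vif_threshold)
            sel = mdl.lasso_select(
                Xr, y,
                threshold_pct=config.weight_threshold_pct,
                cv=config.lasso_cv,
                n_alphas=config.n_alphas,
                seed=config.seed,
            )
            cols = sel.selected if sel.selected else list(sel.weights)
            rep = mdl.fit_evaluate_loocv(
                Xr[cols], y, cv=config.lasso_cv, seed=config.seed
            )
            rep.target = target
            reports[target] = TargetReport(target=target, selection=sel, regression=rep)
        except ValueError as exc:
            log.warning("target %s skipped: %s", target, exc)
    return features, cycle_features, goals, reports
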