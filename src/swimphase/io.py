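"""Readers/writers for the on-disk formats.

IMU CSV: columns ``t,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z`` (SI units,
header mandatory) with a sidecar ``<stem>.meta.yaml`` recording fs, frame
and units.  Reference CSV: ``t,v,d``.  Annotations and cycle boundaries:
JSON.  Calibration: YAML with bias vectors and row-major 3x3 matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    CalibrationParams,
    CycleSet,
    GoalMetricSet,
    ImuRecording,
    PhaseAnnotation,
    ReferenceTrace,
)

IMU_COLUMNS = ["t", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def write_imu_csv(path: str | Path, rec: ImuRecording) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.acc, rec.gyr]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "fs": rec.fs,
        "frame": rec.frame,
        "units": {"t": "s", "acc": "m/s^2", "gyr": "rad/s"},
    }
    _meta_path(path).write_text(yaml.safe_dump(meta))


def read_imu_csv(path: str | Path) -> ImuRecording:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(IMU_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    meta_file = _meta_path(path)
    if meta_file.exists():
        meta = yaml.safe_load(meta_file.read_text())
        fs, frame = float(meta["fs"]), str(meta["frame"])
    else:
        dt = float(np.median(np.diff(df["t"])))
        fs, frame = 1.0 / dt, "sensor"
    return ImuRecording(
        t=df["t"].to_numpy(),
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        gyr=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(),
        fs=fs,
        frame=frame,
    )


def write_reference_csv(path: str | Path, trace: ReferenceTrace) -> None:
    path = Path(path)
    pd.DataFrame({"t": trace.t, "v": trace.v, "d": trace.d}).to_csv(
        path, index=False, float_format="%.9g"
    )
    _meta_path(path).write_text(
        yaml.safe_dump({"fr": trace.fr, "corrected": bool(trace.corrected)})
    )


def read_reference_csv(path: str | Path) -> ReferenceTrace:
    path = Path(path)
    df = pd.read_csv(path)
    fr, corrected = 100.0, False
    meta_file = _meta_path(path)
    if meta_file.exists():
        meta = yaml.safe_load(meta_file.read_text())
        fr = float(meta.get("fr", fr))
        corrected = bool(meta.get("corrected", False))
    return ReferenceTrace(
        t=df["t"].to_numpy(), v=df["v"].to_numpy(), d=df["d"].to_numpy(),
        fr=fr, corrected=corrected,
    )


def write_annotation_json(path: str | Path, ann: PhaseAnnotation) -> None:
    payload = {
        "lap": list(ann.lap),
        "phases": {k: list(v) for k, v in ann.phases.items()},
        "source": ann.source,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotation_json(path: str | Path) -> PhaseAnnotation:
    payload = json.loads(Path(path).read_text())
    return PhaseAnnotation(
        lap=tuple(payload["lap"]),
        phases={k: tuple(v) for k, v in payload["phases"].items()},
        source=payload.get("source", "camera"),
    )


def write_cycles_json(path: str | Path, cycles: CycleSet) -> None:
    Path(path).write_text(
        json.dumps(
            {"technique": cycles.technique, "boundaries": list(cycles.boundaries)},
            indent=1,
        )
    )


def read_cycles_json(path: str | Path) -> CycleSet:
    payload = json.loads(Path(path).read_text())
    return CycleSet(
        boundaries=np.asarray(payload["boundaries"]), technique=payload["technique"]
    )


def write_calibration_yaml(path: str | Path, cal: CalibrationParams) -> None:
    payload = {
        "acc_bias": cal.acc_bias.tolist(),
        "gyr_bias": cal.gyr_bias.tolist(),
        "acc_scale": cal.acc_scale.tolist(),
        "gyr_scale": cal.gyr_scale.tolist(),
        "R_sensor_to_anatomical": cal.R_sensor_to_anatomical.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(payload))


def read_calibration_yaml(path: str | Path) -> CalibrationParams:
    payload = yaml.safe_load(Path(path).read_text())
    return CalibrationParams(**{k: np.asarray(v) for k, v in payload.items()})


def write_goal_metrics_json(path: str | Path, goals: GoalMetricSet) -> None:
    payload = goals.scalars()
    payload["swim_vavg_cycle"] = list(np.asarray(goals.swim_vavg_cycle, dtype=float))
    Path(path).write_text(json.dumps(payload, indent=1))


def write_features_csv(
    path: str | Path, features: pd.DataFrame, categories: dict[str, str]
) -> None:
    path = Path(path)
    features.to_csv(path, index=True, index_label="lap_id", float_format="%.9g")
    path.with_suffix(".categories.json").write_text(json.dumps(categories, indent=1))


def write_report_json(path: str | Path, report) -> None:
    """Serialize a :class:`~swimphase.pipeline.TargetReport`."""
    sel = report.selection
    reg = report.regression
    payload = {
        "target": report.target,
        "n_obs": reg.n_obs,
        "selected": [
            {"name": n, "weight_pct": sel.weights[n], "category": _category(n)}
            for n in sel.selected
        ],
        "weights": sel.weights,
        "category_contrib": sel.category_contrib,
        "category_contrib_renorm": sel.category_contrib_renorm,
        "alpha": sel.alpha,
        "r2": reg.r2,
        "rmse": reg.rmse,
        "rel_rmse": reg.rel_rmse,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _category(name: str) -> str:
    from .features import category_of

    try:
        return category_of(name)
    except KeyError:
        return "unknown"
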