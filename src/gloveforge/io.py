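"""Readers/writers for the toolkit's plain-text interchange formats.

* marker CSV: ``time, m0_x, m0_y, m0_z, …, m20_z`` (one row per frame);
* motion CSV: ``Time`` column plus one named joint column, angles in degrees;
* sensor CSV: ``time`` plus ``<site>/<ax…mz>`` columns per simulated site;
* TRC-style motion-capture text via a documented column map;
* manifest CSV: ``file, activity, session`` linking takes to labels.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ik import IKDiagnostics, JointAngleMotion
from .pipeline import SensorRecording
from .preprocess import MarkerSequence

__all__ = [
    "write_marker_csv",
    "read_marker_csv",
    "read_trc",
    "write_motion_csv",
    "read_motion_csv",
    "write_diagnostics_json",
    "write_sensor_csv",
    "read_sensor_csv",
]

_MARKER_COLS = [f"m{i}_{ax}" for i in range(21) for ax in "xyz"]


def write_marker_csv(seq: MarkerSequence, path) -> None:
    df = pd.DataFrame(seq.positions.reshape(len(seq), -1), columns=_MARKER_COLS)
    df.insert(0, "time", seq.times)
    df.to_csv(path, index=False)


def read_marker_csv(path, handedness: str = "right", source: str = "mocap") -> MarkerSequence:
    df = pd.read_csv(path)
    missing = [c for c in ["time"] + _MARKER_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"marker CSV missing columns: {missing[:4]}…")
    pos = df[_MARKER_COLS].to_numpy(float).reshape(len(df), 21, 3)
    return MarkerSequence(df["time"].to_numpy(float), pos, handedness=handedness, source=source)


def read_trc(path, column_map: dict[int, int] | None = None) -> MarkerSequence:
    """Read TRC-style motion-capture text (tab-separated, 5 header lines).

    ``column_map`` maps TRC marker index (0-based, file order) to the 21-key-
    point index; identity for the first 21 markers when omitted.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise ValidationError("not a TRC file")
    rows = [l.split("\t") for l in lines[5:] if l.strip()]
    data = np.array([[float(v) if v else np.nan for v in r] for r in rows])
    times = data[:, 1]
    xyz = data[:, 2:]
    n_markers = xyz.shape[1] // 3
    cmap = column_map or {i: i for i in range(min(21, n_markers))}
    if len(cmap) < 21:
        raise ValidationError("TRC file does not provide all 21 key-points")
    pos = np.empty((len(times), 21, 3))
    for src, dst in cmap.items():
        pos[:, dst] = xyz[:, 3 * src : 3 * src + 3]
    return MarkerSequence(times, pos, handedness="right", source="mocap")


def write_motion_csv(motion: JointAngleMotion, path) -> None:
    """Motion file: first column ``Time``, then one column per joint (degrees)."""
    df = motion.angles.copy()
    df.insert(0, "Time", motion.times)
    df.to_csv(path, index=False)


def read_motion_csv(path, activity: str = "", session: str = "") -> JointAngleMotion:
    df = pd.read_csv(path)
    if "Time" not in df.columns:
        raise ValidationError("motion CSV must have a 'Time' first column")
    times = df.pop("Time").to_numpy(float)
    return JointAngleMotion(times, df, activity=activity, session=session)


def write_diagnostics_json(diag: IKDiagnostics, path) -> None:
    payload = {
        "mde_mean_mm": diag.mde_mean,
        "mde_std_mm": diag.mde_std,
        "cvr_percent": diag.cvr,
        "cvm_mean_deg": None if np.isnan(diag.cvm_mean) else diag.cvm_mean,
        "cvm_std_deg": None if np.isnan(diag.cvm_std) else diag.cvm_std,
        "frame_mde_mm": diag.frame_mde.tolist(),
        "nonconverged_frames": list(diag.nonconverged_frames),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_sensor_csv(rec: SensorRecording, path) -> None:
    df = pd.DataFrame(rec.data, columns=rec.channel_names)
    df.insert(0, "time", rec.times)
    df.to_csv(path, index=False)


def read_sensor_csv(path, activity: str, take_id: str, source_id: str = "") -> SensorRecording:
    df = pd.read_csv(path)
    times = df.pop("time").to_numpy(float)
    return SensorRecording(
        times=times,
        data=df.to_numpy(float),
        channel_names=list(df.columns),
        activity=activity,
        take_id=take_id,
        source_id=source_id or take_id,
    )
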