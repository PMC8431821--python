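"""Stride-table and marker-table CSV formats.

Stride tables are long-format CSV (UTF-8, '.' decimal, header) with one row
per stride: ``participant, session, condition, phase, stride, vf,
target_sai, sai`` (percentages stored as plain numbers, e.g. 22 not 0.22).
Marker tables hold one column per marker's sagittal position in metres plus
a ``time`` column; blank cells mark occlusion gaps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import ParticipantDataset, Session
from .kinematics import MarkerTrajectory
from .schedules import TargetSchedule

__all__ = [
    "STRIDE_COLUMNS",
    "MARKER_NAMES",
    "read_stride_table",
    "write_stride_table",
    "read_marker_table",
    "write_marker_table",
]

STRIDE_COLUMNS = (
    "participant",
    "session",
    "condition",
    "phase",
    "stride",
    "vf",
    "target_sai",
    "sai",
)

MARKER_NAMES = ("heel_L", "heel_R", "met5_L", "met5_R", "hip_L", "hip_R", "ankle_L", "ankle_R")


class SchemaError(ValueError):
    """A stride/marker file violates the expected schema."""


def write_stride_table(datasets, path) -> None:
    """Serialize one or more participant datasets to a stride-table CSV."""
    if isinstance(datasets, ParticipantDataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        for si, s in enumerate(ds.sessions):
            sched = s.schedule
            frames.append(
                pd.DataFrame(
                    {
                        "participant": ds.participant,
                        "session": si + 1,
                        "condition": sched.condition,
                        "phase": sched.phase,
                        "stride": np.arange(1, sched.n_strides + 1),
                        "vf": sched.vf.astype(int),
                        "target_sai": sched.target,
                        "sai": s.sai,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_stride_table(path) -> list[ParticipantDataset]:
    """Parse a stride-table CSV into per-participant datasets.

    Validates the schema strictly; error messages carry the offending column
    or the first offending CSV line number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in STRIDE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    for col in ("stride", "vf"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise SchemaError(f"{path.name}: column {col!r} must be integer")
    for col in ("target_sai", "sai"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"{path.name}: column {col!r} must be numeric")
        if df[col].isna().any():
            line = int(df.index[df[col].isna()][0]) + 2  # header is line 1
            raise SchemaError(f"{path.name}: line {line}: missing value in {col!r}")

    datasets = []
    for pid, pgroup in df.groupby("participant", sort=False):
        sessions = []
        for sid, g in pgroup.groupby("session", sort=True):
            strides = g["stride"].to_numpy()
            if not (np.diff(strides) > 0).all():
                bad = int(g.index[np.flatnonzero(np.diff(strides) <= 0)[0] + 1]) + 2
                raise SchemaError(
                    f"{path.name}: line {bad}: stride index not strictly increasing "
                    f"(participant {pid!r}, session {sid})"
                )
            cond = g["condition"].iloc[0]
            if (g["condition"] != cond).any():
                raise SchemaError(
                    f"{path.name}: participant {pid!r} session {sid} mixes conditions"
                )
            try:
                sched = TargetSchedule(
                    condition=cond,
                    phase=g["phase"].to_numpy(),
                    vf=g["vf"].to_numpy().astype(bool),
                    target=g["target_sai"].to_numpy(),
                )
            except ValueError as exc:
                raise SchemaError(
                    f"{path.name}: participant {pid!r} session {sid}: {exc}"
                ) from exc
            sessions.append(Session(sched, g["sai"].to_numpy()))
        datasets.append(ParticipantDataset(pid, tuple(sessions)))
    return datasets


def write_marker_table(markers: dict, path, fs: float | None = None) -> None:
    """Serialize a marker set (name -> MarkerTrajectory) to CSV; gaps become blanks."""
    names = list(markers)
    fs = fs if fs is not None else markers[names[0]].fs
    n = len(markers[names[0]])
    data = {"time": np.arange(n) / fs}
    for name in names:
        traj = markers[name]
        if len(traj) != n:
            raise ValueError(f"marker {name!r} length {len(traj)} != {n}")
        col = traj.position.astype(float).copy()
        col[traj.gaps] = np.nan
        data[name] = col
    pd.DataFrame(data).to_csv(path, index=False)


def read_marker_table(path) -> dict[str, MarkerTrajectory]:
    """Parse a marker-table CSV into MarkerTrajectory objects (NaN cells -> gaps)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise SchemaError(f"{path.name}: missing required column(s): time")
    marker_cols = [c for c in df.columns if c != "time"]
    if not marker_cols:
        raise SchemaError(f"{path.name}: no marker columns found")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise SchemaError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6) or dt[0] <= 0:
        raise SchemaError(f"{path.name}: time column must be uniformly increasing")
    fs = 1.0 / dt[0]
    out = {}
    for c in marker_cols:
        pos = df[c].to_numpy(dtype=float)
        gaps = np.isnan(pos)
        pos = np.where(gaps, 0.0, pos)
        out[c] = MarkerTrajectory(pos, fs, gaps=gaps)
    return out
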