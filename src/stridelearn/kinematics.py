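"""Marker trajectories to gait events, step lengths, and asymmetry indices.

The pipeline mirrors standard treadmill gait processing: cubic-spline gap
filling, zero-phase 4th-order Butterworth low-pass filtering at 10 Hz, gait
event detection from marker velocity sign changes (heel strike at the heel
marker's forward extreme, toe off at the fifth-metatarsal marker's backward
extreme), step lengths as the sagittal heel-to-heel distance at leading heel
strike, and the step asymmetry index

    SAI = (SL_long - SL_short) / (SL_long + SL_short) * 100  [percent].

Conventions: "sagittal" is the anterior-posterior axis, positive forward;
frame indices are 0-based; a stride runs left heel strike to left heel
strike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

__all__ = [
    "MarkerTrajectory",
    "GaitEvents",
    "fill_gaps",
    "lowpass",
    "detect_events",
    "step_lengths",
    "sai",
    "stride_sai",
    "limb_placement",
    "placement_asymmetry",
]


@dataclass(frozen=True)
class MarkerTrajectory:
    """Sagittal position (m) of one marker sampled at ``fs`` Hz.

    ``gaps`` marks samples lost to occlusion; non-gap samples must be finite.
    """

    position: np.ndarray
    fs: float = 100.0
    gaps: np.ndarray | None = None

    def __post_init__(self):
        if not self.fs > 0:
            raise ValueError(f"fs={self.fs} must be positive")
        pos = np.asarray(self.position, dtype=float)
        gaps = (
            np.zeros(pos.size, dtype=bool)
            if self.gaps is None
            else np.asarray(self.gaps, dtype=bool)
        )
        if gaps.shape != pos.shape:
            raise ValueError("gap mask must match position length")
        if not np.isfinite(pos[~gaps]).all():
            raise ValueError("non-gap samples must be finite")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "gaps", gaps)

    def __len__(self) -> int:
        return self.position.size


@dataclass(frozen=True)
class GaitEvents:
    """Frame indices of heel strikes and toe offs for one side."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self):
        for name in ("heel_strikes", "toe_offs"):
            idx = np.asarray(getattr(self, name), dtype=int)
            if idx.size > 1 and not (np.diff(idx) > 0).all():
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, idx)


def fill_gaps(traj: MarkerTrajectory) -> MarkerTrajectory:
    """Fill occlusion gaps by cubic-spline interpolation; non-gap samples unchanged."""
    if not traj.gaps.any():
        return traj
    t = np.arange(len(traj))
    good = ~traj.gaps
    if good.sum() < 4:
        raise ValueError("need at least 4 valid samples to spline-fill gaps")
    spline = CubicSpline(t[good], traj.position[good])
    pos = traj.position.copy()
    pos[traj.gaps] = spline(t[traj.gaps])
    return MarkerTrajectory(pos, traj.fs)


def lowpass(traj: MarkerTrajectory, cutoff: float = 10.0, order: int = 4) -> MarkerTrajectory:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Zero-phase application preserves event timing; DC is preserved exactly.
    Gaps must be filled first.
    """
    if traj.gaps.any():
        raise ValueError("fill gaps before filtering")
    b, a = butter(order, cutoff, fs=traj.fs)
    return MarkerTrajectory(filtfilt(b, a, traj.position), traj.fs)


def _prominent_maxima(pos: np.ndarray, min_prominence_frac: float) -> np.ndarray:
    amp = np.ptp(pos)
    if amp == 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(pos, prominence=min_prominence_frac * amp)
    return peaks


def detect_events(
    heel: MarkerTrajectory,
    met5: MarkerTrajectory,
    fs: float | None = None,
    min_prominence_frac: float = 0.05,
) -> GaitEvents:
    """Gait events for one side from heel and fifth-metatarsal markers.

    Heel strike: the heel marker's velocity transitions positive -> negative
    (its forward extreme). Toe off: the fifth-metatarsal velocity transitions
    negative -> positive (its backward extreme). Extrema whose prominence is
    below ``min_prominence_frac`` of the marker's range are discarded — they
    are numerical ripple while the marker is effectively stationary, not
    steps. Raises ``ValueError`` if fewer than two gait cycles are found.
    """
    hs = _prominent_maxima(heel.position, min_prominence_frac)
    to = _prominent_maxima(-met5.position, min_prominence_frac)
    if hs.size < 2:
        raise ValueError(f"detected {hs.size} heel strikes; need at least 2 gait cycles")
    return GaitEvents(heel_strikes=hs, toe_offs=to)


def step_lengths(
    heel_left: MarkerTrajectory,
    heel_right: MarkerTrajectory,
    events_left: GaitEvents,
    events_right: GaitEvents,
) -> pd.DataFrame:
    """Per-step lengths (m) tagged by leading side.

    At each leading heel strike the step length is the sagittal difference
    between the leading and trailing heel markers. Returns a frame-ordered
    DataFrame with columns ``frame``, ``side`` (the leading side), ``length``.
    """
    rows = []
    for side, events, lead, trail in (
        ("L", events_left, heel_left, heel_right),
        ("R", events_right, heel_right, heel_left),
    ):
        for f in events.heel_strikes:
            rows.append({"frame": int(f), "side": side, "length": lead.position[f] - trail.position[f]})
    return pd.DataFrame(rows).sort_values("frame", ignore_index=True)


def sai(step_long, step_short):
    """Step asymmetry index, percent: (long - short) / (long + short) * 100.

    Scale-invariant: multiplying both step lengths by a positive constant
    leaves the index unchanged. Both lengths must be positive.
    """
    long = np.asarray(step_long, dtype=float)
    short = np.asarray(step_short, dtype=float)
    if (long <= 0).any() or (short <= 0).any():
        raise ValueError("step lengths must be positive")
    out = (long - short) / (long + short) * 100.0
    return float(out) if out.ndim == 0 else out


def stride_sai(steps: pd.DataFrame, long_side: str = "L") -> np.ndarray:
    """Per-stride SAI from a step table, strides indexed by ``long_side`` heel strikes.

    Each stride pairs a ``long_side`` step with the next contralateral step.
    By the study's convention the left step is lengthened during learning, so
    SAI is positive when the long side takes longer steps.
    """
    short_side = "R" if long_side == "L" else "L"
    steps = steps.sort_values("frame")
    values = []
    pending_long = None
    for _, row in steps.iterrows():
        if row["side"] == long_side:
            pending_long = row["length"]
        elif pending_long is not None:
            values.append(sai(pending_long, row["length"]))
            pending_long = None
    return np.asarray(values)


def limb_placement(
    hip: MarkerTrajectory, ankle: MarkerTrajectory, events: GaitEvents
) -> tuple[np.ndarray, np.ndarray]:
    """Leading and trailing limb placement (m) for one side.

    Leading placement is the sagittal ankle-minus-hip distance at that limb's
    heel strike (positive: foot ahead of the hip); trailing placement is the
    hip-minus-ankle distance at that limb's toe off (positive: foot behind).
    """
    rel = ankle.position - hip.position
    leading = rel[events.heel_strikes]
    trailing = -rel[events.toe_offs]
    return leading, trailing


def placement_asymmetry(placement_long, placement_short) -> float:
    """Mean long-side minus short-side placement difference (m)."""
    long = np.asarray(placement_long, dtype=float)
    short = np.asarray(placement_short, dtype=float)
    n = min(long.size, short.size)
    return float(long[:n].mean() - short[:n].mean())
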