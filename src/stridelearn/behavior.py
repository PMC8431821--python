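"""Stride-level behavioral measures and the participant data container.

All measures operate on step-asymmetry-index (SAI, percent) series aligned
with a :class:`~stridelearn.schedules.TargetSchedule`. The study's analysis
flow is: baseline-correct each session, summarise the learning phase (mean
and SD of SAI), and characterise the use-dependent aftereffect during the
no-feedback washout through three windows — initial bias (washout strides
1–5), early washout (strides 6–30), and the washout rate (one minus the
AR(1) slope over the first 50 washout strides).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .schedules import TargetSchedule

__all__ = [
    "Session",
    "ParticipantDataset",
    "baseline_correct",
    "learning_stats",
    "washout_epochs",
    "washout_rate",
    "target_accuracy",
    "accuracy_outliers",
    "hit_rate",
]


@dataclass(frozen=True)
class Session:
    """One walking session: a schedule and the observed SAI series."""

    schedule: TargetSchedule
    sai: np.ndarray

    def __post_init__(self):
        sai = np.asarray(self.sai, dtype=float)
        if sai.shape != (self.schedule.n_strides,):
            raise ValueError(
                f"SAI series length {sai.size} does not match schedule length "
                f"{self.schedule.n_strides}"
            )
        object.__setattr__(self, "sai", sai)

    @property
    def condition(self) -> str:
        return self.schedule.condition


@dataclass(frozen=True)
class ParticipantDataset:
    """Observed or synthetic SAI series for one participant's sessions.

    Sessions are stored in the order the participant completed them; the
    full protocol has three sessions with distinct conditions, but partial
    datasets (e.g., single-condition simulations) are allowed.
    """

    participant: str | int
    sessions: tuple[Session, ...]

    def __post_init__(self):
        sessions = tuple(self.sessions)
        if not sessions:
            raise ValueError("a dataset needs at least one session")
        conds = [s.condition for s in sessions]
        if len(set(conds)) != len(conds):
            raise ValueError(f"sessions must have distinct conditions, got {conds}")
        object.__setattr__(self, "sessions", sessions)

    def __iter__(self):
        return iter(self.sessions)

    def session(self, condition: str) -> Session:
        for s in self.sessions:
            if s.condition == condition:
                return s
        raise KeyError(f"no session with condition {condition!r}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(s.condition for s in self.sessions)

    @property
    def n_strides(self) -> int:
        return sum(s.schedule.n_strides for s in self.sessions)

    def corrected(self) -> "ParticipantDataset":
        """Baseline-corrected copy (per session)."""
        return ParticipantDataset(
            self.participant,
            tuple(
                Session(s.schedule, baseline_correct(s.sai, s.schedule)) for s in self.sessions
            ),
        )


def baseline_correct(series, schedule: TargetSchedule, n_last: int = 50) -> np.ndarray:
    """Subtract the mean SAI of the last ``n_last`` baseline strides.

    Idempotent up to floating point once the baseline tail mean is zero.
    """
    series = np.asarray(series, dtype=float)
    idx = np.flatnonzero(schedule.mask("baseline"))
    if idx.size == 0:
        raise ValueError("schedule has no baseline strides to correct against")
    tail = idx[-min(n_last, idx.size):]
    return series - series[tail].mean()


def learning_stats(dataset: ParticipantDataset, correct_baseline: bool = True) -> pd.DataFrame:
    """Mean and SD of SAI over all learning strides, one row per session."""
    rows = []
    for s in dataset:
        y = baseline_correct(s.sai, s.schedule) if correct_baseline else s.sai
        learn = y[s.schedule.mask("learning")]
        rows.append(
            {
                "participant": dataset.participant,
                "condition": s.condition,
                "learning_mean": learn.mean(),
                "learning_sd": learn.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def washout_epochs(series, schedule: TargetSchedule) -> tuple[float, float]:
    """(initial_bias, early_washout): mean SAI of washout strides 1–5 and 6–30."""
    series = np.asarray(series, dtype=float)
    w = series[schedule.mask("washout")]
    if w.size < 30:
        raise ValueError(f"need at least 30 washout strides, got {w.size}")
    return float(w[:5].mean()), float(w[5:30].mean())


def washout_rate(series, schedule: TargetSchedule, n: int = 50) -> float:
    """Per-stride unlearning rate: 1 minus the AR(1) slope of early washout.

    Ordinary least squares (with intercept) of SAI on stride ``k+1`` against
    SAI on stride ``k`` over the first ``n`` washout strides.
    """
    series = np.asarray(series, dtype=float)
    w = series[schedule.mask("washout")][:n]
    if w.size < 3:
        raise ValueError(f"need at least 3 washout strides, got {w.size}")
    x, y = w[:-1], w[1:]
    if np.ptp(x) == 0:
        raise ValueError("washout series is constant; AR(1) slope undefined")
    slope = sps.linregress(x, y).slope
    return 1.0 - slope


def target_accuracy(dataset: ParticipantDataset, correct_baseline: bool = True) -> float:
    """Mean absolute target error |target − SAI| over all learning strides."""
    errs = []
    for s in dataset:
        y = baseline_correct(s.sai, s.schedule) if correct_baseline else s.sai
        m = s.schedule.mask("learning")
        errs.append(np.abs(s.schedule.target[m] - y[m]))
    return float(np.concatenate(errs).mean())


def accuracy_outliers(cohort, z: float = 3.0) -> pd.DataFrame:
    """Flag participants whose target accuracy falls outside ``z`` SD of the cohort mean."""
    acc = np.array([target_accuracy(d) for d in cohort])
    mu, sd = acc.mean(), acc.std(ddof=1)
    return pd.DataFrame(
        {
            "participant": [d.participant for d in cohort],
            "target_accuracy": acc,
            "exclude": np.abs(acc - mu) > z * sd,
        }
    )


def hit_rate(dataset: ParticipantDataset, halfwidth: float = 2.0,
             correct_baseline: bool = True) -> float:
    """Proportion of learning strides within ``halfwidth`` %SAI of the target.

    The on-screen target lines span ±2 % step-length change from baseline for
    each leg; for targets displaced symmetrically off baseline this band maps
    to ±2 percentage points of SAI to first order, which is the default.
    """
    hits = total = 0
    for s in dataset:
        y = baseline_correct(s.sai, s.schedule) if correct_baseline else s.sai
        m = s.schedule.mask("learning")
        hits += int((np.abs(y[m] - s.schedule.target[m]) <= halfwidth).sum())
        total += int(m.sum())
    if total == 0:
        raise ValueError("dataset has no learning strides")
    return hits / total
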