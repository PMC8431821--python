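"""Per-session stride-by-stride target schedules.

A session of visually guided treadmill walking has three phases: a baseline
phase with no visual feedback (VF), a learning phase in which participants
aim their step lengths at targets expressed as a step asymmetry index
(SAI, in percent), and a no-feedback washout phase. Target consistency
during learning is the experimental manipulation:

* ``constant`` — every learning target is 22 %SAI;
* ``LV`` (low variability) — targets drawn from N(22, 5^2);
* ``HV`` (high variability) — targets drawn from U(5, 39).

For the variable conditions a drawn target is held for 1–5 strides (hold
length uniform on {1,...,5}, drawn independently of the target value); the
final hold may be truncated by the end of the learning phase. Baseline and
washout strides carry no VF and an effective target of 0 %SAI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CONDITIONS", "PHASES", "TargetSchedule", "make_schedule"]

CONDITIONS = ("constant", "LV", "HV")
PHASES = ("baseline", "learning", "washout")

#: Default phase lengths (strides): baseline / learning / washout.
DEFAULT_LENGTHS = (250, 500, 750)

#: Half-width of the on-screen target lines, in percent step-length change
#: from baseline. Metadata for hit classification only; does not alter targets.
TARGET_HALFWIDTH = 2.0

_HOLD_CHOICES = np.arange(1, 6)


@dataclass(frozen=True)
class TargetSchedule:
    """Stride-level structure of one walking session.

    Attributes
    ----------
    condition : str
        One of ``constant``, ``LV``, ``HV``.
    phase : np.ndarray of str
        Per-stride phase label (``baseline`` / ``learning`` / ``washout``).
    vf : np.ndarray of bool
        Whether visual feedback was shown on that stride.
    target : np.ndarray of float
        Per-stride target SAI in percent (0 outside the learning phase).
    draws : np.ndarray of float, optional
        The raw target values drawn at change points (LV/HV only; the LV
        normal draws are not clipped).
    """

    condition: str
    phase: np.ndarray
    vf: np.ndarray
    target: np.ndarray
    draws: np.ndarray | None = field(default=None, compare=False)
    target_halfwidth: float = TARGET_HALFWIDTH

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        phase = np.asarray(self.phase)
        vf = np.asarray(self.vf, dtype=bool)
        target = np.asarray(self.target, dtype=float)
        if not (phase.shape == vf.shape == target.shape):
            raise ValueError("phase, vf and target must have equal length")
        unknown = set(np.unique(phase)) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")
        off = phase != "learning"
        if vf[off].any():
            raise ValueError("baseline/washout strides must have vf=False")
        if (target[off] != 0).any():
            raise ValueError("baseline/washout strides must have target=0")
        if not vf[~off].all():
            raise ValueError("learning strides must have vf=True")
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "vf", vf)
        object.__setattr__(self, "target", target)

    def __len__(self) -> int:
        return self.phase.size

    @property
    def n_strides(self) -> int:
        return self.phase.size

    def mask(self, phase: str) -> np.ndarray:
        """Boolean mask of strides in ``phase``."""
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        return self.phase == phase


def _learning_targets(condition: str, n: int, rng: np.random.Generator):
    """Piecewise-constant learning targets and the raw change-point draws."""
    if condition == "constant":
        return np.full(n, 22.0), np.full(1 if n else 0, 22.0)
    values = np.empty(n)
    draws = []
    i = 0
    while i < n:
        if condition == "LV":
            v = rng.normal(22.0, 5.0)
        else:  # HV
            v = rng.uniform(5.0, 39.0)
        hold = int(rng.choice(_HOLD_CHOICES))
        draws.append(v)
        values[i : i + hold] = v  # final hold may be truncated
        i += hold
    return values, np.asarray(draws)


def make_schedule(
    condition: str,
    n_baseline: int = DEFAULT_LENGTHS[0],
    n_learning: int = DEFAULT_LENGTHS[1],
    n_washout: int = DEFAULT_LENGTHS[2],
    seed: int | None = None,
) -> TargetSchedule:
    """Construct a session's target schedule.

    Deterministic for a fixed ``seed``. Phase lengths default to the
    250 / 500 / 750 stride protocol.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    counts = (n_baseline, n_learning, n_washout)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError(f"phase lengths must be non-negative integers, got {counts}")
    n_baseline, n_learning, n_washout = (int(c) for c in counts)

    rng = np.random.default_rng(seed)
    targets, draws = _learning_targets(condition, n_learning, rng)

    phase = np.concatenate(
        [
            np.repeat("baseline", n_baseline),
            np.repeat("learning", n_learning),
            np.repeat("washout", n_washout),
        ]
    )
    vf = phase == "learning"
    target = np.zeros(phase.size)
    target[vf] = targets
    return TargetSchedule(condition=condition, phase=phase, vf=vf, target=target, draws=draws)
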