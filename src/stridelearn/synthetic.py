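"""Synthetic cohorts and marker sessions with known ground truth.

The cohort generator reproduces the study conditions: 18 participants, three
sessions each (baseline 250 / learning 500 / washout 750 strides), one
session per target-consistency condition with the condition order
counterbalanced across the six permutations, SAI dynamics produced by one of
the four learning models, and additive i.i.d. Gaussian stride-to-stride
motor noise (default SD 3.5 %SAI, matching the constant-condition learning
SD of ~3.5 observed empirically). Default generating parameters are the
bootstrapped group means; a jitter option instead draws each participant's
parameters uniformly within the reported 95% CIs.

The marker-session generator builds sagittal heel / fifth-metatarsal / hip /
ankle trajectories whose extrema (and hence detected gait events and step
lengths) are known exactly, as an end-to-end fixture for the kinematics
pipeline. Marker paths are smoothstep arcs between per-event extreme
positions, so velocity sign changes occur exactly at the ground-truth event
frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from ._rng import child_seed, substream
from .behavior import ParticipantDataset, Session
from .kinematics import GaitEvents, MarkerTrajectory
from .models import ABParams, ModABParams, ModSUParams, SUParams, simulate
from .schedules import CONDITIONS, DEFAULT_LENGTHS, make_schedule

__all__ = [
    "CohortSpec",
    "DEFAULT_PARAMS",
    "PARAM_CI",
    "generate_participant",
    "generate_cohort",
    "generate_marker_session",
]

#: Bootstrapped group-mean parameters (point estimates used as defaults).
DEFAULT_PARAMS = {
    "su": SUParams(A=0.99, C=0.46, F=5.0e-4, E=0.95),
    "ab": ABParams(beta=0.22, sigma2_lik=63.9),
    # Use-dependent retention is set to 0.99, the value implied by its 95% CI
    # [0.97, 1.0]; this reproduces the observed ~5-6 %SAI washout bias.
    "mod_su": ModSUParams(A=0.99, C=0.46, F=2.9e-3, E=0.99, gamma_LV=0.76, gamma_HV=0.53),
    "mod_ab": ModABParams(beta_vf=0.20, sigma2_vf=78.86, beta_novf=1.0e-3, sigma2_novf=2.05),
}

#: Reported 95% CIs per parameter, used by the jitter option.
PARAM_CI = {
    "su": {"A": (0.98, 0.99), "C": (0.38, 0.55), "F": (2.8e-4, 1.3e-3), "E": (0.77, 0.999)},
    "ab": {"beta": (0.17, 0.29), "sigma2_lik": (45.86, 78.54)},
    "mod_su": {
        "A": (0.97, 0.99),
        "C": (0.38, 0.55),
        "F": (3.6e-4, 1.3e-2),
        "E": (0.97, 0.999),
        "gamma_LV": (0.59, 0.87),
        "gamma_HV": (0.36, 0.69),
    },
    "mod_ab": {
        "beta_vf": (0.15, 0.28),
        "sigma2_vf": (62.78, 89.69),
        "beta_novf": (4.6e-4, 2.0e-3),
        "sigma2_novf": (0.74, 4.78),
    },
}

_ORDERS = tuple(permutations(CONDITIONS))


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description of a synthetic cohort."""

    n_participants: int = 18
    model: str = "mod_su"
    params: object | None = None  # point values; None -> DEFAULT_PARAMS[model]
    jitter: bool = False  # draw per-participant params within PARAM_CI
    noise_sd: float = 3.5  # %SAI, stride-to-stride motor noise
    lengths: tuple[int, int, int] = DEFAULT_LENGTHS
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.model not in DEFAULT_PARAMS:
            raise ValueError(f"unknown model {self.model!r}")

    def order(self, participant: int) -> tuple[str, ...]:
        """Condition order for a participant (permutations cycled evenly)."""
        return _ORDERS[participant % len(_ORDERS)]


def _participant_params(spec: CohortSpec, participant: int):
    if spec.params is not None and not spec.jitter:
        return spec.params
    base = spec.params if spec.params is not None else DEFAULT_PARAMS[spec.model]
    if not spec.jitter:
        return base
    rng = substream(spec.seed, "params", participant)
    ci = PARAM_CI[spec.model]
    draw = {name: rng.uniform(*ci[name]) for name in ci}
    if spec.model == "mod_su" and draw["gamma_HV"] >= draw["gamma_LV"]:
        draw["gamma_HV"] = draw["gamma_LV"] * rng.uniform(0.5, 0.99)
    if spec.model in ("su", "mod_su") and draw["F"] > draw["C"] / 5.0:
        draw["F"] = draw["C"] / 5.0 * rng.uniform(0.1, 0.99)
    return type(base)(**draw)


def generate_participant(spec: CohortSpec, participant: int) -> ParticipantDataset:
    """One synthetic participant: model dynamics plus motor noise, three sessions.

    Reproducible from (spec.seed, participant); with ``noise_sd=0`` the SAI
    series equal the pure model simulation.
    """
    params = _participant_params(spec, participant)
    noise_rng = substream(spec.seed, "noise", participant)
    sessions = []
    for cond in spec.order(participant):
        sched = make_schedule(
            cond, *spec.lengths, seed=child_seed(spec.seed, "schedule", participant, cond)
        )
        y = simulate(spec.model, params, sched)
        if spec.noise_sd > 0:
            y = y + noise_rng.normal(0.0, spec.noise_sd, sched.n_strides)
        sessions.append(Session(sched, y))
    return ParticipantDataset(f"P{participant:02d}", tuple(sessions))


def generate_cohort(spec: CohortSpec) -> list[ParticipantDataset]:
    """The full synthetic cohort, counterbalanced across condition orders."""
    return [generate_participant(spec, i) for i in range(spec.n_participants)]


def _smoothstep_path(knot_frames: np.ndarray, knot_values: np.ndarray, n_frames: int) -> np.ndarray:
    """C1 path through knots with zero velocity at each knot (held flat outside)."""
    pos = np.empty(n_frames)
    pos[: knot_frames[0] + 1] = knot_values[0]
    for (f0, f1), (v0, v1) in zip(
        zip(knot_frames[:-1], knot_frames[1:]), zip(knot_values[:-1], knot_values[1:])
    ):
        u = np.linspace(0.0, 1.0, f1 - f0 + 1)
        pos[f0 : f1 + 1] = v0 + (v1 - v0) * u**2 * (3 - 2 * u)
    pos[knot_frames[-1] :] = knot_values[-1]
    return pos


@dataclass(frozen=True)
class MarkerSession:
    """Synthetic marker set with ground truth for pipeline validation."""

    markers: dict  # name -> MarkerTrajectory (heel/met5/hip/ankle x L/R)
    events: dict  # side -> GaitEvents (ground truth frames)
    step_lengths: np.ndarray = field(repr=False)  # (n_strides, 2): left, right steps (m)

    @property
    def sai(self) -> np.ndarray:
        left, right = self.step_lengths.T
        long, short = np.maximum(left, right), np.minimum(left, right)
        return np.sign(left - right) * (long - short) / (long + short) * 100.0


def generate_marker_session(
    step_targets,
    stride_duration: float = 1.1,
    fs: float = 100.0,
    seed: int | None = None,
    noise_sd: float = 0.0,
    ankle_offset: float = -0.06,
) -> MarkerSession:
    """Synthetic sagittal marker trajectories realizing given step lengths.

    Parameters
    ----------
    step_targets : array (n_strides, 2)
        Desired (left, right) step lengths in metres, per stride.
    stride_duration : float
        Stride period in seconds (left heel strike to left heel strike).
    noise_sd : float
        Optional white marker noise (m) added to every trajectory.
    ankle_offset : float
        Constant sagittal ankle-minus-heel offset (m).

    Left heel strikes fall at integer multiples of the stride period, right
    heel strikes half a period later; fifth-metatarsal extrema lag the heel
    by 10% of the period so toe off follows the contralateral heel strike.
    """
    targets = np.atleast_2d(np.asarray(step_targets, dtype=float))
    if targets.shape[1] != 2 or (targets <= 0).any():
        raise ValueError("step_targets must be (n_strides, 2) positive lengths")
    n_strides = targets.shape[0]
    spf = stride_duration * fs  # samples per stride
    pad = int(round(0.5 * spf))
    n_frames = int(round((n_strides + 1.5) * spf)) + 1

    def frames(phase: float) -> np.ndarray:
        # one event per stride at the given phase (fraction of the cycle)
        return pad + np.round((np.arange(n_strides + 1) + phase) * spf).astype(int)

    sl_left, sl_right = targets.T
    # forward/backward extreme positions; symmetric split about the hip
    ext = np.empty(n_strides + 1)

    def extend(values):  # repeat the last stride's geometry for the closing half cycle
        ext[:-1] = values
        ext[-1] = values[-1]
        return ext.copy()

    fwd_left = extend(sl_left / 2.0)
    back_right = extend(-sl_left / 2.0)
    fwd_right = extend(sl_right / 2.0)
    back_left = extend(-sl_right / 2.0)

    lhs, rhs = frames(0.0), frames(0.5)
    met_lag = 0.1

    def leg_path(strike_frames, opp_frames, fwd, back):
        knots_f = np.sort(np.concatenate([strike_frames, opp_frames]))
        first_is_strike = strike_frames[0] < opp_frames[0]
        vals = np.empty(knots_f.size)
        vals[0 if first_is_strike else 1 :: 2] = fwd[: vals[0 if first_is_strike else 1 :: 2].size]
        vals[1 if first_is_strike else 0 :: 2] = back[: vals[1 if first_is_strike else 0 :: 2].size]
        return knots_f, vals

    kf_l, kv_l = leg_path(lhs, rhs, fwd_left, back_left)
    kf_r, kv_r = leg_path(rhs, lhs, fwd_right, back_right)

    rng = np.random.default_rng(seed)

    def traj(knot_frames, knot_values, shift=0):
        pos = _smoothstep_path(knot_frames + shift, knot_values, n_frames)
        if noise_sd > 0:
            pos = pos + rng.normal(0.0, noise_sd, n_frames)
        return MarkerTrajectory(pos, fs)

    lag = int(round(met_lag * spf))
    markers = {
        "heel_L": traj(kf_l, kv_l),
        "heel_R": traj(kf_r, kv_r),
        "met5_L": traj(kf_l, kv_l + ankle_offset / 2, shift=lag),
        "met5_R": traj(kf_r, kv_r + ankle_offset / 2, shift=lag),
        "ankle_L": traj(kf_l, kv_l + ankle_offset),
        "ankle_R": traj(kf_r, kv_r + ankle_offset),
        "hip_L": MarkerTrajectory(np.zeros(n_frames), fs),
        "hip_R": MarkerTrajectory(np.zeros(n_frames), fs),
    }
    events = {
        "L": GaitEvents(heel_strikes=lhs, toe_offs=rhs[:-1] + lag),
        "R": GaitEvents(heel_strikes=rhs, toe_offs=lhs[1:] + lag),
    }
    return MarkerSession(markers=markers, events=events, step_lengths=targets)
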