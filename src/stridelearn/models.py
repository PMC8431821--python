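"""Forward simulation of the four learning models.

Two competing accounts of locomotor use-dependent learning, plus a modified
variant of each, all producing noiseless per-stride SAI predictions on a
:class:`~stridelearn.schedules.TargetSchedule`.

Strategy + Use-Dependent (S+U)
    Motor output is the sum of a fast, voluntary strategic process ``s``
    and a slow use-dependent bias ``w``::

        x_n = s_n + w_n
        e_n = t_n - x_n
        s_{n+1} = A s_n + C e_n   (on strides with visual feedback; else 0)
        w_{n+1} = E w_n + gamma * F x_n

    with retention factors ``A``, ``E`` in (0, 1), correction rate ``C`` in
    (0, 1), use-dependent rate ``F`` > 0 constrained to ``C >= 5 F`` (strategy
    must learn at least five times faster), and a gain ``gamma`` on the
    use-dependent rate (1 in the base model). The strategy is zero whenever
    feedback is absent, so washout output is pure use-dependent bias and
    decays by the factor ``E + gamma*F`` per stride.

Adaptive Bayesian (AB)
    Motor output is the maximum a posteriori (MAP) blend of an adaptive
    prior over target position, N(theta_bar, sigma2_prior), and a sensory
    likelihood centred on the current target ``theta`` (0 %SAI when no
    feedback is shown) with variance ``sigma2_lik``::

        x_n        = sigma2_lik/(sigma2_prior + sigma2_lik) * theta_bar
                     + sigma2_prior/(sigma2_prior + sigma2_lik) * theta
        theta_bar'   = (1 - beta) theta_bar + beta theta
        sigma2_prior' = (1 - beta) sigma2_prior + beta (theta_bar - theta)^2

    The prior is initialised at mean 0 with variance ``sigma2_lik`` and the
    prior variance is floored at a small positive value (a long run of
    constant targets otherwise drives it to exactly 0).

The modified S+U model replaces the single gain by condition-specific gains
(1 for constant, ``gamma_LV`` and ``gamma_HV`` with
``0 < gamma_HV < gamma_LV < 1``). The modified AB model switches
``(beta, sigma2_lik)`` between feedback and no-feedback strides; the prior
state carries over across the switch.

All simulators are deterministic. Within a session state persists across
phase boundaries; sessions (days apart) start from the zero/initial state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .schedules import TargetSchedule

__all__ = [
    "SUParams",
    "ABParams",
    "ModSUParams",
    "ModABParams",
    "simulate_su",
    "simulate_su_states",
    "simulate_ab",
    "simulate_ab_states",
    "simulate_modified_su",
    "simulate_modified_ab",
    "simulate",
    "map_estimate",
    "posterior_variance",
    "PRIOR_VARIANCE_FLOOR",
]

#: Lower bound applied to the adaptive prior variance each stride.
PRIOR_VARIANCE_FLOOR = 1e-6

#: Upper bound on the likelihood variance (sigma2_lik), in (%SAI)^2.
SIGMA2_MAX = 100.0


def _check_open(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo < value < hi):
        raise ValueError(f"{name}={value} outside the open interval ({lo}, {hi})")


@dataclass(frozen=True)
class SUParams:
    """Strategy + Use-Dependent parameters (4 free parameters).

    A: strategy retention; C: strategic correction rate; F: use-dependent
    learning rate; E: use-dependent retention. Constraint: ``C >= 5 F``.
    """

    A: float
    C: float
    F: float
    E: float

    def __post_init__(self):
        _check_open("A", self.A, 0.0, 1.0)
        _check_open("C", self.C, 0.0, 1.0)
        _check_open("E", self.E, 0.0, 1.0)
        if not self.F > 0:
            raise ValueError(f"F={self.F} must be positive")
        if not self.C >= 5.0 * self.F:
            raise ValueError(
                f"strategic rate C={self.C} must be at least 5x the use-dependent rate F={self.F}"
            )


@dataclass(frozen=True)
class ABParams:
    """Adaptive Bayesian parameters (2 free parameters).

    beta: prior learning rate in (0, 1); sigma2_lik: likelihood variance in
    (0, 100) (%SAI)^2.
    """

    beta: float
    sigma2_lik: float

    def __post_init__(self):
        _check_open("beta", self.beta, 0.0, 1.0)
        _check_open("sigma2_lik", self.sigma2_lik, 0.0, SIGMA2_MAX)


@dataclass(frozen=True)
class ModSUParams:
    """Modified S+U: condition-specific gains on the use-dependent rate.

    gamma for the constant condition is fixed at 1; the fitted gains must
    decrease ordinally: ``0 < gamma_HV < gamma_LV < 1``.
    """

    A: float
    C: float
    F: float
    E: float
    gamma_LV: float
    gamma_HV: float

    def __post_init__(self):
        SUParams(self.A, self.C, self.F, self.E)
        if not (0.0 < self.gamma_HV < self.gamma_LV < 1.0):
            raise ValueError(
                f"gains must satisfy 0 < gamma_HV ({self.gamma_HV}) < gamma_LV ({self.gamma_LV}) < 1"
            )

    @property
    def su(self) -> SUParams:
        return SUParams(self.A, self.C, self.F, self.E)

    def gamma(self, condition: str) -> float:
        return {"constant": 1.0, "LV": self.gamma_LV, "HV": self.gamma_HV}[condition]


@dataclass(frozen=True)
class ModABParams:
    """Modified AB: separate (beta, sigma2_lik) with and without feedback."""

    beta_vf: float
    sigma2_vf: float
    beta_novf: float
    sigma2_novf: float

    def __post_init__(self):
        ABParams(self.beta_vf, self.sigma2_vf)
        ABParams(self.beta_novf, self.sigma2_novf)


@njit(cache=False)
def _su_kernel_state(target, vf, A, C, F, E, gamma):  # pragma: no cover - jitted
    n = target.size
    x = np.empty(n)
    s_arr = np.empty(n)
    w_arr = np.empty(n)
    s = 0.0
    w = 0.0
    for i in range(n):
        s_arr[i] = s
        w_arr[i] = w
        xi = s + w
        x[i] = xi
        e = target[i] - xi
        if i + 1 < n and vf[i + 1]:
            s = A * s + C * e
        else:
            s = 0.0
        w = E * w + gamma * F * xi
    return x, s_arr, w_arr


@njit(cache=False)
def _su_kernel(target, vf, A, C, F, E, gamma):  # pragma: no cover - jitted
    n = target.size
    x = np.empty(n)
    s = 0.0
    w = 0.0
    for i in range(n):
        xi = s + w
        x[i] = xi
        e = target[i] - xi
        if i + 1 < n and vf[i + 1]:
            s = A * s + C * e
        else:
            s = 0.0
        w = E * w + gamma * F * xi
    return x


@njit(cache=False)
def _ab_kernel_state(target, vf, beta_vf, s2_vf, beta_novf, s2_novf, floor):  # pragma: no cover
    n = target.size
    x = np.empty(n)
    tb_arr = np.empty(n)
    s2p_arr = np.empty(n)
    s2post_arr = np.empty(n)
    theta_bar = 0.0
    s2_prior = s2_vf if (n > 0 and vf[0]) else s2_novf
    for i in range(n):
        if vf[i]:
            beta = beta_vf
            s2_lik = s2_vf
            theta = target[i]
        else:
            beta = beta_novf
            s2_lik = s2_novf
            theta = 0.0
        tb_arr[i] = theta_bar
        s2p_arr[i] = s2_prior
        denom = s2_prior + s2_lik
        s2post_arr[i] = s2_lik * s2_prior / denom
        x[i] = (s2_lik / denom) * theta_bar + (s2_prior / denom) * theta
        d = theta_bar - theta
        s2_prior = (1.0 - beta) * s2_prior + beta * d * d
        if s2_prior < floor:
            s2_prior = floor
        theta_bar = (1.0 - beta) * theta_bar + beta * theta
    return x, tb_arr, s2p_arr, s2post_arr


@njit(cache=False)
def _ab_kernel(target, vf, beta_vf, s2_vf, beta_novf, s2_novf, floor):  # pragma: no cover
    n = target.size
    x = np.empty(n)
    theta_bar = 0.0
    s2_prior = s2_vf if (n > 0 and vf[0]) else s2_novf
    for i in range(n):
        if vf[i]:
            beta = beta_vf
            s2_lik = s2_vf
            theta = target[i]
        else:
            beta = beta_novf
            s2_lik = s2_novf
            theta = 0.0
        denom = s2_prior + s2_lik
        x[i] = (s2_lik / denom) * theta_bar + (s2_prior / denom) * theta
        d = theta_bar - theta
        s2_prior = (1.0 - beta) * s2_prior + beta * d * d
        if s2_prior < floor:
            s2_prior = floor
        theta_bar = (1.0 - beta) * theta_bar + beta * theta
    return x


def map_estimate(theta_bar, sigma2_prior, theta, sigma2_lik):
    """MAP blend of prior mean and sensory target (precision weighting)."""
    denom = np.asarray(sigma2_prior) + np.asarray(sigma2_lik)
    return (sigma2_lik / denom) * theta_bar + (sigma2_prior / denom) * theta


def posterior_variance(sigma2_lik, sigma2_prior):
    """Variance of the posterior of two Gaussian sources (harmonic combination)."""
    return sigma2_lik * sigma2_prior / (sigma2_lik + sigma2_prior)


def simulate_su(params: SUParams, schedule: TargetSchedule, gamma: float = 1.0) -> np.ndarray:
    """Noiseless S+U output series for one session."""
    if not isinstance(params, SUParams):
        params = SUParams(*params)
    if not gamma > 0:
        raise ValueError(f"gamma={gamma} must be positive")
    return _su_kernel(
        schedule.target, schedule.vf, params.A, params.C, params.F, params.E, float(gamma)
    )


def simulate_su_states(params: SUParams, schedule: TargetSchedule, gamma: float = 1.0) -> dict:
    """S+U simulation with per-stride state: keys ``x``, ``s``, ``w``."""
    if not isinstance(params, SUParams):
        params = SUParams(*params)
    if not gamma > 0:
        raise ValueError(f"gamma={gamma} must be positive")
    x, s, w = _su_kernel_state(
        schedule.target, schedule.vf, params.A, params.C, params.F, params.E, float(gamma)
    )
    return {"x": x, "s": s, "w": w}


def simulate_ab_states(params, schedule: TargetSchedule) -> dict:
    """AB (or modified-AB) simulation with per-stride state.

    Keys: ``x`` (MAP output), ``theta_bar`` (prior mean), ``sigma2_prior``,
    ``sigma2_post`` — each the value used to produce that stride's output.
    """
    if isinstance(params, ABParams):
        args = (params.beta, params.sigma2_lik, params.beta, params.sigma2_lik)
    elif isinstance(params, ModABParams):
        args = (params.beta_vf, params.sigma2_vf, params.beta_novf, params.sigma2_novf)
    else:
        raise TypeError("params must be ABParams or ModABParams")
    x, tb, s2p, s2post = _ab_kernel_state(
        schedule.target, schedule.vf, *args, PRIOR_VARIANCE_FLOOR
    )
    return {"x": x, "theta_bar": tb, "sigma2_prior": s2p, "sigma2_post": s2post}


def simulate_ab(params: ABParams, schedule: TargetSchedule) -> np.ndarray:
    """Noiseless AB output series for one session."""
    if not isinstance(params, ABParams):
        params = ABParams(*params)
    b, s2 = params.beta, params.sigma2_lik
    return _ab_kernel(schedule.target, schedule.vf, b, s2, b, s2, PRIOR_VARIANCE_FLOOR)


def simulate_modified_su(params: ModSUParams, schedule: TargetSchedule) -> np.ndarray:
    """Modified S+U: gain selected by the schedule's condition."""
    if not isinstance(params, ModSUParams):
        params = ModSUParams(*params)
    return simulate_su(params.su, schedule, gamma=params.gamma(schedule.condition))


def simulate_modified_ab(params: ModABParams, schedule: TargetSchedule) -> np.ndarray:
    """Modified AB: (beta, sigma2_lik) switched by the per-stride VF flag."""
    if not isinstance(params, ModABParams):
        params = ModABParams(*params)
    return _ab_kernel(
        schedule.target,
        schedule.vf,
        params.beta_vf,
        params.sigma2_vf,
        params.beta_novf,
        params.sigma2_novf,
        PRIOR_VARIANCE_FLOOR,
    )


_SIMULATORS = {
    "su": simulate_su,
    "ab": simulate_ab,
    "mod_su": simulate_modified_su,
    "mod_ab": simulate_modified_ab,
}

MODEL_LABELS = tuple(_SIMULATORS)

PARAM_TYPES = {
    "su": SUParams,
    "ab": ABParams,
    "mod_su": ModSUParams,
    "mod_ab": ModABParams,
}


def simulate(model: str, params, schedule: TargetSchedule) -> np.ndarray:
    """Dispatch to one of the four simulators by model label."""
    try:
        fn = _SIMULATORS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_LABELS}") from None
    return fn(params, schedule)
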