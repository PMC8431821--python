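"""Per-participant model fitting, selection, and recovery.

Each of the four learning models is fit to a participant's concatenated
session data (all strides, baseline included) by bounded nonlinear least
squares with Latin-hypercube multi-start. Ordinal constraints are enforced
by reparameterization:

* S+U: ``F = r * C / 5`` with ``r`` in (0, 1), so ``C >= 5 F`` always holds;
* modified S+U gains: ``gamma_LV = u``, ``gamma_HV = u * v`` with
  ``u, v`` in (0, 1), so ``gamma_HV < gamma_LV`` always holds.

Model selection uses the Gaussian profiled-variance criteria

    AIC = n ln(SSE / n) + 2 k        BIC = n ln(SSE / n) + k ln(n)

(no additive likelihood constant; only differences between models matter).
Model recovery simulates noisy data from each candidate with randomized
parameters, refits all candidates, and tabulates the win proportions in a
confusion matrix per condition and pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from ._rng import child_seed, substream
from .behavior import ParticipantDataset, Session
from .models import (
    ABParams,
    ModABParams,
    ModSUParams,
    PRIOR_VARIANCE_FLOOR,
    SIGMA2_MAX,
    SUParams,
    _ab_kernel,
    _su_kernel,
)
from .schedules import CONDITIONS, make_schedule

__all__ = [
    "FitResult",
    "ConfusionMatrix",
    "aic",
    "bic",
    "sse_objective",
    "fit_model",
    "fit_washout_only",
    "model_recovery",
    "bootstrap_ci",
    "free_parameter_count",
]

_EPS = 1e-6

# Free-parameter counts by model label.
_K = {"su": 4, "ab": 2, "mod_su": 6, "mod_ab": 4}

# Bounds of the reparameterized search space, per model.
_BOUNDS = {
    "su": ([_EPS] * 4, [1.0 - _EPS] * 4),  # A, C, r, E
    "ab": ([_EPS, 1e-3], [1.0 - _EPS, SIGMA2_MAX - 1e-3]),  # beta, sigma2
    "mod_su": ([_EPS] * 6, [1.0 - _EPS] * 6),  # A, C, r, E, u, v
    "mod_ab": (
        [_EPS, 1e-3, _EPS, 1e-3],
        [1.0 - _EPS, SIGMA2_MAX - 1e-3, 1.0 - _EPS, SIGMA2_MAX - 1e-3],
    ),
}


def free_parameter_count(model: str) -> int:
    """Number of free parameters (4 for S+U, 2 for AB, 6/4 for the modified variants)."""
    _check_model(model)
    return _K[model]


def _check_model(model: str) -> None:
    if model not in _K:
        raise ValueError(f"unknown model {model!r}; expected one of {tuple(_K)}")


def _decode(model: str, z: np.ndarray):
    """Reparameterized vector -> natural parameter dataclass."""
    if model == "su":
        A, C, r, E = z
        return SUParams(A, C, r * C / 5.0, E)
    if model == "ab":
        return ABParams(*z)
    if model == "mod_su":
        A, C, r, E, u, v = z
        return ModSUParams(A, C, r * C / 5.0, E, u, u * v)
    if model == "mod_ab":
        return ModABParams(*z)
    _check_model(model)


def _encode(model: str, p) -> np.ndarray:
    """Natural parameters -> reparameterized vector."""
    if model == "su":
        return np.array([p.A, p.C, 5.0 * p.F / p.C, p.E])
    if model == "ab":
        return np.array([p.beta, p.sigma2_lik])
    if model == "mod_su":
        return np.array(
            [p.A, p.C, 5.0 * p.F / p.C, p.E, p.gamma_LV, p.gamma_HV / p.gamma_LV]
        )
    if model == "mod_ab":
        return np.array([p.beta_vf, p.sigma2_vf, p.beta_novf, p.sigma2_novf])
    _check_model(model)


def _coerce_params(model: str, params):
    from .models import PARAM_TYPES

    cls = PARAM_TYPES[model]
    return params if isinstance(params, cls) else cls(*np.atleast_1d(params))


def _predict_z(model: str, z: np.ndarray, sessions) -> np.ndarray:
    """Concatenated noiseless prediction, decoding directly to the jitted kernels."""
    out = []
    if model == "su":
        A, C, r, E = z
        F = r * C / 5.0
        for s in sessions:
            out.append(_su_kernel(s.schedule.target, s.schedule.vf, A, C, F, E, 1.0))
    elif model == "mod_su":
        A, C, r, E, u, v = z
        F = r * C / 5.0
        gammas = {"constant": 1.0, "LV": u, "HV": u * v}
        for s in sessions:
            g = gammas[s.schedule.condition]
            out.append(_su_kernel(s.schedule.target, s.schedule.vf, A, C, F, E, g))
    elif model == "ab":
        b, s2 = z
        for s in sessions:
            out.append(
                _ab_kernel(s.schedule.target, s.schedule.vf, b, s2, b, s2, PRIOR_VARIANCE_FLOOR)
            )
    elif model == "mod_ab":
        bv, s2v, bn, s2n = z
        for s in sessions:
            out.append(
                _ab_kernel(s.schedule.target, s.schedule.vf, bv, s2v, bn, s2n, PRIOR_VARIANCE_FLOOR)
            )
    else:
        _check_model(model)
    return np.concatenate(out)


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters and goodness of fit for one participant x model."""

    model: str
    params: object
    sse: float
    n: int
    k: int
    aic: float
    bic: float
    r2: float
    participant: str | int | None = None
    phases: tuple[str, ...] = ("baseline", "learning", "washout")

    def params_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in vars(self.params).items()}

    def to_row(self) -> dict:
        row = {"participant": self.participant, "model": self.model}
        row.update(self.params_dict())
        row.update(sse=self.sse, n=self.n, k=self.k, aic=self.aic, bic=self.bic, r2=self.r2)
        return row


def aic(sse: float, n: int, k: int) -> float:
    """Gaussian profiled-variance Akaike criterion: n ln(SSE/n) + 2k."""
    if not sse > 0:
        raise ValueError(f"sse={sse} must be positive")
    if not n > k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    return n * math.log(sse / n) + 2 * k


def bic(sse: float, n: int, k: int) -> float:
    """Gaussian profiled-variance Bayesian criterion: n ln(SSE/n) + k ln(n)."""
    if not sse > 0:
        raise ValueError(f"sse={sse} must be positive")
    if not n > k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    return n * math.log(sse / n) + k * math.log(n)


def _safe_ic(fn, sse, n, k) -> float:
    return fn(sse, n, k) if sse > 0 else float("-inf")


def _observed(dataset: ParticipantDataset) -> np.ndarray:
    return np.concatenate([s.sai for s in dataset.sessions])


def sse_objective(model: str, params, dataset: ParticipantDataset) -> float:
    """Sum of squared residuals between the model prediction and observed SAI.

    All strides of all sessions are included (baseline too). Parameters
    outside their bounds are rejected with ``ValueError`` (the optimizer
    itself searches a reparameterized box and never proposes them).
    """
    p = _coerce_params(model, params)  # validates bounds
    z = _encode(model, p)
    resid = _predict_z(model, z, dataset.sessions) - _observed(dataset)
    return float(resid @ resid)


def _start_points(model: str, n_restarts: int, seed: int) -> np.ndarray:
    lo, hi = (np.asarray(b, dtype=float) for b in _BOUNDS[model])
    sampler = qmc.LatinHypercube(d=lo.size, seed=seed)
    u = sampler.random(n_restarts)
    margin = 0.02 * (hi - lo)
    return lo + margin + u * (hi - lo - 2 * margin)


def fit_model(
    model: str,
    dataset: ParticipantDataset,
    n_restarts: int = 20,
    seed: int = 0,
    xtol: float = 1e-12,
) -> FitResult:
    """Best-of-restarts bounded least-squares fit of ``model`` to ``dataset``.

    Deterministic for a fixed seed. Raises ``RuntimeError`` if every restart
    fails (does not occur in practice on finite data).
    """
    _check_model(model)
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    y = _observed(dataset)
    sessions = dataset.sessions

    def resid(z):
        return _predict_z(model, z, sessions) - y

    lo, hi = _BOUNDS[model]
    starts = _start_points(model, n_restarts, seed)
    best = None
    failures = []
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=xtol)
        except Exception as exc:  # optimizer failure on this start
            failures.append(exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed; last error: {failures[-1]}")

    sse = float(2.0 * best.cost)
    n, k = y.size, _K[model]
    tss = float(((y - y.mean()) ** 2).sum())
    return FitResult(
        model=model,
        params=_decode(model, best.x),
        sse=sse,
        n=n,
        k=k,
        aic=_safe_ic(aic, sse, n, k),
        bic=_safe_ic(bic, sse, n, k),
        r2=1.0 - sse / tss if tss > 0 else float("-inf"),
        participant=dataset.participant,
    )


def fit_washout_only(
    fit: FitResult, dataset: ParticipantDataset, phases: tuple[str, ...] = ("washout",)
) -> FitResult:
    """Re-score an existing fit on a subset of phases (default: washout only).

    The already-fitted parameters are kept; residuals are restricted to the
    selected strides and the criteria recomputed with the same ``k``.
    """
    z = _encode(fit.model, fit.params)
    pred = _predict_z(fit.model, z, dataset.sessions)
    y = _observed(dataset)
    mask = np.concatenate(
        [np.isin(s.schedule.phase, phases) for s in dataset.sessions]
    )
    if not mask.any():
        raise ValueError(f"no strides in phases {phases}")
    r = pred[mask] - y[mask]
    sse = float(r @ r)
    n, k = int(mask.sum()), fit.k
    ym = y[mask]
    tss = float(((ym - ym.mean()) ** 2).sum())
    return FitResult(
        model=fit.model,
        params=fit.params,
        sse=sse,
        n=n,
        k=k,
        aic=_safe_ic(aic, sse, n, k),
        bic=_safe_ic(bic, sse, n, k),
        r2=1.0 - sse / tss if tss > 0 else float("-inf"),
        participant=fit.participant,
        phases=tuple(phases),
    )


def _random_params(model: str, rng: np.random.Generator):
    """Uniform draw within each parameter's bounds (reparameterized space)."""
    lo, hi = (np.asarray(b, dtype=float) for b in _BOUNDS[model])
    return _decode(model, lo + rng.uniform(size=lo.size) * (hi - lo))


@dataclass
class ConfusionMatrix:
    """Model-recovery win proportions, per condition and pooled.

    ``matrix(condition, criterion)`` returns a DataFrame whose rows are the
    generating models and columns the winning (best-criterion) models; rows
    sum to 1 over completed fits.
    """

    models: tuple[str, str]
    conditions: tuple[str, ...]
    counts_aic: dict = field(repr=False)
    counts_bic: dict = field(repr=False)
    n_failed: int = 0

    def matrix(self, condition: str = "combined", criterion: str = "aic") -> pd.DataFrame:
        counts = {"aic": self.counts_aic, "bic": self.counts_bic}[criterion]
        if condition == "combined":
            m = sum(counts[c] for c in self.conditions)
        else:
            m = counts[condition]
        m = np.asarray(m, dtype=float)
        return pd.DataFrame(
            m / m.sum(axis=1, keepdims=True), index=self.models, columns=self.models
        )

    def diagonal_min(self, criterion: str = "aic") -> float:
        """Smallest diagonal entry over all per-condition and combined matrices."""
        vals = [
            np.diag(self.matrix(c, criterion).to_numpy()).min()
            for c in (*self.conditions, "combined")
        ]
        return float(min(vals))

    def discriminability(self, criterion: str = "aic") -> float:
        """Mean diagonal minus mean off-diagonal of the combined matrix."""
        m = self.matrix("combined", criterion).to_numpy()
        return float(np.diag(m).mean() - m[~np.eye(2, dtype=bool)].mean())


def model_recovery(
    models: tuple[str, str] = ("su", "ab"),
    n_per_condition: int = 100,
    seed: int = 0,
    noise_sd: float = 3.5,
    n_restarts: int = 6,
    conditions: tuple[str, ...] = CONDITIONS,
    lengths: tuple[int, int, int] = (250, 500, 750),
) -> ConfusionMatrix:
    """Simulate-and-refit confusion matrices for a pair of models.

    For each condition and each generating model, ``n_per_condition``
    single-session datasets are simulated with parameters drawn uniformly
    within their bounds plus i.i.d. Gaussian motor noise, then fit by both
    models; the winner is the lower criterion. AIC and BIC tallies are kept
    from the same fits.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    counts_aic = {c: np.zeros((2, 2), dtype=int) for c in conditions}
    counts_bic = {c: np.zeros((2, 2), dtype=int) for c in conditions}
    n_failed = 0
    from .models import simulate

    for cond in conditions:
        for gi, gen in enumerate(models):
            rng = substream(seed, "recovery", cond, gen)
            for rep in range(n_per_condition):
                sched = make_schedule(
                    cond, *lengths, seed=child_seed(seed, "recovery-sched", cond, gen, rep)
                )
                truth = _random_params(gen, rng)
                y = simulate(gen, truth, sched) + rng.normal(0.0, noise_sd, sched.n_strides)
                ds = ParticipantDataset(f"{gen}-{cond}-{rep}", (Session(sched, y),))
                try:
                    fits = [
                        fit_model(
                            m,
                            ds,
                            n_restarts=n_restarts,
                            seed=child_seed(seed, "recovery-fit", cond, gen, rep, m),
                        )
                        for m in models
                    ]
                except RuntimeError:
                    n_failed += 1
                    continue
                counts_aic[cond][gi, int(np.argmin([f.aic for f in fits]))] += 1
                counts_bic[cond][gi, int(np.argmin([f.bic for f in fits]))] += 1
    return ConfusionMatrix(
        models=tuple(models),
        conditions=tuple(conditions),
        counts_aic=counts_aic,
        counts_bic=counts_bic,
        n_failed=n_failed,
    )


def bootstrap_ci(
    params_table: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Bootstrap mean and 95% percentile CI of per-participant parameters.

    Participants (rows) are resampled with replacement ``n_boot`` times; for
    each parameter column the mean of the bootstrap sample means and the
    empirical 2.5th / 97.5th percentiles are reported.
    """
    rng = substream(seed, "bootstrap")
    values = params_table.to_numpy(dtype=float)
    n = values.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = values[idx].mean(axis=1)  # (n_boot, n_params)
    lo, hi = np.percentile(boot_means, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"mean": boot_means.mean(axis=0), "ci_low": lo, "ci_high": hi},
        index=params_table.columns,
    )
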