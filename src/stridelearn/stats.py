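"""The study's inferential battery.

Cohort-level condition effects are tested with one-way repeated-measures
ANOVA (partial eta squared as effect size) followed by Bonferroni-corrected
paired t tests with Cohen's d_z. Absence of condition effects is assessed
with the TOST equivalence procedure at d_z bounds of ±0.3. Whole-washout
condition differences use a cluster-based permutation test on 3-stride bins.
A noncentral-t power routine reproduces the a priori sample-size
calculation, and Shapiro-Wilk / Levene checks cover the parametric
assumptions.

Cohort tables are wide DataFrames: one row per participant, one column per
condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from ._rng import substream

__all__ = [
    "RMAnovaResult",
    "TostResult",
    "ClusterPermutationResult",
    "SlopeTestResult",
    "rm_anova",
    "pairwise_bonferroni",
    "tost",
    "cluster_permutation",
    "slope_test",
    "required_sample_size",
    "normality_and_variance_checks",
]


def _as_wide(table: pd.DataFrame) -> pd.DataFrame:
    table = pd.DataFrame(table)
    if table.isna().any().any():
        raise ValueError("cohort table must be complete (no missing cells)")
    return table


@dataclass(frozen=True)
class RMAnovaResult:
    """One-way within-subject ANOVA decomposition.

    ``df_error`` follows the standard (n-1)(k-1) convention; some reports
    instead print participants-1, provided here as ``df_error_subjects`` for
    comparison. The F statistic and p value use the standard convention.
    """

    F: float
    df_effect: int
    df_error: int
    df_error_subjects: int
    p: float
    eta_p2: float
    ss_effect: float
    ss_error: float


def rm_anova(table: pd.DataFrame) -> RMAnovaResult:
    """Repeated-measures ANOVA on a participants x conditions table."""
    table = _as_wide(table)
    n, k = table.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    long = table.reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="y"
    )
    with np.errstate(invalid="ignore"):
        res = pg.rm_anova(
            data=long, dv="y", within="condition", subject="subject",
            detailed=True, effsize="np2",
        )
    effect = res.loc[res["Source"] == "condition"].iloc[0]
    error = res.loc[res["Source"] == "Error"].iloc[0]
    if float(effect["SS"]) == 0.0:  # degenerate: no condition variation at all
        F, p, np2 = 0.0, 1.0, 0.0
    else:
        p_col = "p_unc" if "p_unc" in res.columns else "p-unc"
        F, p, np2 = float(effect["F"]), float(effect[p_col]), float(effect["np2"])
    return RMAnovaResult(
        F=F,
        df_effect=int(effect["DF"]),
        df_error=int(error["DF"]),
        df_error_subjects=n - 1,
        p=p,
        eta_p2=np2,
        ss_effect=float(effect["SS"]),
        ss_error=float(error["SS"]),
    )


def cohen_dz(differences) -> float:
    """Paired effect size: mean of differences over their SD."""
    d = np.asarray(differences, dtype=float)
    sd = d.std(ddof=1)
    return float(d.mean() / sd) if sd > 0 else 0.0


def pairwise_bonferroni(table: pd.DataFrame) -> pd.DataFrame:
    """All pairwise paired t tests with Bonferroni correction and Cohen's d_z."""
    table = _as_wide(table)
    pairs = list(combinations(table.columns, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = table[a].to_numpy() - table[b].to_numpy()
        if np.ptp(diff) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(table[a], table[b])
        rows.append(
            {
                "A": a,
                "B": b,
                "t": float(t),
                "df": len(table) - 1,
                "p_raw": float(p),
                "p_bonf": min(1.0, m * float(p)),
                "dz": cohen_dz(diff),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TostResult:
    """Two one-sided tests against symmetric d_z equivalence bounds."""

    t_lower: float
    p_lower: float
    t_upper: float
    p_upper: float
    bound_dz: float
    bound_raw: float
    equivalent: bool

    @property
    def p(self) -> float:
        """The TOST p value: the larger of the two one-sided p values."""
        return max(self.p_lower, self.p_upper)


def tost(differences, bound_dz: float = 0.3, alpha: float = 0.05) -> TostResult:
    """Equivalence test on paired differences with bounds of ±``bound_dz`` SDs.

    Rejecting both one-sided nulls (effect <= -bound, effect >= +bound) at
    ``alpha`` declares statistical equivalence.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("differences are constant; equivalence test undefined")
    bound = bound_dz * sd
    se = sd / np.sqrt(n)
    df = n - 1
    t_lower = (d.mean() + bound) / se  # H0: effect <= -bound
    t_upper = (d.mean() - bound) / se  # H0: effect >= +bound
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    return TostResult(
        t_lower=float(t_lower),
        p_lower=p_lower,
        t_upper=float(t_upper),
        p_upper=p_upper,
        bound_dz=bound_dz,
        bound_raw=float(bound),
        equivalent=bool(max(p_lower, p_upper) < alpha),
    )


@dataclass(frozen=True)
class ClusterPermutationResult:
    mass: float
    p: float
    t_bins: np.ndarray
    significant: np.ndarray
    cluster: tuple[int, int] | None  # [start, stop) bin indices of the largest cluster


def _bin_means(x: np.ndarray, width: int) -> np.ndarray:
    n_bins = x.shape[1] // width
    return x[:, : n_bins * width].reshape(x.shape[0], n_bins, width).mean(axis=2)


def _paired_t(d: np.ndarray):
    """Columnwise paired t over participants (rows)."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def _max_cluster(t: np.ndarray, sig: np.ndarray):
    """Largest same-sign run of significant bins; returns (mass, (start, stop))."""
    best, best_span = 0.0, None
    mass, start, sign = 0.0, 0, 0.0
    for j in range(t.size):
        if sig[j]:
            sj = 1.0 if t[j] > 0 else -1.0
            if mass > 0 and sj == sign:
                mass += abs(t[j])
            else:
                mass, start, sign = abs(t[j]), j, sj
            if mass > best:
                best, best_span = mass, (start, j + 1)
        else:
            mass, sign = 0.0, 0.0
    return best, best_span


def _max_cluster_rows(t: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """Row-wise max cluster mass, vectorized over permutations."""
    n_perm, n_bins = t.shape
    best = np.zeros(n_perm)
    mass = np.zeros(n_perm)
    sign = np.zeros(n_perm)
    for j in range(n_bins):
        tj = t[:, j]
        sj = sig[:, j]
        s = np.sign(tj)
        cont = sj & (s == sign) & (mass > 0)
        mass = np.where(sj, np.where(cont, mass + np.abs(tj), np.abs(tj)), 0.0)
        sign = np.where(sj, s, 0.0)
        best = np.maximum(best, mass)
    return best


def cluster_permutation(
    series_a: np.ndarray,
    series_b: np.ndarray,
    bin_width: int = 3,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusterPermutationResult:
    """Cluster-based permutation test between two paired stride series.

    ``series_a`` and ``series_b`` are (participants x strides) arrays of the
    same shape (truncate both to the shortest washout first). Strides are
    averaged into consecutive ``bin_width``-stride bins; paired t tests are
    run per bin; the largest same-sign cluster of consecutively significant
    bins (p < ``alpha``) is summed (|t| mass) and compared with a null built
    by randomly swapping condition labels within participants.
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    b = np.atleast_2d(np.asarray(series_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"series must have equal shapes, got {a.shape} vs {b.shape}")
    n_part = a.shape[0]
    if n_part < 2:
        raise ValueError("need at least 2 participants")
    d = _bin_means(a, bin_width) - _bin_means(b, bin_width)
    n_bins = d.shape[1]
    if n_bins < 1:
        raise ValueError("series shorter than one bin")

    tcrit = sps.t.ppf(1 - alpha / 2, n_part - 1)
    t_obs = _paired_t(d)
    sig_obs = np.abs(t_obs) > tcrit
    mass_obs, span = _max_cluster(t_obs, sig_obs)

    rng = substream(seed, "cluster-permutation")
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_part))
    # Paired t under sign flips: means vary, sum of squares is flip-invariant.
    m = flips @ d / n_part
    ss = (d**2).sum(axis=0)
    var = (ss - n_part * m**2) / (n_part - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(var > 0, m / np.sqrt(var / n_part), 0.0)
    null_mass = _max_cluster_rows(t_null, np.abs(t_null) > tcrit)

    if mass_obs == 0:
        p = 1.0
    else:
        p = (1 + int((null_mass >= mass_obs).sum())) / (n_perm + 1)
    return ClusterPermutationResult(
        mass=float(mass_obs), p=float(p), t_bins=t_obs, significant=sig_obs, cluster=span
    )


@dataclass(frozen=True)
class SlopeTestResult:
    slopes: np.ndarray
    mean_slope: float
    t: float
    p: float
    ci: tuple[float, float]


def slope_test(x: pd.DataFrame, y: pd.DataFrame) -> SlopeTestResult:
    """Per-participant OLS slopes of y on x, tested against zero.

    ``x`` and ``y`` are participants x conditions tables (matching layout).
    Each participant contributes one slope (OLS with intercept across their
    conditions); the slopes are compared with 0 by a one-sample t test.
    """
    x = _as_wide(x)
    y = _as_wide(y)
    if x.shape != y.shape:
        raise ValueError("x and y tables must have the same shape")
    xv, yv = x.to_numpy(dtype=float), y.to_numpy(dtype=float)
    xc = xv - xv.mean(axis=1, keepdims=True)
    yc = yv - yv.mean(axis=1, keepdims=True)
    denom = (xc**2).sum(axis=1)
    if (denom == 0).any():
        raise ValueError("a participant has constant x across conditions; slope undefined")
    slopes = (xc * yc).sum(axis=1) / denom
    if np.ptp(slopes) == 0:
        t, p = 0.0 if slopes[0] == 0 else np.inf, 1.0 if slopes[0] == 0 else 0.0
    else:
        t, p = sps.ttest_1samp(slopes, 0.0)
    n = slopes.size
    se = slopes.std(ddof=1) / np.sqrt(n)
    half = sps.t.ppf(0.975, n - 1) * se
    m = slopes.mean()
    return SlopeTestResult(
        slopes=slopes,
        mean_slope=float(m),
        t=float(t),
        p=float(p),
        ci=(float(m - half), float(m + half)),
    )


def paired_t_power(n: int, d_z: float, alpha: float = 0.05) -> float:
    """Power of a two-tailed paired t test at effect size ``d_z``."""
    if n < 2:
        return 0.0
    df = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    nc = d_z * np.sqrt(n)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def required_sample_size(
    d_z: float, alpha: float = 0.05, power: float = 0.90, n_max: int = 10_000
) -> int:
    """Smallest n whose two-tailed paired t test reaches the target power."""
    if not d_z > 0:
        raise ValueError("d_z must be positive")
    for n in range(2, n_max + 1):
        if paired_t_power(n, d_z, alpha) >= power:
            return n
    raise ValueError(f"no n <= {n_max} reaches power {power} at d_z={d_z}")


def normality_and_variance_checks(table: pd.DataFrame) -> dict:
    """Shapiro-Wilk per condition and Levene's test across conditions."""
    table = _as_wide(table)
    if any(np.ptp(table[c].to_numpy()) == 0 for c in table.columns):
        raise ValueError("a condition has constant values; tests undefined")
    shapiro = {
        c: {"W": float(w), "p": float(p)}
        for c, (w, p) in ((c, sps.shapiro(table[c])) for c in table.columns)
    }
    w, p = sps.levene(*(table[c].to_numpy() for c in table.columns))
    return {"shapiro": shapiro, "levene": {"W": float(w), "p": float(p)}}
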