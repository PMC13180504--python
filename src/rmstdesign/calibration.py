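"""Critical-value calibration for the sculpted two-stage RMST design.

A two-stage futility design continues past the interim only when
D̂1(τ1) > m1 and R̂E1(τ1) > q1, and rejects the null at the final analysis
when additionally D̂2(τ2) > m2 and R̂E2(τ2) > q2 (all inequalities strict).
The sculpting thresholds q1, q2 are tied to the difference thresholds m1, m2
through the control function

    f(Ñ) = exp(−γ · Ñ / N),   γ > 0,

which fixes the conditional probabilities
P(R̂E1 > q1 | D̂1 > m1) = f(Ñ) and P(R̂E2 > q2 | D̂2 > m2) = f(N) under the
alternative.  Given Monte-Carlo moments of (D̂i, R̂Ei) under H1, each qi is
the corresponding conditional-normal quantile (truncated-bivariate-normal
moment formulas); (γ, m1, m2) are then grid-searched against the empirical
type-I-error and power computed on the simulated replicate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfcx, ndtri

from ._engine import TrialBatch, simulate_batch, stage_statistics
from .scenario import ScenarioSpec

__all__ = [
    "StageStats",
    "MomentSummary",
    "CriticalValues",
    "OperatingCharacteristics",
    "CalibrationResult",
    "control_f",
    "stage_moments",
    "conditional_moments",
    "q_from_m",
    "empirical_oc",
    "expected_sample_size",
    "calibrate",
    "simple_rmst_calibrate",
    "simulate_stage_stats",
    "stage_stats_from_batch",
]

# gamma enters the design only through f = exp(-gamma*N_frac), and the
# attainable type-I-error level is exponentially sensitive to gamma, so the
# default grid is log-spaced to cover every scale between "barely sculpted"
# (f near 1) and "heavily sculpted" designs.
DEFAULT_GAMMA_GRID = np.geomspace(0.01, 3.0, 48)
DEFAULT_M_GRID_SIZE = 81
_THETA_MAX = 37.0  # beyond this the normal tail underflows in double precision


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------
@dataclass
class StageStats:
    """Per-replicate stage statistics under one hypothesis."""

    d1: np.ndarray
    re1: np.ndarray
    d2: np.ndarray
    re2: np.ndarray
    hypothesis: str  # "H0" or "H1"
    tau1: np.ndarray | None = None
    tau2: np.ndarray | None = None

    @property
    def b_reps(self) -> int:
        return int(self.d1.shape[0])


@dataclass(frozen=True)
class MomentSummary:
    """Monte-Carlo means and 2x2 covariances of (D̂i, R̂Ei) per stage."""

    mean_d: tuple[float, float]
    mean_e: tuple[float, float]
    cov: tuple[np.ndarray, np.ndarray]

    def stage(self, i: int) -> tuple[float, float, float, float, float]:
        """(mu_e, sigma_e, mu_d, sigma_d, rho) of stage i in {1, 2}."""
        c = self.cov[i - 1]
        sigma_d = float(np.sqrt(c[0, 0]))
        sigma_e = float(np.sqrt(c[1, 1]))
        denom = sigma_d * sigma_e
        rho = float(c[0, 1] / denom) if denom > 0 else 0.0
        return self.mean_e[i - 1], sigma_e, self.mean_d[i - 1], sigma_d, rho


@dataclass(frozen=True)
class CriticalValues:
    m1: float
    q1: float
    m2: float
    q2: float
    gamma: float | None = None  # None for the simple (q=0) rule


@dataclass(frozen=True)
class OperatingCharacteristics:
    alpha: float
    power: float
    pet0: float
    pet1: float
    en0: float
    en1: float
    en_mean: float
    n_interim: int
    n_total: int


@dataclass
class CalibrationResult:
    found: bool
    critical_values: CriticalValues | None = None
    oc: OperatingCharacteristics | None = None
    n_feasible: int = 0
    selection_rule: str = "max_power"
    feasible_table: pd.DataFrame | None = field(default=None, repr=False)


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------
def control_f(n_interim, n_total, gamma) -> float | np.ndarray:
    """Adaptive probability threshold f(Ñ) = exp(−γ·Ñ/N)."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("gamma must be positive")
    n_interim = np.asarray(n_interim, dtype=float)
    if np.any(n_interim <= 0) or np.any(n_interim > n_total):
        raise ValueError("need 0 < n_interim <= n_total")
    out = np.exp(-gamma * n_interim / n_total)
    return float(out) if out.ndim == 0 else out


def stage_moments(stats_h1: StageStats) -> MomentSummary:
    """Monte-Carlo stage moments (1/B-normalized); H1 replicates only."""
    if stats_h1.hypothesis != "H1":
        raise ValueError("moments must be estimated from H1 replicates")
    if stats_h1.b_reps < 2:
        raise ValueError("need at least two replicates")
    covs, mean_d, mean_e = [], [], []
    for d, e in ((stats_h1.d1, stats_h1.re1), (stats_h1.d2, stats_h1.re2)):
        ok = np.isfinite(d) & np.isfinite(e)  # drop empty-interim sentinels
        d, e = d[ok], e[ok]
        x = np.stack([d, e])
        mean_d.append(float(d.mean()))
        mean_e.append(float(e.mean()))
        covs.append(np.cov(x, ddof=0))
    return MomentSummary(mean_d=tuple(mean_d), mean_e=tuple(mean_e), cov=tuple(covs))


def _inverse_mills(theta):
    """phi(theta)/(1 - Phi(theta)), numerically stable for all theta."""
    return np.sqrt(2.0 / np.pi) / erfcx(theta / np.sqrt(2.0))


def conditional_moments(mu_e, sigma_e, mu_d, sigma_d, rho, m):
    """Mean and variance of R̂E | D̂ > m under a bivariate normal.

    mean = μE + ρ σE h(θ),  var = (1−ρ²)σE² + ρ²σE²(1 + θ·h(θ) − h(θ)²),
    with θ = (m − μD)/σD and h the inverse Mills ratio φ/(1−Φ).
    """
    if sigma_e <= 0 or sigma_d <= 0:
        raise ValueError("sigma_e and sigma_d must be positive")
    if not np.all(np.abs(rho) <= 1):
        raise ValueError("|rho| must not exceed 1")
    theta = (np.asarray(m, dtype=float) - mu_d) / sigma_d
    if np.any(theta > _THETA_MAX):
        raise OverflowError(
            "truncation point so extreme that P(D > m) underflows"
        )
    h = _inverse_mills(theta)
    mean = mu_e + rho * sigma_e * h
    trunc = 1.0 + theta * h - h**2  # truncated-normal variance factor
    var = (1.0 - rho**2) * sigma_e**2 + rho**2 * sigma_e**2 * trunc
    return mean, np.maximum(var, 0.0)


def q_from_m(moments: MomentSummary, stage: int, m, target_prob):
    """Sculpting threshold q with P(R̂E > q | D̂ > m) = target_prob.

    Uses the normal approximation to the conditional law of R̂E given
    D̂ > m: q is its (1 − target_prob) quantile.
    """
    target_prob = np.asarray(target_prob, dtype=float)
    if np.any(target_prob <= 0) or np.any(target_prob >= 1):
        raise ValueError("target_prob must lie in (0, 1)")
    mu_e, sigma_e, mu_d, sigma_d, rho = moments.stage(stage)
    mean, var = conditional_moments(mu_e, sigma_e, mu_d, sigma_d, rho, m)
    return mean + ndtri(1.0 - target_prob) * np.sqrt(var)


def expected_sample_size(n_interim: int, n_total: int, pet: float) -> float:
    """EN = Ñ·PET + N·(1 − PET) for one hypothesis."""
    if not 0.0 <= pet <= 1.0:
        raise ValueError("PET must lie in [0, 1]")
    return n_interim * pet + n_total * (1.0 - pet)


def empirical_oc(
    stats_h0: StageStats,
    stats_h1: StageStats,
    cv: CriticalValues,
    n_interim: int,
    n_total: int,
) -> OperatingCharacteristics:
    """Empirical operating characteristics of a fixed decision rule."""
    if stats_h0.b_reps != stats_h1.b_reps:
        raise ValueError("H0 and H1 replicate counts must match")
    res = {}
    for tag, st in (("0", stats_h0), ("1", stats_h1)):
        go = (st.d1 > cv.m1) & (st.re1 > cv.q1)
        reject = go & (st.d2 > cv.m2) & (st.re2 > cv.q2)
        res["pet" + tag] = float(1.0 - go.mean())
        res["rej" + tag] = float(reject.mean())
    en0 = expected_sample_size(n_interim, n_total, res["pet0"])
    en1 = expected_sample_size(n_interim, n_total, res["pet1"])
    return OperatingCharacteristics(
        alpha=res["rej0"],
        power=res["rej1"],
        pet0=res["pet0"],
        pet1=res["pet1"],
        en0=en0,
        en1=en1,
        en_mean=0.5 * (en0 + en1),
        n_interim=int(n_interim),
        n_total=int(n_total),
    )


# --------------------------------------------------------------------------
# grid search
# --------------------------------------------------------------------------
def _m_grid(values_h0: np.ndarray, values_h1: np.ndarray, size: int) -> np.ndarray:
    """Data-adaptive threshold grid: pooled 1st–99th percentile range."""
    pooled = np.concatenate([values_h0, values_h1])
    return np.unique(np.quantile(pooled, np.linspace(0.01, 0.99, size)))


def _reject_matrix(go: np.ndarray, fin: np.ndarray) -> np.ndarray:
    b = go.shape[1]
    return go.astype(np.float32) @ fin.astype(np.float32).T / np.float32(b)


@dataclass
class _Candidate:
    key: tuple
    cv: CriticalValues
    alpha: float
    power: float
    pet0: float
    pet1: float


def _selection_key(rule: str, power: float, target: float, pet0: float, q2: float):
    # lexicographic maximization; ties broken by larger PET0, then larger q2
    if rule == "max_power":
        return (power, pet0, q2)
    if rule == "closest_power":
        # prefer the smallest power at or above target; below target, the largest
        if power >= target:
            return (1, -power, pet0, q2)
        return (0, power, pet0, q2)
    raise ValueError(f"unknown selection rule {rule!r}")


def _search_grids(
    stats_h0: StageStats,
    stats_h1: StageStats,
    alpha0: float,
    target_power: float,
    rule: str,
    gamma_grid,
    m1_grid,
    m2_grid,
    q_builder,
    collect_table: bool = False,
):
    """Shared grid-search core for sculpted and simple rules.

    ``q_builder(gamma) -> (q1_vec, q2_vec)`` maps a control-function
    parameter to sculpting thresholds aligned with the m-grids.
    """
    best: _Candidate | None = None
    n_feasible = 0
    rows = [] if collect_table else None
    # the D-threshold half of every pass condition is gamma-free: hoist it
    d1m_h0 = stats_h0.d1[None, :] > np.asarray(m1_grid)[:, None]
    d2m_h0 = stats_h0.d2[None, :] > np.asarray(m2_grid)[:, None]
    d1m_h1 = stats_h1.d1[None, :] > np.asarray(m1_grid)[:, None]
    d2m_h1 = stats_h1.d2[None, :] > np.asarray(m2_grid)[:, None]
    for gamma in gamma_grid:
        q1_vec, q2_vec = q_builder(gamma)
        go0 = d1m_h0 & (stats_h0.re1[None, :] > np.asarray(q1_vec)[:, None])
        fin0 = d2m_h0 & (stats_h0.re2[None, :] > np.asarray(q2_vec)[:, None])
        go1 = d1m_h1 & (stats_h1.re1[None, :] > np.asarray(q1_vec)[:, None])
        fin1 = d2m_h1 & (stats_h1.re2[None, :] > np.asarray(q2_vec)[:, None])
        alpha_mat = _reject_matrix(go0, fin0)
        feasible = alpha_mat <= alpha0 + 1e-12
        if not feasible.any():
            continue
        power_mat = _reject_matrix(go1, fin1)
        pet0_row = 1.0 - go0.mean(axis=1)
        pet1_row = 1.0 - go1.mean(axis=1)
        ii, jj = np.nonzero(feasible)
        n_feasible += ii.size
        if collect_table:
            rows.append(
                pd.DataFrame(
                    {
                        "gamma": np.nan if gamma is None else gamma,
                        "m1": m1_grid[ii],
                        "q1": np.asarray(q1_vec)[ii],
                        "m2": m2_grid[jj],
                        "q2": np.asarray(q2_vec)[jj],
                        "alphaE": alpha_mat[ii, jj],
                        "powerE": power_mat[ii, jj],
                        "PET0": pet0_row[ii],
                        "PET1": pet1_row[ii],
                    }
                )
            )
        # vectorized lexicographic argmax over this gamma's feasible combos
        pv = power_mat[ii, jj]
        petv = pet0_row[ii]
        q2v = np.asarray(q2_vec)[jj]
        if rule == "max_power":
            pick = np.lexsort((q2v, petv, pv))[-1]
        else:  # closest_power
            above = pv >= target_power
            pick = np.lexsort(
                (q2v, petv, np.where(above, -pv, pv), above.astype(int))
            )[-1]
        i, j = int(ii[pick]), int(jj[pick])
        key = _selection_key(
            rule, float(power_mat[i, j]), target_power, float(pet0_row[i]), float(np.asarray(q2_vec)[j])
        )
        if best is None or key > best.key:
            best = _Candidate(
                key=key,
                cv=CriticalValues(
                    m1=float(m1_grid[i]),
                    q1=float(np.asarray(q1_vec)[i]),
                    m2=float(m2_grid[j]),
                    q2=float(np.asarray(q2_vec)[j]),
                    gamma=None if gamma is None else float(gamma),
                ),
                alpha=float(alpha_mat[i, j]),
                power=float(power_mat[i, j]),
                pet0=float(pet0_row[i]),
                pet1=float(pet1_row[i]),
            )
    table = pd.concat(rows, ignore_index=True) if rows else None
    return best, n_feasible, table


def _finalize(
    best, n_feasible, table, rule, stats_h0, stats_h1, n_interim, n_total
) -> CalibrationResult:
    if best is None:
        return CalibrationResult(found=False, selection_rule=rule, n_feasible=0)
    oc = empirical_oc(stats_h0, stats_h1, best.cv, n_interim, n_total)
    return CalibrationResult(
        found=True,
        critical_values=best.cv,
        oc=oc,
        n_feasible=n_feasible,
        selection_rule=rule,
        feasible_table=table,
    )


def calibrate(
    stats_h0: StageStats,
    stats_h1: StageStats,
    n_interim: int,
    n_total: int,
    alpha0: float,
    beta0: float = 0.2,
    *,
    selection_rule: str = "closest_power",
    gamma_grid=DEFAULT_GAMMA_GRID,
    m_grid_size: int = DEFAULT_M_GRID_SIZE,
    return_table: bool = False,
) -> CalibrationResult:
    """Calibrate the sculpted rule (m1, q1, m2, q2, γ) at fixed (Ñ, N).

    For every γ in the grid and every m in data-adaptive grids for the two
    stages, q1/q2 follow from the control-function constraints; combinations
    with empirical α ≤ α0 are feasible, and the selection rule picks either
    the empirical-power maximizer (``max_power``) or the feasible design
    whose power sits closest above 1−β0 (``closest_power``).  Returns a
    ``found=False`` result when no grid point is feasible.
    """
    if len(np.atleast_1d(gamma_grid)) == 0:
        raise ValueError("gamma grid must be non-empty")
    moments = stage_moments(stats_h1)
    m1_grid = _m_grid(stats_h0.d1, stats_h1.d1, m_grid_size)
    m2_grid = _m_grid(stats_h0.d2, stats_h1.d2, m_grid_size)

    def q_builder(gamma):
        f1 = control_f(n_interim, n_total, gamma)
        f2 = control_f(n_total, n_total, gamma)
        q1 = q_from_m(moments, 1, m1_grid, f1)
        q2 = q_from_m(moments, 2, m2_grid, f2)
        return q1, q2

    best, n_feasible, table = _search_grids(
        stats_h0,
        stats_h1,
        alpha0,
        1.0 - beta0,
        selection_rule,
        list(np.atleast_1d(gamma_grid)),
        m1_grid,
        m2_grid,
        q_builder,
        collect_table=return_table,
    )
    return _finalize(best, n_feasible, table, selection_rule, stats_h0, stats_h1, n_interim, n_total)


def simple_rmst_calibrate(
    stats_h0: StageStats,
    stats_h1: StageStats,
    n_interim: int,
    n_total: int,
    alpha0: float,
    beta0: float = 0.2,
    *,
    selection_rule: str = "closest_power",
    m_grid_size: int = DEFAULT_M_GRID_SIZE,
    return_table: bool = False,
) -> CalibrationResult:
    """Calibrate the simple RMST-difference rule: q1 = q2 = 0.

    The degenerate form of the sculpted rule; since RMST is non-negative the
    q-constraints are inert and only (m1, m2) are searched.
    """
    m1_grid = _m_grid(stats_h0.d1, stats_h1.d1, m_grid_size)
    m2_grid = _m_grid(stats_h0.d2, stats_h1.d2, m_grid_size)

    def q_builder(_gamma):
        return np.zeros_like(m1_grid), np.zeros_like(m2_grid)

    best, n_feasible, table = _search_grids(
        stats_h0,
        stats_h1,
        alpha0,
        1.0 - beta0,
        selection_rule,
        [None],
        m1_grid,
        m2_grid,
        q_builder,
        collect_table=return_table,
    )
    return _finalize(best, n_feasible, table, selection_rule, stats_h0, stats_h1, n_interim, n_total)


# --------------------------------------------------------------------------
# simulation glue
# --------------------------------------------------------------------------
def stage_stats_from_batch(batch: TrialBatch, n_interim: int, hypothesis: str) -> StageStats:
    """Stage statistics of an already-simulated latent batch."""
    arrays = stage_statistics(batch, n_interim)
    return StageStats(
        d1=arrays.d1,
        re1=arrays.re1,
        d2=arrays.d2,
        re2=arrays.re2,
        hypothesis=hypothesis,
        tau1=arrays.tau1,
        tau2=arrays.tau2,
    )


def hypothesis_rng(seed: int, n_total: int, hypothesis: str) -> np.random.Generator:
    """Deterministic substream per (root seed, design point, hypothesis)."""
    h = 0 if hypothesis == "H0" else 1
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(n_total), h]))


def simulate_stage_stats(
    spec: ScenarioSpec,
    n_interim: int,
    n_total: int,
    b_reps: int,
    seed: int,
    hypothesis: str = "H1",
) -> StageStats:
    """Simulate B paired interim/final replicates under one hypothesis."""
    world = spec.under_null() if hypothesis == "H0" else spec
    rng = hypothesis_rng(seed, n_total, hypothesis)
    batch = simulate_batch(world, n_total, b_reps, rng)
    return stage_stats_from_batch(batch, n_interim, hypothesis)
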