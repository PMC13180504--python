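"""Vectorized Kaplan–Meier / RMST engine for Monte-Carlo replicates.

Calibrating a two-stage design needs tens of thousands of product-limit fits
(B replicates x 2 hypotheses x 2 stages x 2 arms), so the estimator is
computed here as batched numpy array operations: every replicate occupies one
row of a (B, n) matrix and sorting/cumulative operations run along axis 1.
Simulated times are continuous, so within-row ties have probability zero and
the tie-handling of the scalar estimator in :mod:`rmstdesign.nonparametric`
is not needed on this path; agreement between the two routes is asserted in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenario import ScenarioSpec

__all__ = [
    "TrialBatch",
    "StageArrays",
    "simulate_batch",
    "batch_km_rmst",
    "stage_statistics",
    "single_stage_rejections",
]


@dataclass
class TrialBatch:
    """Latent state of B simulated trials (one row per replicate, per arm)."""

    spec: ScenarioSpec
    n_total: int
    entry: dict[str, np.ndarray]  # arm -> (B, N/2)
    surv: dict[str, np.ndarray]
    cens: dict[str, np.ndarray]
    _final_cache: dict = None  # final-stage results, keyed by tau2

    @property
    def b_reps(self) -> int:
        return self.entry["E"].shape[0]


@dataclass
class StageArrays:
    """Per-replicate stage statistics (D̂1, R̂E1, D̂2, R̂E2) of one batch."""

    d1: np.ndarray
    re1: np.ndarray
    d2: np.ndarray
    re2: np.ndarray
    tau1: np.ndarray  # data-dependent interim horizon per replicate
    tau2: np.ndarray  # final horizon actually used per replicate


def simulate_batch(
    spec: ScenarioSpec, n_total: int, b_reps: int, rng: np.random.Generator
) -> TrialBatch:
    """Draw latent (entry, survival, censoring) arrays for B trials."""
    if n_total <= 0 or n_total % 2 != 0:
        raise ValueError("n_total must be a positive even number (1:1 allocation)")
    a = spec.accrual_period_for(n_total)
    b = spec.min_followup
    half = n_total // 2
    entry, surv, cens = {}, {}, {}
    for arm, model in (("E", spec.experimental), ("C", spec.control)):
        entry[arm] = rng.uniform(0.0, a, size=(b_reps, half))
        # censoring is administrative: observation ends at the final analysis
        # a+b, so the censoring time after entry is a+b-E ~ U[b, a+b]
        cens[arm] = a + b - entry[arm]
        surv[arm] = model.draw(rng, (b_reps, half))
    return TrialBatch(spec=spec, n_total=n_total, entry=entry, surv=surv, cens=cens)


def _observe(entry, surv, cens, calendar_time: float):
    """Administratively censored view at a calendar time.

    Returns (time, event, included); excluded (not yet enrolled) subjects get
    time=+inf so they sort to the end and never enter risk sets (weight 0).
    """
    included = entry <= calendar_time
    admin = calendar_time - entry
    cutoff = np.minimum(cens, admin)
    time = np.where(included, np.minimum(surv, cutoff), np.inf)
    event = included & (surv <= cutoff)
    return time, event, included


def batch_km_rmst(time, event, included, tau, return_var: bool = False):
    """Row-wise Kaplan–Meier RMST (and Greenwood-type variance).

    ``time, event, included``: (B, n) arrays; ``tau``: scalar or (B,).
    Rows are assumed tie-free (continuous simulated data).  The survival curve
    is integrated on [0, tau]; tau must not exceed the largest included time
    of the row (callers enforce this through the data-dependent horizon).
    """
    time = np.asarray(time, dtype=float)
    tau = np.broadcast_to(np.asarray(tau, dtype=float), time.shape[:1]).copy()

    order = np.argsort(time, axis=1, kind="stable")
    t = np.take_along_axis(time, order, axis=1)
    d = np.take_along_axis(event & included, order, axis=1).astype(float)
    w = np.take_along_axis(included, order, axis=1).astype(float)

    n_incl = w.sum(axis=1, keepdims=True)
    at_risk = n_incl - (np.cumsum(w, axis=1) - w)  # Y_j just before t_j
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(d > 0, 1.0 - d / at_risk, 1.0)
    surv_after = np.cumprod(factor, axis=1)  # Ŝ(t_j+)

    tc = np.minimum(np.where(np.isfinite(t), t, np.inf), tau[:, None])
    tc = np.where(np.isfinite(tc), tc, tau[:, None])
    prev = np.concatenate([np.zeros_like(tc[:, :1]), tc[:, :-1]], axis=1)
    s_prev = np.concatenate([np.ones_like(surv_after[:, :1]), surv_after[:, :-1]], axis=1)
    seg = s_prev * (tc - prev)
    value = seg.sum(axis=1) + surv_after[:, -1] * (tau - tc[:, -1])

    if not return_var:
        return value, None

    cum_area = np.cumsum(seg, axis=1)  # ∫_0^{t_j} Ŝ
    area_right = value[:, None] - cum_area  # ∫_{t_j}^{tau} Ŝ
    contributes = (d > 0) & (t < tau[:, None]) & (at_risk - d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            contributes,
            area_right**2 * d / (at_risk * (at_risk - d)),
            0.0,
        )
    return value, terms.sum(axis=1)


def _arm_max_observed(time, included):
    masked = np.where(included, time, -np.inf)
    return masked.max(axis=1)


def _final_stage(batch: TrialBatch, tau2: float):
    """Final-analysis (R̂E, R̂C, τ2_eff); cached, shared by all interim sizes."""
    if batch._final_cache is None:
        batch._final_cache = {}
    key = float(tau2)
    if key not in batch._final_cache:
        spec = batch.spec
        t_final = spec.accrual_period_for(batch.n_total) + spec.min_followup
        obs = {
            arm: _observe(batch.entry[arm], batch.surv[arm], batch.cens[arm], t_final)
            for arm in ("E", "C")
        }
        tau2_eff = np.minimum(
            tau2,
            np.minimum(
                _arm_max_observed(obs["E"][0], obs["E"][2]),
                _arm_max_observed(obs["C"][0], obs["C"][2]),
            ),
        )
        re2, _ = batch_km_rmst(*obs["E"], tau2_eff)
        rc2, _ = batch_km_rmst(*obs["C"], tau2_eff)
        batch._final_cache[key] = (re2, rc2, tau2_eff)
    return batch._final_cache[key]


def stage_statistics(
    batch: TrialBatch, n_interim: int, tau2: float | None = None
) -> StageArrays:
    """Interim and final (D̂, R̂E) per replicate.

    The interim look happens at calendar time a*Ñ/N (the expected accrual
    time of the Ñ-th patient); its RMST horizon τ1 is the minimum over arms of
    the largest observed follow-up, per replicate.  The final analysis at
    calendar time a+b uses min(tau2, same data-dependent bound), so the
    estimate never extrapolates beyond the observed follow-up.
    """
    spec = batch.spec
    if not (0 < n_interim < batch.n_total):
        raise ValueError("n_interim must lie strictly between 0 and n_total")
    a = spec.accrual_period_for(batch.n_total)
    t_interim = a * n_interim / batch.n_total
    tau2 = spec.tau if tau2 is None else tau2

    obs = {
        arm: {
            "interim": _observe(batch.entry[arm], batch.surv[arm], batch.cens[arm], t_interim),
        }
        for arm in ("E", "C")
    }
    # replicates where an arm has no enrolled patient at the interim look are
    # rare (only possible for very small N_interim); they carry no evidence of
    # efficacy and are treated as futility stops below
    bad = ~(
        obs["E"]["interim"][2].any(axis=1) & obs["C"]["interim"][2].any(axis=1)
    )
    if bad.mean() > 0.01:
        raise ValueError(
            "more than 1% of replicates have an empty interim arm; "
            "the interim look is too early for this accrual pattern"
        )

    tau1 = np.minimum(
        _arm_max_observed(obs["E"]["interim"][0], obs["E"]["interim"][2]),
        _arm_max_observed(obs["C"]["interim"][0], obs["C"]["interim"][2]),
    )
    re2, rc2, tau2_eff = _final_stage(batch, tau2)

    re1, _ = batch_km_rmst(*obs["E"]["interim"], np.where(bad, 0.0, tau1))
    rc1, _ = batch_km_rmst(*obs["C"]["interim"], np.where(bad, 0.0, tau1))
    d1 = re1 - rc1
    if bad.any():
        d1 = np.where(bad, -np.inf, d1)
        re1 = np.where(bad, -np.inf, re1)
        tau1 = np.where(bad, 0.0, tau1)
    return StageArrays(
        d1=d1, re1=re1, d2=re2 - rc2, re2=re2, tau1=tau1, tau2=tau2_eff
    )


def single_stage_rejections(
    batch: TrialBatch, alpha: float, tau: float | None = None
) -> np.ndarray:
    """Boolean per-replicate outcomes of the single-stage RMST z-test.

    Rejects when D̂(τ) > z_{1-α}·sqrt(Var[D̂(τ)]) at the final analysis,
    with the same data-dependent cap on the horizon as the two-stage engine.
    """
    from scipy.stats import norm

    spec = batch.spec
    t_final = spec.accrual_period_for(batch.n_total) + spec.min_followup
    tau = spec.tau if tau is None else tau
    obs_e = _observe(batch.entry["E"], batch.surv["E"], batch.cens["E"], t_final)
    obs_c = _observe(batch.entry["C"], batch.surv["C"], batch.cens["C"], t_final)
    tau_eff = np.minimum(
        tau,
        np.minimum(
            _arm_max_observed(obs_e[0], obs_e[2]),
            _arm_max_observed(obs_c[0], obs_c[2]),
        ),
    )
    re, var_e = batch_km_rmst(*obs_e, tau_eff, return_var=True)
    rc, var_c = batch_km_rmst(*obs_c, tau_eff, return_var=True)
    z = norm.ppf(1.0 - alpha)
    return (re - rc) > z * np.sqrt(var_e + var_c)
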