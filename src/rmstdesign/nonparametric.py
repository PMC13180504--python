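"""Kaplan–Meier estimation, RMST, and the single-stage RMST z-test.

This is the scalar (one sample at a time) estimator used on real patient
data and as the reference route for the vectorized Monte-Carlo engine.  The
restricted mean survival time R(τ) = ∫_0^τ Ŝ(t) dt is the area under the
product-limit curve up to the horizon τ, with the usual Greenwood-type
variance

    Var[R̂(τ)] = Σ_j [∫_{t_j}^{τ} Ŝ(u) du]^2 · d_j / (Y_j (Y_j − d_j))

over event times t_j < τ.  τ must not exceed the largest observed time of
the sample (estimability), matching the behaviour of the standard R
implementation of this estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "KMCurve",
    "RMSTEstimate",
    "DiffEstimate",
    "km_fit",
    "rmst",
    "rmst_difference",
    "single_stage_test",
    "interim_tau",
    "EstimabilityError",
]


class EstimabilityError(ValueError):
    """Raised when the RMST horizon exceeds the largest observed time."""


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: distinct event times with counts and Ŝ."""

    event_times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # Ŝ(t_j+)
    at_risk: np.ndarray  # Y_j just before t_j
    n_events: np.ndarray  # d_j
    max_observed: float  # largest observed (event or censored) time

    def evaluate(self, t) -> np.ndarray:
        """Ŝ(t) as a right-continuous step function, vectorized."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]


@dataclass(frozen=True)
class RMSTEstimate:
    value: float
    variance: float
    tau: float
    n: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass(frozen=True)
class DiffEstimate:
    """Between-arm RMST difference R̂E − R̂C with summed variances."""

    value: float
    variance: float
    tau: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def _clean(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty sample")
    if times.shape != events.shape:
        raise ValueError("times and events must have the same shape")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise ValueError("times must be finite and non-negative")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return times, events.astype(bool)


def km_fit(times, events) -> KMCurve:
    """Product-limit estimator.

    Ties between censored and event times at the same instant are resolved
    events-first: censored subjects at t_j remain in the risk set Y_j.
    """
    times, events = _clean(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = t_sorted.size

    uniq, start = np.unique(t_sorted, return_index=True)
    d = np.add.reduceat(e_sorted.astype(int), start)
    at_risk_all = n - start  # number with O >= t for each distinct time
    is_event_time = d > 0

    tj = uniq[is_event_time]
    dj = d[is_event_time]
    yj = at_risk_all[is_event_time]
    surv = np.cumprod(1.0 - dj / yj)
    return KMCurve(
        event_times=tj,
        survival=surv,
        at_risk=yj.astype(int),
        n_events=dj.astype(int),
        max_observed=float(t_sorted[-1]),
    )


def rmst(times, events, tau: float) -> RMSTEstimate:
    """RMST point estimate and variance from right-censored data."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    curve = km_fit(times, events)
    if tau > curve.max_observed:
        raise EstimabilityError(
            f"tau={tau} exceeds the largest observed time {curve.max_observed}; "
            "the survival curve is not estimable on the full horizon"
        )
    keep = curve.event_times < tau
    tj = curve.event_times[keep]
    sj = curve.survival[keep]
    dj = curve.n_events[keep]
    yj = curve.at_risk[keep]

    grid = np.concatenate([[0.0], tj, [tau]])
    heights = np.concatenate([[1.0], sj])
    widths = np.diff(grid)
    segments = heights * widths
    value = float(segments.sum())

    # ∫_{t_j}^{tau} Ŝ = total area minus area up to t_j
    cum_to_tj = np.cumsum(segments)[:-1] if tj.size else np.array([])
    area_right = value - cum_to_tj
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            yj - dj > 0, area_right**2 * dj / (yj * (yj - dj)), 0.0
        )
    variance = float(terms.sum()) if tj.size else 0.0
    return RMSTEstimate(value=value, variance=variance, tau=float(tau), n=int(np.size(times)))


def rmst_difference(times_e, events_e, times_c, events_c, tau: float) -> DiffEstimate:
    """D̂(τ) = R̂E(τ) − R̂C(τ); variances add across independent arms."""
    est_e = rmst(times_e, events_e, tau)
    est_c = rmst(times_c, events_c, tau)
    return DiffEstimate(
        value=est_e.value - est_c.value,
        variance=est_e.variance + est_c.variance,
        tau=float(tau),
    )


def single_stage_test(times_e, events_e, times_c, events_c, tau: float, alpha: float) -> dict:
    """One-sided superiority z-test on the RMST difference.

    Rejects H0 (equal RMST) when D̂(τ) > z_{1−α}·SE[D̂(τ)]; the boundary
    itself is non-rejection (strict inequality).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    diff = rmst_difference(times_e, events_e, times_c, events_c, tau)
    threshold = norm.ppf(1.0 - alpha) * diff.se
    return {
        "reject": bool(diff.value > threshold),
        "difference": diff.value,
        "se": diff.se,
        "threshold": threshold,
        "z": diff.value / diff.se if diff.se > 0 else np.nan,
    }


def interim_tau(times_e, times_c) -> float:
    """Data-dependent interim horizon τ1.

    The minimum over arms of the largest observed follow-up time (censored
    times included), so both interim RMSTs are computed on a horizon
    supported by the data of both arms.
    """
    times_e = np.asarray(times_e, dtype=float)
    times_c = np.asarray(times_c, dtype=float)
    if times_e.size == 0 or times_c.size == 0:
        raise ValueError("both arms must be non-empty at the interim analysis")
    return float(min(times_e.max(), times_c.max()))


def split_arms(sample: pd.DataFrame):
    """(times_E, events_E, times_C, events_C) from a patient-level table."""
    e = sample[sample["arm"] == "E"]
    c = sample[sample["arm"] == "C"]
    return (
        e["time"].to_numpy(float),
        e["status"].to_numpy(int),
        c["time"].to_numpy(float),
        c["status"].to_numpy(int),
    )
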