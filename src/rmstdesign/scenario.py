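"""Generative scenario descriptions for two-arm survival trials.

A scenario fixes everything needed to simulate one trial world: the survival
model of each arm (exponential or piecewise-exponential, allowing
non-proportional hazards through a hazard ratio that changes at a known time),
uniform patient accrual, uniform loss-to-follow-up censoring, and the RMST
horizon ``tau`` used at the final analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = ["ArmModel", "ScenarioSpec", "draw_survival_time", "true_rmst"]


@dataclass(frozen=True)
class ArmModel:
    """Survival-time model for one arm.

    Parameters
    ----------
    kind:
        ``"exponential"`` — constant hazard ``lam0 * delta1`` (``delta2`` and
        ``change_time`` are ignored).
        ``"piecewise_exponential"`` — hazard ``lam0 * delta1`` before
        ``change_time`` and ``lam0 * delta2`` after it, i.e. survival
        ``S(t) = exp(-delta1*lam0*min(t, CT) - delta2*lam0*max(t - CT, 0))``.
    lam0:
        Baseline hazard (events per unit time), > 0.
    delta1, delta2:
        Hazard ratios applied to ``lam0`` before/after ``change_time``, > 0.
    change_time:
        Time at which the hazard ratio switches from ``delta1`` to ``delta2``.
    """

    kind: Literal["exponential", "piecewise_exponential"] = "exponential"
    lam0: float = 1.0
    delta1: float = 1.0
    delta2: float = 1.0
    change_time: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "piecewise_exponential"):
            raise ValueError(f"unknown arm model kind: {self.kind!r}")
        if not (self.lam0 > 0 and np.isfinite(self.lam0)):
            raise ValueError("lam0 must be positive and finite")
        if not (self.delta1 > 0 and self.delta2 > 0):
            raise ValueError("hazard ratios delta1, delta2 must be positive")
        if self.change_time < 0:
            raise ValueError("change_time must be non-negative")

    # -- survival function and its inverse ---------------------------------
    def survival(self, t):
        """S(t) of the model, vectorized over ``t``."""
        t = np.asarray(t, dtype=float)
        if self.kind == "exponential":
            return np.exp(-self.lam0 * self.delta1 * t)
        h1 = self.lam0 * self.delta1
        h2 = self.lam0 * self.delta2
        ct = self.change_time
        return np.exp(-h1 * np.minimum(t, ct) - h2 * np.maximum(t - ct, 0.0))

    def quantile(self, u):
        """Inverse survival: the time t with S(t) = u, vectorized."""
        u = np.asarray(u, dtype=float)
        if np.any(~np.isfinite(u)) or np.any(u <= 0.0) or np.any(u >= 1.0):
            raise ValueError("u must lie strictly inside (0, 1)")
        x = -np.log(u)  # cumulative hazard
        h1 = self.lam0 * self.delta1
        if self.kind == "exponential":
            return x / h1
        h2 = self.lam0 * self.delta2
        ct = self.change_time
        x0 = h1 * ct  # cumulative hazard at the change time
        return np.where(x <= x0, x / h1, ct + (x - x0) / h2)

    def draw(self, rng: np.random.Generator, size):
        """Draw survival times by inverse-CDF sampling."""
        u = rng.random(size)
        # rng.random() ∈ [0, 1); nudge exact zeros away from the boundary
        u = np.where(u == 0.0, np.finfo(float).tiny, u)
        return self.quantile(u)

    def true_rmst(self, tau: float) -> float:
        """Analytic restricted mean survival time ∫_0^tau S(t) dt."""
        if tau <= 0:
            raise ValueError("tau must be positive")
        h1 = self.lam0 * self.delta1
        if self.kind == "exponential":
            return (1.0 - np.exp(-h1 * tau)) / h1
        h2 = self.lam0 * self.delta2
        ct = self.change_time
        if tau <= ct:
            return (1.0 - np.exp(-h1 * tau)) / h1
        head = (1.0 - np.exp(-h1 * ct)) / h1
        tail = np.exp(-h1 * ct) * (1.0 - np.exp(-h2 * (tau - ct))) / h2
        return float(head + tail)


def draw_survival_time(model: ArmModel, u) -> np.ndarray | float:
    """Inverse-CDF sample: the time t solving S(t) = u for u ~ U(0,1)."""
    out = model.quantile(u)
    return float(out) if np.ndim(out) == 0 else out


def true_rmst(model: ArmModel, tau: float) -> float:
    """Analytic RMST of an arm model (test oracle and effect-size helper)."""
    return model.true_rmst(tau)


@dataclass(frozen=True)
class ScenarioSpec:
    """One arm-pair trial world.

    Accrual is uniform on ``[0, a]`` where the accrual period ``a`` is either
    given directly (``accrual_period``) or implied by a constant accrual rate
    ``r`` as ``a = N / r`` (``accrual_rate``); exactly one must be supplied.
    Loss-to-follow-up censoring is uniform on ``[b, a + b]`` with ``b`` the
    minimum follow-up, so the final analysis at calendar time ``a + b``
    guarantees every patient at least ``b`` of follow-up.  ``tau`` is the RMST
    horizon of the final analysis.
    """

    experimental: ArmModel
    control: ArmModel
    min_followup: float
    tau: float
    accrual_period: float | None = None
    accrual_rate: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if (self.accrual_period is None) == (self.accrual_rate is None):
            raise ValueError(
                "specify exactly one of accrual_period or accrual_rate"
            )
        if self.accrual_period is not None and self.accrual_period <= 0:
            raise ValueError("accrual_period must be positive")
        if self.accrual_rate is not None and self.accrual_rate <= 0:
            raise ValueError("accrual_rate must be positive")
        if self.min_followup < 0:
            raise ValueError("min_followup must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def accrual_period_for(self, n_total: int) -> float:
        """Accrual period a for a trial of n_total patients."""
        if self.accrual_period is not None:
            return float(self.accrual_period)
        return float(n_total) / float(self.accrual_rate)

    def under_null(self) -> "ScenarioSpec":
        """The matched null world: both arms follow the control model."""
        return replace(self, experimental=self.control, label="H0")

    def model(self, arm: str) -> ArmModel:
        if arm in ("E", "experimental"):
            return self.experimental
        if arm in ("C", "control"):
            return self.control
        raise ValueError(f"unknown arm {arm!r}")
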