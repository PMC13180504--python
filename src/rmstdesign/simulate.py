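"""Patient-level trial simulation and observation snapshots.

``simulate_trial`` draws the latent state of a trial (entry, survival and
censoring times per patient); ``snapshot`` turns that latent state into the
administratively censored data actually observable at a calendar time — the
interim look or the final analysis at accrual period + minimum follow-up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scenario import ScenarioSpec

__all__ = ["simulate_trial", "snapshot", "final_analysis_time", "write_sample", "read_sample"]

LATENT_COLUMNS = ["id", "arm", "entry", "surv_time", "censor_time"]
SAMPLE_COLUMNS = ["id", "arm", "entry", "time", "status", "snapshot"]


def final_analysis_time(spec: ScenarioSpec, n_total: int) -> float:
    """Calendar time of the final analysis: accrual period + minimum follow-up."""
    return spec.accrual_period_for(n_total) + spec.min_followup


def simulate_trial(
    spec: ScenarioSpec, n_total: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Simulate the latent state of one trial with 1:1 block allocation.

    Returns a DataFrame with columns ``id, arm, entry, surv_time,
    censor_time``: entry ~ U[0, a]; censoring after entry ~ U[b, a+b];
    survival from each arm's model.  ``n_total`` must be even (N/2 per arm).
    """
    if n_total <= 0 or n_total % 2 != 0:
        raise ValueError("n_total must be a positive even number (1:1 allocation)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = spec.accrual_period_for(n_total)
    b = spec.min_followup
    half = n_total // 2
    frames = []
    for arm, model in (("E", spec.experimental), ("C", spec.control)):
        entry = rng.uniform(0.0, a, size=half)
        # administrative censoring induced by accrual: a patient entering at E
        # can be observed for a+b-E by the final analysis, so C ~ U[b, a+b]
        cens = a + b - entry
        surv = model.draw(rng, half)
        frames.append(
            pd.DataFrame(
                {"arm": arm, "entry": entry, "surv_time": surv, "censor_time": cens}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", np.arange(n_total))
    return out


def snapshot(records: pd.DataFrame, calendar_time: float, stage: str = "interim") -> pd.DataFrame:
    """Observable data at a calendar time.

    Patients with entry ≤ ``calendar_time`` are included; each contributes
    observed time ``O = min(T, C, calendar_time − entry)`` and event indicator
    ``δ = 1{T ≤ min(C, calendar_time − entry)}``.  The final analysis uses
    ``calendar_time = a + b``.
    """
    if calendar_time <= 0:
        raise ValueError("calendar_time must be positive")
    included = records.loc[records["entry"] <= calendar_time]
    if included.empty:
        raise ValueError("no patients enrolled by the requested calendar time")
    admin = calendar_time - included["entry"].to_numpy()
    surv = included["surv_time"].to_numpy()
    cens = included["censor_time"].to_numpy()
    cutoff = np.minimum(cens, admin)
    time = np.minimum(surv, cutoff)
    status = (surv <= cutoff).astype(int)
    return pd.DataFrame(
        {
            "id": included["id"].to_numpy(),
            "arm": included["arm"].to_numpy(),
            "entry": included["entry"].to_numpy(),
            "time": time,
            "status": status,
            "snapshot": stage,
        }
    )


def write_sample(sample: pd.DataFrame, path) -> None:
    """Write an observed sample (or latent records) to CSV."""
    sample.to_csv(path, index=False)


def read_sample(path) -> pd.DataFrame:
    """Read a patient-level CSV in the simulator's format."""
    df = pd.read_csv(path)
    missing = {"arm", "time", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"patient-level CSV lacks columns: {sorted(missing)}")
    return df
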