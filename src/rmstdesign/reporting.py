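"""Side-by-side design tables and application of a calibrated rule to data."""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CriticalValues
from .config import RunConfig
from .nonparametric import interim_tau, rmst_difference, split_arms
from .search import search_designs

__all__ = ["run_table", "write_table", "apply_rule", "TABLE_COLUMNS"]

TABLE_COLUMNS = [
    "method", "PET0", "PET1", "alphaE", "powerE",
    "EN0", "EN1", "ENbar", "N_interim", "N_total",
]


def run_table(config: RunConfig) -> pd.DataFrame:
    """One design row per method (the minimax or optimal design per config).

    Deterministic given the config's seed; infeasible scenarios yield a
    "no design" marker row.
    """
    rows = []
    for method in config.methods:
        result = search_designs(
            config.scenario,
            config.alpha0,
            config.beta0,
            b_reps=config.b_reps,
            seed=config.seed,
            method=method,
            stride=config.stride,
            interim_stride=config.interim_stride,
            **config.search_kwargs,
        )
        dp = getattr(result, config.design) if result.found else None
        if dp is None:
            rows.append(
                {"method": f"{method} (no design)", **{c: np.nan for c in TABLE_COLUMNS[1:]}}
            )
            continue
        rows.append(
            {
                "method": method,
                "PET0": dp.oc.pet0,
                "PET1": dp.oc.pet1,
                "alphaE": dp.oc.alpha,
                "powerE": dp.oc.power,
                "EN0": dp.oc.en0,
                "EN1": dp.oc.en1,
                "ENbar": dp.oc.en_mean,
                "N_interim": dp.n_interim,
                "N_total": dp.n_total,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write a design table to CSV with an audit-trail comment header."""
    with open(path, "w") as fh:
        fh.write(f"# rmstdesign {__version__}\n")
        if config is not None:
            fh.write(f"# {config.fingerprint()}\n")
        df.to_csv(fh, index=False)


def apply_rule(
    cv: CriticalValues,
    interim_sample: pd.DataFrame,
    final_sample: pd.DataFrame | None,
    tau2: float,
) -> dict:
    """Run the two-stage decision on patient-level data.

    Computes the data-dependent interim horizon τ1 and the interim pair
    (D̂1, R̂E1); the trial continues only when both strictly exceed (m1, q1).
    At the final stage (D̂2, R̂E2) at τ2 must strictly exceed (m2, q2) to
    reject H0.  All four comparisons are reported.
    """
    te, ee, tc, ec = split_arms(interim_sample)
    tau1 = interim_tau(te, tc)
    diff1 = rmst_difference(te, ee, tc, ec, tau1)
    from .nonparametric import rmst

    re1 = rmst(te, ee, tau1)
    stage1 = {
        "tau1": tau1,
        "D1": diff1.value,
        "RE1": re1.value,
        "pass_D1": bool(diff1.value > cv.m1),
        "pass_RE1": bool(re1.value > cv.q1),
    }
    report = {"critical_values": asdict(cv), "interim": stage1}
    if not (stage1["pass_D1"] and stage1["pass_RE1"]):
        report["decision"] = "terminate for futility at interim"
        report["reject_h0"] = False
        return report
    if final_sample is None:
        raise ValueError("trial continues past interim but no final data given")
    te, ee, tc, ec = split_arms(final_sample)
    diff2 = rmst_difference(te, ee, tc, ec, tau2)
    re2 = rmst(te, ee, tau2)
    stage2 = {
        "tau2": float(tau2),
        "D2": diff2.value,
        "RE2": re2.value,
        "pass_D2": bool(diff2.value > cv.m2),
        "pass_RE2": bool(re2.value > cv.q2),
    }
    report["final"] = stage2
    reject = stage2["pass_D2"] and stage2["pass_RE2"]
    report["decision"] = "reject H0: treatment effective" if reject else "fail to reject H0"
    report["reject_h0"] = bool(reject)
    return report
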