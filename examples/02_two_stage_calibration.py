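"""Calibrate sculpted and simple two-stage rules at fixed (N_interim, N).

Simulates B trials per hypothesis under the proportional-hazards world of
example 01, then grid-searches the stage-wise critical values maximizing
empirical power under alpha <= 0.05.  The sculpted rule demands both a large
RMST difference (D > m) and a large experimental-arm RMST (RE > q) at each
stage; the simple rule is its q=0 degenerate form.  Expect the sculpted rule
to convert the same type-I-error budget into noticeably more power.
"""

from rmstdesign import (
    ArmModel,
    ScenarioSpec,
    calibrate,
    simple_rmst_calibrate,
    simulate_stage_stats,
)

B = 4000  # raise to 10000 for protocol-grade numbers

spec = ScenarioSpec(
    experimental=ArmModel("exponential", lam0=0.9),
    control=ArmModel("exponential", lam0=0.9 * 1.7),
    accrual_rate=60.0,
    min_followup=1.0,
    tau=2.5,
)
h0 = simulate_stage_stats(spec, 60, 100, B, seed=1, hypothesis="H0")
h1 = simulate_stage_stats(spec, 60, 100, B, seed=1, hypothesis="H1")

for name, result in (
    ("simple ", simple_rmst_calibrate(h0, h1, 60, 100, 0.05, selection_rule="max_power")),
    ("sculpted", calibrate(h0, h1, 60, 100, 0.05, selection_rule="max_power")),
):
    cv, oc = result.critical_values, result.oc
    print(
        f"{name}: m1={cv.m1:+.3f} q1={cv.q1:.3f} m2={cv.m2:+.3f} q2={cv.q2:.3f}"
        + (f" gamma={cv.gamma:.3f}" if cv.gamma else "")
    )
    print(
        f"          alpha={oc.alpha:.4f} power={oc.power:.4f} "
        f"PET0={oc.pet0:.3f} PET1={oc.pet1:.3f} EN0={oc.en0:.1f}"
    )
# PET0 is the chance of stopping a futile trial at the interim look;
# EN0 the expected number of patients enrolled when the drug is inactive.
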