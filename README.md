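# rmstdesign

Two-stage double-arm phase II survival trial designs based on the
**restricted mean survival time (RMST)** with a **sculpted critical
region**, plus a simple RMST-difference rule and a two-stage log-rank test
as comparators.

## Who this is for

Trial statisticians designing randomized phase II studies with a
time-to-event endpoint who want (i) an effect measure that stays valid under
non-proportional hazards and reads directly as "extra life expectancy up to
τ", and (ii) a futility interim that actually saves patients.  The package
simulates the trial world, calibrates the decision rule by Monte Carlo,
evaluates operating characteristics, and searches minimax / optimal
sample-size configurations.

## The design

Let R̂_E, R̂_C be Kaplan–Meier RMST estimates and D̂ = R̂_E − R̂_C.  With a
total of N patients and an interim look after Ñ accrued, the trial

- stops for futility at the interim unless **D̂₁(τ₁) > m₁ and R̂_E1(τ₁) > q₁**,
- rejects H0 at the final analysis only if additionally
  **D̂₂(τ₂) > m₂ and R̂_E2(τ₂) > q₂**.

The q-thresholds ("sculpting") remove rejections driven by an unusually poor
control arm rather than a genuinely long-surviving experimental arm.  They
are tied to the m-thresholds by the control function **f(Ñ) = exp(−γÑ/N)**
through the conditional constraints under H1

    P(R̂_E1 > q₁ | D̂₁ > m₁) = f(Ñ),   P(R̂_E2 > q₂ | D̂₂ > m₂) = f(N),

solved with truncated-bivariate-normal conditional moments, while (γ, m₁,
m₂) are grid-searched against empirical type I error and power computed on
B simulated trials per hypothesis.  Designs satisfying α_E ≤ α₀ and
power ≥ 1−β₀ feed a Simon-style search: the **minimax** design minimizes N,
the **optimal** design minimizes the expected sample size under the null,
EN₀ = Ñ·PET₀ + N(1−PET₀), where PET is the probability of early
termination.  See `docs/methods.md` for the full model and the numerical
choices.

## Worked example

Calibrate the simple and sculpted rules for a proportional-hazards world
(experimental hazard 0.9/yr vs control 1.53/yr, accrual 60 patients/yr,
1-year minimum follow-up, τ = 2.5 y) at N = 100 with an interim at 60:

```bash
python examples/02_two_stage_calibration.py
```

prints (B = 4000 simulated trials per hypothesis):

```
simple : m1=-0.042 q1=0.000 m2=+0.174 q2=0.000
          alpha=0.0500 power=0.8345 PET0=0.327 PET1=0.036 EN0=86.9
sculpted: m1=-0.185 q1=0.452 m2=-0.052 q2=0.754 gamma=0.055
          alpha=0.0493 power=0.9310 PET0=0.393 PET1=0.030 EN0=84.3
```

Reading: both rules spend the same type-I-error budget (α ≈ 0.05), but the
sculpted rule converts it into ~10 points more power at the same sample
size — it may reject with a *smaller* between-arm difference (m₂ = −0.05 y)
because it simultaneously demands a long experimental-arm RMST
(R̂_E2 > 0.75 y).  PET0 is the chance a futile trial stops at the interim;
EN0 the expected enrolment when the drug is inactive.

Other examples: `01` simulation + RMST estimation, `03` minimax/optimal
search, `04` three-method comparison under non-proportional hazards, `05`
robustness of a frozen rule to hazard misspecification, `06` applying a
calibrated rule to patient-level data.  A thin CLI mirrors the library:

```bash
rmstdesign simulate --config examples/scenario_ph.yaml --n 100 --seed 7 --out trial.csv
rmstdesign rmst --input trial.csv --tau 2.0
rmstdesign calibrate --config examples/scenario_ph.yaml --n-total 100 --n-interim 60 --seed 1 --out rule.json
rmstdesign search --config examples/scenario_ph.yaml --b-reps 2000 --seed 1 --out designs/
```

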