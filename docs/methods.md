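# Methods

## The design problem

A randomized phase II trial compares an experimental treatment (arm E)
against a control (arm C) on a survival endpoint, with one interim look for
futility.  The treatment effect is measured by the restricted mean survival
time, R(τ) = E[min(T, τ)] = ∫₀^τ S(t)dt — the life expectancy up to a
clinically chosen horizon τ — estimated as the area under the Kaplan–Meier
curve.  The one-sided hypotheses are H0: R_E(τ) = R_C(τ) against
H1: R_E(τ) > R_C(τ).

The two-stage decision rule uses a *sculpted* critical region at each stage:
the trial continues past the interim only if

    D̂₁(τ₁) > m₁  and  R̂_E1(τ₁) > q₁,

and rejects H0 at the final analysis only if additionally

    D̂₂(τ₂) > m₂  and  R̂_E2(τ₂) > q₂,

where D̂ = R̂_E − R̂_C.  All inequalities are strict; boundary equality is
non-rejection.  The q-thresholds remove "control-driven" rejections — trials
in which the difference is large only because the control arm happened to do
unusually poorly — and re-spend that type-I-error budget on higher power.

## Trial world (the synthetic-data generator)

The generator *is* the study condition set, not a test fixture:

- survival: exponential (hazard λ₀Δ₁) or piecewise exponential with
  S_E(t) = exp(−Δ₁λ₀·min(t, CT) − Δ₂λ₀·(t−CT)₊), covering proportional
  hazards and early/late-difference alternatives; under H0 both arms follow
  the control model;
- accrual: uniform on [0, a], with the accrual period a either fixed or
  implied by a constant rate r = N/a;
- censoring: administrative only — observation ends at the final analysis
  at calendar time a + b, so the censoring time after entry is
  C = a + b − E, marginally U[b, a+b], where b is the minimum follow-up.
  (An *additional* independent dropout draw on the same support would
  double-censor the final stage; the induced-administrative reading is the
  one consistent with censoring-support and final-snapshot invariants.)
- allocation: exact N/2 per arm (block randomization), so all sample-size
  grids step by 2;
- interim timing: the look happens at calendar time a·Ñ/N, the expected
  accrual time of the Ñ-th patient, making runs deterministic given seeds.

What the generator does **not** emulate: covariates and stratification,
non-uniform accrual, loss to follow-up beyond administrative censoring,
cure fractions, competing risks, unequal allocation.  Passing tests
demonstrate correct operating characteristics in this idealized world only.

### RMST horizons

τ₂ is prespecified; τ₁ is data-dependent: the minimum over arms of the
largest observed follow-up (censored times included) at the interim, so the
two interim RMSTs share the widest horizon both arms support.  Under many
published configurations the specified τ₂ exceeds the maximum possible
follow-up a + b for part or all replicates, where a fixed-τ₂ estimator would
be undefined.  The pipeline therefore caps the final horizon per replicate,
τ₂_eff = min(τ₂, min over arms of the largest observed time) — the same
data-dependent truncation rule as at the interim.  The scalar `rmst()`
function keeps the strict estimability error (τ beyond the last observation
raises), matching the standard R implementation's contract; capping is a
pipeline policy, and `robustness_profile` reports the capped fraction.

## Calibration of (m₁, q₁, m₂, q₂, γ)

The control function f(Ñ) = exp(−γ·Ñ/N), γ > 0, links the two stages by
fixing conditional probabilities under H1:

    P(R̂_E1 > q₁ | D̂₁ > m₁) = f(Ñ),   P(R̂_E2 > q₂ | D̂₂ > m₂) = f(N).

Because f(Ñ) > f(N), the interim applies the more lenient sculpting.  Given
Monte-Carlo moments of (D̂ᵢ, R̂_Ei) under H1 (means and 1/B-normalized
covariances per stage; cross-stage correlation deliberately not modeled —
the control function is the only cross-stage link), each qᵢ is computed
from the normal approximation to R̂_Ei | D̂ᵢ > mᵢ with truncated-bivariate-
normal moments

    E = μ_E + ρσ_E·h(θ),   Var = (1−ρ²)σ_E² + ρ²σ_E²(1 + θh(θ) − h(θ)²),

θ = (m−μ_D)/σ_D, h = φ/(1−Φ) the inverse Mills ratio, evaluated through
`erfcx` so it is stable at any θ (an explicit overflow guard raises beyond
θ = 37, where the conditioning event itself underflows).  The variance
factor 1 + θh − h² is the standard truncated-normal result; it is verified
against a rejection-sampling oracle at truncation points away from the mean,
where the sign of the θh term matters.

(γ, m₁, m₂) are then grid-searched; empirical type I error and power are
computed on the same B paired replicates (each simulated trial contributes
its interim and final statistics, preserving within-trial dependence) as
boolean-matrix products over the (m₁ × m₂) grid.

### Grids and selection

- m-grids: empirical quantiles of D̂ᵢ pooled over H0 and H1, 1st–99th
  percentile, 81 points per stage (configurable).  Data-adaptive ranges
  guarantee the feasible boundary is covered at every design size.
- γ-grid: `geomspace(0.01, 3.0, 48)`.  γ enters only through f, and the
  attainable empirical α at fixed (m₁, m₂) falls roughly exponentially in
  γ; for configurations whose α ≈ α₀ frontier lies below γ = 0.1 an
  arithmetic grid has no resolution there and calibrates far inside the
  constraint.  Log spacing covers every sculpting scale from nearly inert
  (f ≈ 1) to severe.
- selection: `max_power` maximizes empirical power subject to α_E ≤ α₀
  (used for fixed-(Ñ,N) comparisons); `closest_power`, used inside the
  design search, prefers the smallest power at or above 1−β₀ and falls back
  to the largest power below it.  A literal two-sided "closest" could pick a
  point marginally below target and make the outer search discard an (Ñ, N)
  that had feasible combinations.  Ties break toward larger PET₀, then
  larger q₂ (the more robust boundary).
- the simple RMST rule is the q₁ = q₂ = 0 degenerate form, searched over
  (m₁, m₂) only.

Empirical power maximized over a large grid on the calibration replicates
is mildly optimistic; re-evaluating selected rules on fresh replicates shows
the selection bias is below 0.005 at B = 10000 for the configurations in
the test suite, so calibration and reporting share one replicate set, as in
the procedure the design is based on.

## Design search

The single-stage reference n₀ is the smallest even N whose one-sided RMST
z-test (reject when D̂ > z₁₋α·SE, Greenwood-type variance) reaches power
1−β₀ empirically; it is located by doubling-then-bisection over a per-N
deterministic seed substream, so the probe path cannot change the answer.
n₀ only seeds the scan: the search ascends N from 0.9·n₀ (even, stride
configurable), scans all Ñ < N, and stores every design with α_E ≤ α₀ and
power_E ≥ 1−β₀; the minimax design minimizes N (ties: smaller EN₀) and the
optimal design minimizes EN₀ = Ñ·PET₀ + N(1−PET₀) (ties: smaller N).  The
published outer loop is unbounded ("all N ≥ 0.9 n₀"), so the scan stops
when EN₀ has not improved for a patience window (default 5 N-steps) after
the minimax is found, and continues downward below the floor while feasible
designs keep appearing.  Latent trial data are simulated once per (N,
hypothesis) and shared by all interim sizes, which both removes needless
Monte-Carlo variance between interim points and keeps interim and final
snapshots of one replicate nested.

Default Monte-Carlo sizes: B = 10000 for calibration and 5000 for
operating-characteristic tables, the sizes the design methodology itself
prescribes; the quick searches in the test suite and examples use B = 2000
with strides of 4–8, stated there as the package's scaled profile.

## Two-stage log-rank comparator

The comparator continues when W₁/σ₁ > c_l and rejects when W/σ > c, with
the standard O−E log-rank sum and hypergeometric variance (sign convention:
positive favors arm E).  Under H0 the pair is asymptotically bivariate
normal with correlation ρ₀ = √(Var W₁ / Var W) by independent increments;
ρ₀ is estimated from the H0 Monte-Carlo variances, which keeps the
comparator free of the proportional-hazards assumption.  For each c_l on an
empirical-quantile grid (61 points), c solves the bivariate-normal tail
equation P(Z₁ > c_l, Z₂ > c) = α₀ to |P−α₀| ≤ 10⁻⁶ (Gauss–Legendre
integral + Brent root).  Feasibility is primarily this exact constraint;
the empirical rejection rate is additionally required to agree within two
Monte-Carlo standard errors.  A strict empirical cut at α₀ would be
self-defeating: rejection events are shared across the c_l grid, so a
sub-SE offset in the simulated tail disqualifies every useful boundary at
once and leaves only near-degenerate high-c_l designs.

## Randomness

Every public simulation entry point takes an integer seed.  Substreams are
derived as `SeedSequence([seed, N_total, hypothesis])`, so H0/H1 sets are
independent, different design sizes are independent, and any (seed, B)
pair reproduces exactly.  Replicates are rows of vectorized draws within a
substream; changing B changes individual replicates (prefix stability is
not promised).

## Known limitations

- The normal approximation to R̂_E | D̂ > m is an acknowledged
  approximation; its adequacy is checked empirically (the α constraint is
  enforced on simulated rejection rates, not on the approximation).
- Empirical calibration ties the rule to the assumed generative world.  The
  q-thresholds in particular exploit the assumed control hazard; if λ₀ was
  overestimated at design time the realized type I error exceeds the
  nominal level more than for difference-only rules — `robustness_profile`
  quantifies exactly this, and a conservative design can be re-searched on
  a λ₀ grid.
- Grid-search calibration this thorough can dominate published operating
  characteristics produced with coarser unspecified grids: on some
  published scenarios the search certifies feasible designs at smaller N
  than the printed minimax row (the acceptance suite measures these gaps
  rather than hiding them), while reproducing single-stage reference sizes
  and fixed-design type-I errors closely.
- Minimum follow-up b materially shifts attainable power at fixed (Ñ, N);
  configurations quoted without b are reproduced at the conventional
  b = 1 year of the non-proportional-hazards settings.
- Decisions use strict inequalities throughout; with continuous data the
  boundary has probability zero, but on discretized real data a boundary
  value terminates (futility) or fails to reject.
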