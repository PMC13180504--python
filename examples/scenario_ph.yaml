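label: ph-hr-1.7
experimental:
  kind: exponential
  lam0: 0.9
control:
  kind: exponential
  lam0: 1.53        # 0.9 * 1.7, hazard per year
accrual_period: null
accrual_rate: 60.0  # patients per year
min_followup: 1.0   # years
tau: 2.5            # RMST horizon at the final analysis, years
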