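# Final population PK/PD (indirect-response) model for LDL-C.
# Reference patient: male, non-Black, weight 83.7 kg, no concomitant statin or
# ezetimibe, no prior lipid-modifying therapy, no HeFH, no T2DM.
thetas:
  imax: 0.350          # maximum fractional inhibition of LDL-C production
  ic50: 3.17           # µg/mL
  baseline_ldl: 143.0  # mg/dL
  turn: 85.8           # h; LDL-C turnover time, 1/k_out
covariate_effects:
  - {target: imax, covariate: ezetimibe,       form: proportional, theta: 0.190}
  - {target: imax, covariate: statin_low,      form: proportional, theta: -0.238}
  - {target: imax, covariate: statin_moderate, form: proportional, theta: -0.302}
  - {target: imax, covariate: statin_high,     form: proportional, theta: -0.424}
  - {target: imax, covariate: female,          form: proportional, theta: 0.203}
  - {target: imax, covariate: weight,          form: power, reference: 83.7, theta: 0.544}
  - {target: imax, covariate: black,           form: proportional, theta: -0.240}
  - {target: imax, covariate: prior_statin,    form: proportional, theta: -0.373}
  - {target: baseline_ldl, covariate: statin_low,      form: proportional, theta: -0.159}
  - {target: baseline_ldl, covariate: statin_moderate, form: proportional, theta: -0.268}
  - {target: baseline_ldl, covariate: statin_high,     form: proportional, theta: -0.293}
  - {target: baseline_ldl, covariate: hefh,            form: proportional, theta: 0.0671}
  - {target: baseline_ldl, covariate: t2dm,            form: proportional, theta: -0.0661}
  - {target: baseline_ldl, covariate: prior_ezetimibe, form: proportional, theta: -0.0596}
  - {target: baseline_ldl, covariate: prior_statin,    form: proportional, theta: -0.296}
omega_cv:              # interindividual variability, %CV (log-normal)
  imax: 43.1
  baseline_ldl: 23.9
sigma:
  proportional: 0.153  # fraction
  additive: 3.94       # mg/dL
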