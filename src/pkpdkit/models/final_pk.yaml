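# Final population PK model of bempedoic acid.
# Reference subject: fasted, male, white, healthy, non-diabetic, no concomitant
# lipid-modifying therapy; continuous covariates centered at population medians
# (weight 83.7 kg, age 62 y, eGFR 89.3 mL/min).
thetas:
  cl_f: 0.755     # L/h
  vc_f: 19.1      # L
  ka: 1.41        # 1/h
  k23: 0.184      # 1/h
  k32: 0.156      # 1/h
  f1_rel: 1.0     # fixed; atorvastatin effect is relative bioavailability
covariate_effects:
  - {target: ka,   covariate: food,           form: proportional, theta: -0.777}
  - {target: cl_f, covariate: female,         form: proportional, theta: -0.127}
  - {target: cl_f, covariate: weight,         form: power, reference: 83.7, theta: 0.61}
  - {target: cl_f, covariate: black,          form: proportional, theta: -0.143}
  - {target: cl_f, covariate: hyperlipidemia, form: proportional, theta: -0.0945}
  - {target: cl_f, covariate: t2dm,           form: proportional, theta: -0.177}
  - {target: cl_f, covariate: egfr,           form: power, reference: 89.3, theta: 0.574}
  - {target: cl_f, covariate: ezetimibe,      form: proportional, theta: -0.0934}
  - {target: vc_f, covariate: female,         form: proportional, theta: -0.0895}
  - {target: vc_f, covariate: age,            form: power, reference: 62.0, theta: 0.743}
  - {target: vc_f, covariate: weight,         form: power, reference: 83.7, theta: 0.942}
  - {target: vc_f, covariate: simvastatin,    form: proportional, theta: -0.154}
  - {target: f1_rel, covariate: atorvastatin, form: proportional, theta: 0.142}
omega_cv:          # interindividual variability, %CV (log-normal)
  cl_f: 29.7
  vc_f: 100.0
  ka: 73.9
sigma:             # log-additive residual SD by sampling design
  serial: 0.319
  sparse: 0.543
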