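# Reference parameter set: maximum-likelihood estimates of the fibrosis
# progression Markov model from the Swedish serial-biopsy NAFLD cohort.
# Rates are per year; kCC3_fixed is a structural constant (not estimated);
# age_center is the centering age of the death-hazard age effect.
k01: 0.066
k12: 0.076
k23: 0.078
k3CC: 0.11
kback: 0.061
kCCDC: 0.15
kdeath: 0.071
lambda_death: 0.21
k_age: 0.12
k_DSTEA: 1.8
beta_T2D: 0.36
kCC3_fixed: 1.0e-06
age_center: 76.9
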