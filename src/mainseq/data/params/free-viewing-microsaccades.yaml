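name: free-viewing-microsaccades
description: >
  Aggregate inverse-linear logistic fit to microsaccades recorded at 500 Hz
  during free viewing of centrally presented stimuli, with duration-law
  coefficients and observed amplitude moments.
rate_hz: 500
lambda_micro: 6.0
n: 57031
residual_sd: 19.41
velocity:
  family: il_logistic
  Va: 323.29
  A1: 0.71
  A2: 5.79
  A0: -0.18
velocity_se:
  Va: 8.95
  A1: 0.05
  A2: 0.12
  A0: 0.008
amplitude:
  dist: truncnorm
  mean: 0.48
  sd: 0.21
  min: 0.03
  max: 1.55
observed:
  mean_amplitude: 0.48
  mean_peak_velocity: 101.01
duration:
  k0: 0.769782
  k1: 0.995477
  k2: 1.70962
  K_over_Va: 0.01685
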