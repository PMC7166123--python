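name: fixation-300hz-microsaccades
description: >
  Aggregate inverse-linear logistic fit to microsaccades recorded at 300 Hz
  during sustained central fixation (detection lambda lowered to 3.6 for the
  coarser sampling), with duration-law coefficients and observed amplitude
  moments.
rate_hz: 300
lambda_micro: 3.6
n: 14150
residual_sd: 13.29
velocity:
  family: il_logistic
  Va: 188.58
  A1: 0.11
  A2: 3.37
  A0: -0.64
velocity_se:
  Va: 3.87
  A1: 0.02
  A2: 0.07
  A0: 0.008
amplitude:
  dist: truncnorm
  mean: 0.54
  sd: 0.25
  min: 0.06
  max: 1.98
observed:
  mean_amplitude: 0.54
  mean_peak_velocity: 66.73
duration:
  k0: 0.336892
  k1: 14.32469
  k2: 2.866794
  K_over_Va: 0.0076
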