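name: fixation-500hz-microsaccades
description: >
  Aggregate inverse-linear logistic fit to microsaccades recorded at 500 Hz
  during sustained central fixation, with the matching duration-law
  coefficients and the sample moments of the observed amplitude
  distribution.
rate_hz: 500
lambda_micro: 6.0
n: 22351
residual_sd: 12.13
velocity:
  family: il_logistic
  Va: 236.22
  A1: 0.16
  A2: 3.93
  A0: -0.48
velocity_se:
  Va: 4.71
  A1: 0.02
  A2: 0.07
  A0: 0.007
amplitude:
  dist: truncnorm
  mean: 0.40
  sd: 0.16
  min: 0.02
  max: 1.60
observed:
  mean_amplitude: 0.40
  mean_peak_velocity: 70.64
duration:
  k0: 0.516223
  k1: 3.51575
  k2: 2.29179
  K_over_Va: 0.0132
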