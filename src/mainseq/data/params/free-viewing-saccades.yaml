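name: free-viewing-saccades
description: >
  Aggregate inverse-linear logistic fit to saccades (amplitudes up to ~6
  deg) recorded at 500 Hz during free viewing, with duration-law
  coefficients and observed amplitude moments.  Saccade amplitudes are
  right-skewed, hence the log-normal amplitude model.
rate_hz: 500
lambda_saccade: 8.0
n: 89020
residual_sd: 37.59
velocity:
  family: il_logistic
  Va: 895.06
  A1: 1.56
  A2: 1.70
  A0: -0.63
velocity_se:
  Va: 18.24
  A1: 0.08
  A2: 0.01
  A0: 0.02
amplitude:
  dist: lognormal
  mean: 0.74
  sd: 0.54
  min: 0.07
  max: 6.31
observed:
  mean_amplitude: 0.74
  mean_peak_velocity: 160.19
duration:
  k0: 0.369424
  k1: 0.262244
  k2: 5.278945
  K_over_Va: 0.018
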