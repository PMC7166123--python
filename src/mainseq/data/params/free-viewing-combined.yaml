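name: free-viewing-combined
description: >
  Aggregate inverse-linear logistic fit to the superposition of free-viewing
  microsaccades and saccades in a single data set, spanning the small- and
  mid-amplitude ranges.  The amplitude model is the mixture of the two
  component distributions in their observed proportions.
rate_hz: 500
n: 148569
residual_sd: 32.69
velocity:
  family: il_logistic
  Va: 793.48
  A1: 0.91
  A2: 1.49
  A0: -0.88
velocity_se:
  Va: 8.73
  A1: 0.04
  A2: 0.01
  A0: 0.01
amplitude:
  dist: mixture
  components:
    - weight: 59549
      dist: truncnorm
      mean: 0.48
      sd: 0.21
      min: 0.03
      max: 1.55
    - weight: 89020
      dist: lognormal
      mean: 0.74
      sd: 0.54
      min: 0.07
      max: 6.31
observed:
  # pooled across the two components in their observed proportions
  mean_amplitude: 0.6357
  mean_peak_velocity: 136.47
duration:
  k0: 0.369424
  k1: 0.262244
  k2: 5.278945
  K_over_Va: 0.0177
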