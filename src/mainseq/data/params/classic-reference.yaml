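name: classic-reference
description: >
  Classical literature reference set used for illustration and validation:
  the Baloh affine duration law MT = 0.037 + 0.0027 A (seconds), its
  exponential peak-velocity counterpart (Va = 551 deg/s, A0 = 14 deg), the
  Yarbus power duration law, and an inverse-linear logistic parameter set
  chosen to visually match the Baloh curves in the large-amplitude range.
  The duration coefficients here are on the millisecond scale
  (K_over_Va = 2.5 ms·deg/s per deg/s).
linear_duration:
  a: 0.037
  b: 0.0027
power_duration:
  a: 0.021
  b: 0.4
exponential:
  family: exponential
  Va: 551.0
  A0: 14.0
peak_mean_scale_K: 3.11
velocity:
  family: il_logistic
  Va: 551.0
  A0: -0.71
  A1: 4.0
  A2: 3.70
duration:
  k0: 14.99
  k1: 3.0
  k2: 0.48
  K_over_Va: 2.5
  time_unit: ms
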