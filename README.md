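# mainseq

Saccadic main-sequence modelling and eye-movement event detection for
oculomotor research.

The *main sequence* is the stereotyped pair of relationships linking the
amplitude `A` (degrees visual angle) of a saccadic eye movement to its peak
velocity `Vp` (deg/s) — quasi-linear at small amplitudes, saturating
beyond 15–20° — and to its duration `MT`, which stays nearly affine
(`MT = a + b·A`) up to very large amplitudes.  Classical one- and
two-parameter models (the inverse-linear / Michaelis–Menten curve
`Vp = Va·A/(A + A0)`, the exponential `Vp = Va·(1 − e^(−A/A0))` and the
power law `Vp = Va·A^b`) each fit only part of the amplitude range and
cannot express the S-shaped flattening seen at *both* ends of the curve,
in particular the inflection near 0.5–0.7° visible in microsaccade data.

`mainseq` implements the **inverse-linear logistic model**,

    Vp(A) = Va · A/(A + A1) · 1 / (1 + exp(−A2·(A + A0)))

an inverse-linear factor (shift `A1`) times a logistic factor (steepness
`A2`, midpoint `−A0`), which is flat at both amplitude extremes and — via
the mean-velocity identity `Vm = A/MT` and the scaling `Vp = K·Vm` — also
yields a duration law

    MT(A) = (K/Va) · (A + k0 − A0) / (1 + k1·A1·exp(−k2·A2·A))

that becomes exactly affine once the logistic correction decays, so one
model covers both halves of the main sequence.  Around the model the
package provides:

* **Detection** (`mainseq.detection`): Engbert-style velocity-threshold
  detection of microsaccades and saccades from raw gaze samples —
  cyclopean averaging of binocular data, the 5-sample velocity stencil,
  median-based dispersion thresholds `η = λ·σ` with the elliptic
  criterion `(vx/ηx)² + (vy/ηy)² > 1`, Savitzky–Golay I-VT fixation
  segmentation, minimum-duration and 20 ms lockout rules, and the
  two-sample edge rule for saccades.
* **Fitting and comparison** (`mainseq.fitting`): nonlinear least squares
  for all five model families with standard errors and t statistics,
  Gaussian-likelihood AIC/ΔAIC, Vuong's non-nested z test with the
  AIC-type correction, and OLS duration fits with F and R².
* **Synthesis** (`mainseq.synth`): seeded generation of main-sequence
  scatter (truncated normal/log-normal amplitudes, Gaussian residual
  noise) and of full gaze recordings — fixational drift plus
  ground-truth-labelled gamma-profile events — so every algorithm is
  testable without recorded data.
* **Canonical parameter sets** (`mainseq.params`): published aggregate
  fits for 500 Hz/300 Hz fixation microsaccades, free-viewing
  microsaccades and saccades, and their superposition, shipped as YAML.
* **Statistics and IO** (`mainseq.stats`, `mainseq.io`): descriptive event
  summaries (mean/SD/min/max/skewness/excess kurtosis, per-trial rates)
  and delimited-text gaze/event/report dialects with pixel→degree
  conversion.

## Worked example

Generate microsaccade-like scatter from the canonical 500 Hz fixation
parameter set (ground truth `Va = 236.22`, `A1 = 0.16`, `A2 = 3.93`,
`A0 = −0.48`, residual SD 12.13) and let the four families compete:

```python
from mainseq.params import scatter_spec
from mainseq.synth import gen_scatter
from mainseq.fitting import compare_models

s = gen_scatter(scatter_spec("fixation-500hz-microsaccades", seed=1, n=20000))
cmp_ = compare_models(s.A, s.Vp, seed=1)
```

which prints (via the `mainseq compare` CLI or a few lines of
formatting):

```
best family: il_logistic
  il_logistic      residual SE  12.06   dAIC      0.0
  power_law        residual SE  12.59   dAIC   1733.0  z = 21.49, p = 1.89e-102
  inverse_linear   residual SE  12.59   dAIC   1733.0  z = 21.49, p = 1.89e-102
  exponential      residual SE  12.59   dAIC   1733.0  z = 21.49, p = 1.89e-102
  Va  =  237.052  (SE 8.060, t = 29.4)
  A1  =    0.154  (SE 0.023, t = 6.6)
  A2  =    3.939  (SE 0.125, t = 31.5)
  A0  =   -0.487  (SE 0.007, t = -73.4)
```

The generating model wins decisively (smallest AIC; positive Vuong z
against every competitor) and its parameters are recovered within their
standard errors.  On this microsaccadic amplitude range (≤ 1.6°) the
three classical families all collapse to their best *linear* member,
which is why their fits are indistinguishable from one another — they
lack the S-curve's second bend.

The same workflow is available from the shell:

```sh
mainseq simulate --seed 1 --mode scatter --n 20000 --out-scatter scatter.csv
mainseq compare scatter.csv --out report.csv
mainseq simulate --seed 5 --duration 10 --out-gaze gaze.csv --out-events truth.csv
mainseq detect gaze.csv --out events.csv
mainseq describe events.csv --kind microsaccade --trial-duration 10
```

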