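# Methods

## Model families and canonical forms

All velocity families map amplitude `A ≥ 0` (deg) to peak velocity
(deg/s):

| family           | form                                              | location meaning                     |
|------------------|---------------------------------------------------|--------------------------------------|
| inverse_linear   | `Va·A/(A + A0)`                                   | `A0` = half-maximum amplitude        |
| exponential      | `Va·(1 − e^(−A/A0))`                              | `A0` = 63%-saturation amplitude      |
| power_law        | `Va·A^A0`                                         | `A0` = exponent (1/2 → square root)  |
| logistic         | `Va/(1 + e^(−A2·(A − A0)))`                       | `A0` = sigmoid midpoint              |
| il_logistic      | `Va·A/(A + A1) · 1/(1 + e^(−A2·(A + A0)))`        | midpoint at `−A0`                    |

The inverse-linear logistic sign convention (`A + A0`, midpoint at `−A0`)
is fixed by three observations: every published aggregate fit has a small
*negative* `A0`, only this convention places the sigmoid inflection at a
small positive amplitude (≈ 0.2–0.9° across the shipped parameter sets,
0.71° for the classical illustration set), and only this convention
reproduces all four published (mean amplitude → mean peak velocity) pairs
within 12%.  These checks are encoded as tests; any reparameterisation of
the closed forms must continue to pass them.

The duration form

    MT(A) = (K/Va)·(A + k0 − A0) / (1 + k1·A1·e^(−k2·A2·A))

is the additive-shift rearrangement of `MT = K·A/Vp(A)`.  The
multiplicative alternative (applying the logistic correction to the full
numerator) was rejected because it predicts > 100 ms durations at 1°,
wildly off the ~14 ms microsaccade durations the additive form produces.
With the classical illustration coefficients (`Va = 551`, `A0 = −0.71`,
`A1 = 4.0`, `A2 = 3.70`, `k0 = 14.99`, `k1 = 3`, `k2 = 0.48`,
`K/Va = 2.5` on the millisecond scale) it matches the classical affine
law `37 + 2.7·A` ms within 2 ms at 5°, 10° and 15°.  Once
`k1·A1·e^(−k2·A2·A) < 1e−9` the form is affine with slope `K/Va` to
machine precision — the mechanism behind linear and inverse-linear
logistic duration fits being statistically indistinguishable.

**Units.**  Internally all angles are degrees, velocities deg/s, times
seconds.  `MT` comes out in the unit implied by `K/Va`: the shipped
study coefficient sets use `K/Va ≈ 0.008–0.018` (seconds scale) while the
classical illustration set uses `K/Va = 2.5` (milliseconds scale); the
parameter files record which.

**Gamma velocity profile.**  Event waveforms are
`v(t) = α·(t/β)^(γ−1)·e^(−t/β)/N` with `N` normalising the peak to `α`
(deg/s) at `t = (γ−1)·β`.  The shape skewness is `2/√γ`: small `γ` gives
the skewed profile of large saccades, `γ → ∞` tends to a Gaussian.  `γ`
must exceed 1 so the profile rises from rest (`v(0) = 0`).  Event support
is truncated where the profile falls below 1% of its peak; the closed
form `β = amplitude·N/(α·Γ(γ))` (computed in log space) makes the time
integral equal the event amplitude.

## Detection cascade

Velocities come from the 5-sample stencil
`v_n = (x_{n+2} + x_{n+1} − x_{n−1} − x_{n−2})/D`, separably per
component.  The default denominator is the actual timestamp span
`t_{n+2} − t_{n−2}` (robust to sampling jitter); on a uniform grid that
equals `4Δt`, so velocities are inflated 1.5× relative to the nominal
`6Δt` convention, which is available as `denominator_mode="six_dt"`.
Because the median-based thresholds scale identically, detection
*decisions* are essentially invariant to the choice; both behaviours are
pinned by exact linear-ramp tests.

Thresholds use the median-based dispersion `σ² = ⟨v²⟩ − ⟨v⟩²` per
component and trial, `η = λ·σ`, with the elliptic over-threshold test.
Defaults: `λ = 6` for microsaccades at 500 Hz (3.6 at 300 Hz, reflecting
the coarser sampling), `λ = 8` for saccades, exactly as published; the
value is configuration, never inferred from data.  Zero dispersion raises
an explicit error from `estimate_thresholds` (infinite sensitivity is
never silently accepted); `detect_saccades` treats a flat segment as
trivially saccade-free.

Minimum event length is defined in *samples* (≥ 3 for microsaccades, ≥ 2
for saccades — the edge rule) because a sample count is what a threshold
test can enforce; the implied milliseconds depend on the rate (6 ms at
500 Hz, 6.7 ms at 300 Hz).  A 20 ms lockout after each microsaccade
suppresses overshoot re-detections; it applies to microsaccades only.
Fixations are segmented first (I-VT on a Savitzky–Golay derivative,
100 deg/s) and microsaccades are sought only inside them.  The published
filter description ("3rd degree, width 3") is internally impossible —
a window must exceed the polynomial degree — so the default is the
smallest consistent reading: degree 2, window `2·3 + 1 = 7` samples; both
are configurable.  Event amplitude follows the Engbert convention
`√(Δx² + Δy²)` with `Δx` the coordinate range over the event (an upper
bound on endpoint displacement, which is also provided).  Missing samples
(blinks) split segments; nothing is interpolated, since interpolation
would manufacture velocities.

## Fitting and model comparison

Nonlinear fits minimise `Σ(Vp − V(A;θ))²` with trust-region-reflective
least squares, analytic Jacobians, and quantile-based starts
(`Va = 1.1·max(Vp)`, `A0 = −median(A)`, `A1 = median(A)/2`,
`A2 = 2/IQR(A)`), up to 10 seeded jittered restarts; bounds keep `Va > 0`,
`A1 ≥ 0`, `A2 > 0` and confine the power-law exponent to `(0, 1]`.
Convergence tolerance is 1e−10 on cost decrease.  Standard errors come
from the Jacobian covariance `(JᵀJ)⁻¹·rss/(n−k)`; a singular Jacobian is
reported on the result rather than hidden.  Power-law fitting stays in
the original space so every family minimises the same criterion.

AIC uses the full Gaussian likelihood at the MLE variance `rss/n` with
one extra parameter for the variance: `AIC = n(ln 2π + ln(rss/n) + 1)
+ 2(k + 1)`.  Only ΔAIC is a contract; absolute values depend on this
convention.  Ties break toward fewer parameters.  Vuong's z forms
pointwise Gaussian log-likelihood ratios at each model's MLE variance and
applies the standard AIC-type correction — the parameter-count difference
subtracted from the summed ratio — as the only published correction of
that kind; whether the published degrees of freedom included the variance
parameter does not affect z materially.  Identical fits return `(0, 1)`;
genuinely indistinguishable non-identical models raise.  Duration fitting
freezes the four velocity-shape parameters at their fitted values and
optimises only `k0, k1, k2, K`, starting from the OLS line; note the
full-likelihood AIC penalises its two extra coefficients by 4 relative to
the affine law even when the fits coincide, so agreement is asserted on
R² and predictions rather than on raw AIC equality.

## Synthetic data: what it emulates, and what it does not

Scatter generation reproduces each study's conditions exactly as
published: sample size, residual SD, and amplitude moments (truncated
normal for fixation microsaccades; moment-matched truncated log-normal
for the right-skewed free-viewing saccades, skewness ≈ 1.17; the
superposition draws both components in their observed proportions,
89 020 : 59 549).  Residual noise is homoscedastic Gaussian.

Gaze streams model fixational drift as white Gaussian velocity noise per
component — the simplest process with randomly oriented velocity vectors.
The default `drift_sd = 9 deg/s` is calibrated so that λ = 6 thresholds
sit near 30 deg/s at 500 Hz, a realistic operating point; no published
drift magnitude exists, so this is a fixture choice.  Real drift is
correlated, tremor and blinks exist, residuals are heteroscedastic, and
amplitude distributions have structure beyond two moments — so passing
tests certify algorithmic correctness under the stated model, not
detector performance on any particular eye tracker.

Seeds are mandatory everywhere; there is no global RNG state, and equal
seeds give bit-identical output.

## Problem sizes

The test suite refits each published condition at its full n (22 351,
89 020 and 148 569 points; 20 replicates each) — the analytic Jacobians
keep each fit under a second, and the whole suite runs in under a
minute.  The acceptance script uses the same full-scale replicates.
Detector false-positive rates are measured over 100 seeded 2-second
trials; recall over 50 injected events across 10 streams.

## Known limitations

* The binocular temporal-overlap criterion is deliberately replaced by
  cyclopean averaging; vendor binary formats, blink/pupil analytics and
  streaming operation are out of scope.
* Amplitudes beyond the small/mid range (~6°) are extrapolation for the
  shipped parameter sets; `Va` is an extrapolated parameter whose
  uncertainty grows sharply when the data stop before saturation.
* On microsaccade-range data the three classical families degenerate
  toward their common linear limit (`Va, A0 → ∞` at fixed ratio, or the
  exponent bound 1); fits then sit on a ridge, which is reported via the
  standard errors rather than prevented.
* The I-VT stage caps in-fixation microsaccade peak velocities near the
  100 deg/s threshold on the smoothed trace; faster events fragment the
  fixation instead (they are still found by the saccade detector).
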