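# Methods

This note documents the models behind `torporflow`, the defaults and their
units, the numerical choices, and the limits of what a green test on the
synthetic world establishes.

## 1. The metabolic model

A bat's resting oxygen consumption (V̇O2, mL O2 h⁻¹) as a function of ambient
temperature T_a (°C) follows the classical Scholander–Irving decomposition:

- **euthermic**: V̇O2 = BMR for T_a ≥ T_lc, and
  V̇O2 = BMR + s_RMR·(T_lc − T_a) below the lower critical temperature T_lc
  (s_RMR > 0 is the cost of defending body temperature per degree of cooling);
- **torpid, thermoconforming**: V̇O2 = a·b^{T_a} with growth base b > 1
  (metabolism tracks tissue temperature);
- **torpid, thermoregulating**: below a critical temperature T_crit the bat
  defends a minimal body temperature, so
  V̇O2 = a·b^{T_crit} + s_th·(T_crit − T_a); the line meets the exponential
  curve at T_crit by construction, and s_th is much shallower than s_RMR
  (increased insulation in the torpid posture).

Default parameter values restate a published *Plecotus auritus* dataset: BMR
15.5 mL O2 h⁻¹, s_RMR 2.9 mL O2 h⁻¹ °C⁻¹, T_lc 29.7 °C, (a, b) =
(0.141, 1.151) for bats that stayed torpid into the thermoneutral zone
("group 1") and (0.127, 1.148) for bats that aroused below T_lc ("group 2"),
s_th 1.30 mL O2 h⁻¹ °C⁻¹ and T_crit 6.7 °C. State dependence enters through
body mass m (g): torpor-entry delay has conditional mean −284.2 + 51.5·m
minutes, and the arousal-triggering ambient temperature has mean
54.38 − 3.56·m °C; the arousal overshoot height above the torpid level has
mean 198.38 − 5.46·T_a mL O2 h⁻¹.

## 2. The simulator (the stated world)

One experiment follows the study protocol: the bat enters the 325 mL chamber
overnight (default clock 01:30, near the study's mean placement time), the
cabinet holds 5 °C, drops to 0 °C at ~09:00 (rounded to a whole hour), then
warms +5 °C per hour to 25 °C and +3 °C per hour to 37 °C. Every hour starts
with 15 min of baseline (animal-free) measurement; incurrent flow is
315 mL min⁻¹, reduced to a per-bat value in [101, 248] mL min⁻¹ during
torpor and restored at the detected arousal peak.

State machine: EXPLORE at 2.5 × BMR for the entry delay; a step into TORPID
(the study gives no numeric entry trajectory, and a step makes truth timing
unambiguous); AROUSAL once chamber temperature first reaches the bat's
threshold — a normalized logistic rise over 25 min from the pre-onset torpid
level to the overshoot peak, then exponential relaxation (τ = 20 min) toward
the euthermic level; EUTHERMIC thereafter. The overshoot decay is
deliberately excluded from every estimator (the study excluded the decrease
phase as baseline-interrupted), so its shape is cosmetic.

Chamber temperature is a first-order approach to the set point with
τ = 12 min. This single mechanism reproduces two observed features: T_a sits
*above* the set point during the 0 °C hour (cooling down from 5 °C) and
slightly *below* it during warming, and arousal thresholds are crossed
mid-hour rather than exactly at set-point steps. Recorded T_a adds zero-mean
Gaussian jitter (SD 0.5 °C per minute).

Analyzer rendering inverts the package's own flow equations exactly: for each
animal minute the excurrent fractions (F_eO2, F_eCO2) are solved (coupled
fixed point, 40 sweeps, machine precision) so that the oxygen equation
returns the true V̇O2 at the scheduled flow with V̇CO2 = RQ·V̇O2 (RQ default
0.85, mixed fuel; the study reports none). Span drift (piecewise-linear,
|offset| ≤ 5 × 10⁻⁴), Gaussian fraction noise (default 2 × 10⁻⁵ on each
channel), and optional washout (first-order filtering of the fraction
deficits with τ = chamber volume / flow; off by default) are applied on top.
With all analyzer effects off, the pipeline reproduces truth V̇O2 to
≤ 10⁻⁹ mL O2 h⁻¹ — the round-trip is exact by construction, which is what
makes the recovery experiments meaningful.

Mass loss uses a single energy-to-mass factor, 0.002 g per mL O2, chosen so
a ~16 h run loses ~0.5–1 g as observed; the study weighed bats directly and
states no conversion. Mass accounting is exact:
mass_start − mass_end = factor × ∫V̇O2.

Noise choices the source does not state: entry-delay residuals are
*multiplicative lognormal* (σ_log = 0.45, unit mean). Additive Gaussian
residuals (the obvious alternative) are incompatible with the printed
regression: with its negative intercept, a positivity floor would truncate
the left tail and systematically flatten every recovered slope, whereas a
positive waiting time with multiplicative noise preserves the printed
conditional mean exactly. Arousal-temperature residuals are Gaussian
(SD 3 °C, matching the printed group SDs); between-bat scatter is lognormal
on the TMR prefactor (σ = 0.15) and Gaussian on BMR (SD 3.4). Masses are
drawn N(7.82, 0.96²) g, truncated to [6.0, 11.0] (the study's range was
6.6–10.7 g); about half the bats thermoregulate, as observed.

## 3. Trace processing

Baseline windows are trimmed 2 min at each edge (washout guard; the study
does not state its trimming) and averaged; incurrent fractions are
interpolated linearly between window means and held constant outside the
anchored span. Linear interpolation removes an affine drift exactly in the
F_iO2 − F_eO2 difference; a common-mode offset still leaks through the flow
equation's F_eO2-dependent terms at second order (≤ ~0.05 mL O2 h⁻¹ at the
permitted drift magnitude), which is why the drift test asserts that bound
rather than machine precision. Span-calibration events are treated as
ordinary baseline windows.

V̇O2 is reported in mL O2 h⁻¹ (flow is stored in mL min⁻¹ and converted by
60 inside the equation); no STP correction is applied (none is stated).
Negative V̇O2 values are retained in the series — they are honest noise — but
floored at zero inside mass apportionment, whose decrement rule is a
weighting scheme, not a noise model. Gap minutes (baselines, flagged
stretches) are filled for mass apportionment with the mean of the five
non-gap minutes before and after the gap. The mass at minute 0 is the start
weighing; each later minute t loses (w_t / Σ_{t≥1} w_t)·M_t, so both
weighings are honored exactly and total loss is conserved to ≤ 10⁻⁹ g.

Per set-temperature level, candidate stretches are maximal runs of ≥ 5
consecutive non-gap minutes, excluding the first 10 min after each set-point
change (the settle allowance; raise it to ~25 min if chamber washout is
being modeled, i.e. ≥ 4 chamber time constants after each baseline window).
"Stable" is operationalized as the run minimizing the absolute OLS slope of
V̇O2 on minute; within it the lowest 5-min running mean is reported with the
mean T_a over the same window (half-open windows, no crossing of level
boundaries). At the coldest level the selection instead prefers the minutes
with the lowest T_a, which is where active thermoregulation is quantified.

## 4. Event detection

The study detected events by eye; the package formalizes them with exposed
thresholds (`ProcessingConfig`):

- **entry**: reference = median V̇O2 of the first 30 non-gap minutes; entry is
  the first minute from which V̇O2 stays below 0.5 × reference for ≥ 10
  consecutive non-gap minutes. The detector presumes the series begins in the
  pre-torpid phase; bats that enter torpor within the first half hour cannot
  be referenced (the study likewise quantified entry for 19 of 22 bats).
- **arousal onset**: first post-entry minute exceeding the trailing 15-sample
  torpid median by max(min((rise_factor−1)·median, 20), 5) mL O2 h⁻¹ with a
  strictly increasing continuation of ≥ 3 samples (rise_factor default 3; the
  absolute floor rejects noise around near-zero torpid values, the cap keeps
  warm arousals with modest overshoot detectable). A rise while the chamber
  is actively cooling (trailing T_a slope < −0.04 °C min⁻¹) is torpid
  thermoregulation, not arousal, and is rejected. The onset is backtracked to
  the pre-rise local minimum, stopping at the trailing median level, at the
  torpid drift rate, or at a trace gap. An onset that begins inside a
  baseline gap is flagged low-confidence and its T_a is the mean of the
  bracketing non-gap readings.
- **peak**: first running 3-sample maximum whose forward 5-sample slope is
  ≤ 2% of the peak value per minute ("peaked or stabilized"); ΔV̇O2 =
  V̇O2(peak) − V̇O2(last pre-onset minute), invariant to constant offsets.
- **groups**: onset T_a < T_lc → group 2; onset at/above T_lc (ties to
  group 1) or no apparent arousal with torpid readings above T_lc → group 1.
- **thermoregulation flag**: over segment minima with mean T_a ≤ 8 °C
  (just above the population's fitted critical temperature, so the flag does
  not presuppose the intersection) spanning ≥ 1 °C: flagged when the
  V̇O2-on-T_a slope is negative and the cold-minus-warm rise exceeds 1.5 ×
  the drop the thermoconforming curve itself predicts. The guard holds the
  false-positive rate on simulated conformers below 5% at default noise.

## 5. Thermal profile estimation

- **Broken stick**: continuous two-segment least squares with the breakpoint
  profiled on a 0.01 °C interior grid (vectorized via cumulative sums) and
  polished by bounded scalar minimization; a free-slope variant serves the
  linearity test and a plateau (right slope 0) variant defines BMR/T_lc,
  since the study treats BMR as temperature-independent above the inflection.
  The no-breakpoint test is a Davies-type maximum |score| over 20 interior
  candidate breakpoints, calibrated by a seeded parametric bootstrap under
  the fitted linear model (default 999 replicates, add-one p-value rule).
  Breakpoints pinned to the grid edge are flagged; fewer than 3 points per
  side is an error.
- **Exponential TMR**: ordinary least squares of log V̇O2 on T_a initializes
  a = exp(intercept), b = exp(slope); Gauss–Newton with step halving then
  minimizes the untransformed RSS (relative tolerance 10⁻¹⁰, ≤ 200
  iterations); R² is on the original scale. Fits are scale-equivariant and
  match `scipy.optimize.curve_fit` to 10⁻⁶ in the tests.
- **Random intercept (REML)**: the single variance ratio λ = τ²/σ² is
  profiled out in closed form per group block and optimized on the bounded
  transform λ/(1+λ) (tolerance 10⁻¹⁰, explicit λ = 0 boundary check); fixed
  effects are GLS at the optimum. λ = 0 reproduces OLS exactly. Standard
  errors come from the GLS covariance — no Satterthwaite/Kenward–Roger
  small-sample correction, a documented difference from lmer-style p-values.
- **Thermoregulation line**: random-intercept fit of V̇O2 on T_a pooled over
  flagged bats' qualifying points (≥ 2 bats required); the slope is reported
  as the positive per-degree-of-cooling magnitude. Pooling unflagged
  conformers attenuates the slope toward the curve's local slope.
- **Critical T_a**: the warmest sign change of line(T) − a·b^T on (0, T_lc),
  refined by Brent root bracketing to ≤ 10⁻⁶ °C (the warmest root is the
  onset of thermoregulation as T_a falls); a tangency within 10⁻⁹ returns the
  touching point, no sign change is an error reporting both endpoint values.
  A fitted T_crit ≥ T_lc is surfaced as an error, never stored.
- **Assembly**: euthermic points are segment minima starting ≥ 60 min after
  the arousal peak (excluding the overshoot decay); torpid points lie
  strictly inside the bout. Group TMR curves exclude flagged bats' points at
  T_a ≤ 8 °C; the critical temperature is computed against the pooled curve.
  Missing components are explicit `None`s, never silent.

## 6. Cohort statistics

Welch's unequal-variance t (the study's fractional degrees of freedom
identify it) via scipy, reducing exactly to Student's t at equal variances
and sizes; simple OLS via scipy with two-sided t-based slope p-values; no
multiple-testing correction (the study applies none). The report is a
deterministic, JSON-serializable bundle echoing every threshold, seed and the
package version; group contrasts are computed only when both groups have ≥ 2
members.

## 7. What the synthetic world does and does not establish

A green recovery test establishes that the estimators are consistent with
the stated generative physiology at realistic noise and the study's sample
sizes. It does not establish robustness to what the simulator leaves out:
behavioural V̇O2 transients (grooming, posture shifts), humidity or
barometric effects (air is dried; no pressure channel), analyzer span error
beyond piecewise-linear drift, body-temperature dynamics (metabolism responds
to chamber T_a instantly above the lag already modeled), or multi-bout
torpor (every study bat completed exactly one bout).

Known limitations, visible in the examples: arousals with small overshoot at
warm T_a (roughly, onset above ~32 °C) fall below any defensible detection
threshold — the study itself had four indeterminate arousals — and such bats'
post-arousal euthermic minutes are then mislabeled torpid, inflating the
group-1 TMR prefactor and deflating its base in the cohort profile (the
direct recovery tests, which generate TMR points cleanly, recover both bases
to < 1%). The per-bat minimum torpid metabolic rate is a minimum statistic
and therefore noise-floor sensitive: at default analyzer noise it reads low
relative to the generating curve. Detected onset temperatures inherit a
small positive bias (≤ one half set-step) for onsets inside baseline
windows. The entry-delay slope recovered from detected events tracks the
truth-sample regression to ~2%; residual attenuation against the printed
51.5 min g⁻¹ comes from the 45-min exploration floor in the generator.
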