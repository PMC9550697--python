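# torporflow

Open-flow respirometry analysis of torpor and arousal in small heterothermic
endotherms — bats in particular — from raw analyzer traces to cohort-level
statistics, together with a ground-truth-carrying experiment simulator that
makes every stage of the pipeline verifiable by parameter recovery.

## The problem

Small insectivorous bats at high latitudes survive long days and food
shortage by entering torpor: a controlled drop of metabolic rate far below
the euthermic resting level. Laboratory torpor experiments measure oxygen
consumption (V̇O2, mL O2 h⁻¹) in an open-flow respirometry chamber while a
temperature-controlled cabinet walks the ambient temperature T_a through a
programmed schedule. Turning such an experiment into physiology requires a
chain of careful steps, each of which this package implements as a tested,
reusable function:

1. **Trace processing** — incurrent gas fractions are anchored on hourly
   baseline (animal-free) measurements and interpolated between them to
   remove analyzer drift; V̇O2 follows from the incurrent-flow equation

   V̇O2 = FR_i [(F_iO2 − F_eO2) − F_eO2 (F_eCO2 − F_iCO2)] / (1 − F_eO2),

   with FR_i the incurrent flow. Per set-temperature level the lowest 5-min
   running mean within the most stable stretch is extracted, and body mass
   between the start and end weighings is interpolated minute-by-minute in
   proportion to V̇O2.
2. **Event detection** — torpor entry (sustained drop below a fraction of the
   early-run euthermic reference), arousal (sustained substantial rise above
   the trailing torpid level, backtracked to the pre-rise minimum), the
   arousal cost proxy ΔV̇O2 = V̇O2(peak) − V̇O2(last pre-onset minute), group
   classification (aroused below vs at/above the lower critical temperature),
   and an active-thermoregulation flag for bats whose torpid V̇O2 rises as
   T_a falls.
3. **Thermal profile** — a broken-stick (segmented) regression of euthermic
   V̇O2 on T_a finds the lower critical temperature T_lc of the thermoneutral
   zone (with a Davies-type parametric-bootstrap linearity test); BMR and the
   RMR line are estimated with a bat-level random intercept (REML); torpid
   metabolic rate is fitted as the exponential V̇O2 = a·b^Ta by Gauss–Newton;
   the thermoregulation line V̇O2 = c − s·T_a is fitted over flagged bats and
   intersected with the TMR curve to give the critical T_a below which torpid
   bats defend their temperature.
4. **Cohort statistics** — state-dependence regressions (entry delay ~ mass,
   arousal T_a ~ mass, ΔV̇O2 ~ T_a, end mass ~ start mass) and Welch t
   contrasts between the two groups, assembled into one deterministic JSON
   report.

Because raw field data of this kind are rarely deposited, the package ships a
first-class simulator (`torporflow.simulate`): a bat metabolic state machine
(exploration → torpor → arousal overshoot → euthermia) driven through the
standard protocol and rendered to analyzer level — baseline switching, span
drift, measurement noise, optional chamber washout, chamber-temperature lag —
with the generating phenotype and event log exported for every run. Default
population parameters reproduce a published brown long-eared bat
(*Plecotus auritus*) study: BMR 15.5 mL O2 h⁻¹, RMR slope 2.9 mL O2 h⁻¹ °C⁻¹
below T_lc = 29.7 °C, group TMR curves 0.141·1.151^Ta and 0.127·1.148^Ta,
thermoregulation slope 1.30 mL O2 h⁻¹ °C⁻¹ below a critical 6.7 °C, entry
delay −284.2 + 51.5·mass and arousal temperature 54.38 − 3.56·mass.

## Worked example

```python
import torporflow as tf

experiments, truth = tf.simulate_cohort(22, seed=1)
processed = [
    tf.process_experiment(e.trace, e.phenotype.mass_start, e.mass_end,
                          e.protocol.tset_schedule, e.protocol.duration,
                          bat_id=e.bat_id)
    for e in experiments
]
profile = tf.fit_thermal_profile(processed, breakpoint_n_boot=499, seed=1)
print(profile.t_lc, profile.bmr, profile.thermoreg_line.slope, profile.t_crit)
```

With this seed the pipeline prints (see `examples/03_thermal_profile.py`):

```
T_lc (breakpoint): 29.67 C   (generating value 29.7; linearity bootstrap p = 0.002)
BMR plateau: 15.44 +/- 0.80 mL O2/h (generating 15.5)
TMR group 2 (aroused below T_lc): 0.106 x 1.151**Ta  (generating 0.127 x 1.148**Ta)
thermoregulation slope: 1.21 mL O2/h per C of cooling (generating 1.30)
critical Ta: 6.37 C (generating 6.7)
```

meaning: from 22 noisy simulated traces the pipeline re-found the
thermoneutral-zone boundary within 0.03 °C, the basal plateau within
0.1 mL O2 h⁻¹, and the torpid thermoregulation behaviour (slope and critical
temperature) within ~10% of the generating physiology. The narrative scripts
in `examples/` cover one capability each: single-experiment simulation, trace
processing, thermal-profile estimation, and the cohort report.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch: it simulates a 22-bat
cohort from the default population with the given seed, processes every raw
trace (drift correction, V̇O2, segment minima, mass trajectory, event
detection), fits the cohort thermal profile and builds the report, then
writes the results JSON to `--out`. A one-line summary of the fitted profile
goes to stderr.

## Layout

- `src/torporflow/simulate.py` — phenotype, protocol, analyzer models, the
  state machine, trace rendering, cohort generation
- `src/torporflow/trace.py` — trace I/O and validation, baseline/drift model,
  the flow equation, segment minima, mass interpolation
- `src/torporflow/events.py` — torpor entry, arousal, groups, thermoregulation
- `src/torporflow/thermal.py` — broken stick, exponential fit, REML random
  intercept, thermoregulation line, critical temperature
- `src/torporflow/stats.py`, `src/torporflow/pipeline.py` — cohort statistics,
  the end-to-end pipeline and report
- `docs/methods.md` — the model, the defaults and what they mean, numerical
  choices, and what the synthetic world does and does not establish
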