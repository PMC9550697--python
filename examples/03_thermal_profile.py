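"""Estimate the cohort thermal-energetics profile from simulated experiments.

Pools euthermic and torpid segment minima across a 22-bat cohort and fits:
the broken-stick inflection separating the rising resting metabolism (RMR)
from the flat basal plateau (BMR) — the lower critical temperature T_lc —
the exponential torpid-metabolic-rate curves per group, the active
thermoregulation line of flagged bats, and the critical temperature where
that line meets the TMR curve.
"""

import warnings

import torporflow as tf

warnings.simplefilter("ignore")

experiments, truth = tf.simulate_cohort(22, seed=1)
processed = [
    tf.process_experiment(
        e.trace, e.phenotype.mass_start, e.mass_end,
        e.protocol.tset_schedule, e.protocol.duration, bat_id=e.bat_id,
    )
    for e in experiments
]
profile = tf.fit_thermal_profile(processed, breakpoint_n_boot=499, seed=1)

bs = profile.broken_stick
print(f"T_lc (breakpoint): {profile.t_lc:.2f} C   "
      f"(generating value 29.7; linearity bootstrap p = {bs.linearity_pvalue:.3f})")
print(f"BMR plateau: {profile.bmr:.2f} +/- {profile.bmr_se:.2f} mL O2/h (generating 15.5)")
print(f"RMR line: {profile.rmr_intercept:.1f} {profile.rmr_slope:+.2f} x Ta (generating slope -2.9)")
for name, fit, gen in (
    ("group 1 (torpid into TNZ)", profile.tmr_fit_group1, (0.141, 1.151)),
    ("group 2 (aroused below T_lc)", profile.tmr_fit_group2, (0.127, 1.148)),
):
    if fit:
        print(f"TMR {name}: {fit.coeff_a:.3f} x {fit.base_b:.3f}**Ta  "
              f"(generating {gen[0]} x {gen[1]}**Ta, r2 {fit.r2:.2f}, n {fit.n_points})")
line = profile.thermoreg_line
print(f"thermoregulation slope: {line.slope:.2f} mL O2/h per C of cooling "
      f"(generating 1.30; {line.n_individuals} bats, {line.n_points} points)")
print(f"critical Ta: {profile.t_crit:.2f} C (generating 6.7)")
print(f"minimum TMR: {profile.min_tmr:.2f} mL O2/h at {profile.min_tmr_ta:.1f} C")
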