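"""Torpor-entry and arousal detection, group classification, thermoregulation.

Detection operationalizes what the original study did by eye in the
acquisition software: torpor entry is a sustained drop of V̇O2 below a
fraction of the early-run euthermic reference; arousal onset is the point
where V̇O2 rises substantially above the trailing torpid level, backtracked
to the last pre-rise local minimum; the arousal cost proxy is the V̇O2
difference between the peak and the last pre-onset minute.  Bats are
classified by where (relative to the lower critical temperature) they left
torpor, and active thermoregulation is flagged when V̇O2 rises as Ta falls at
low ambient temperatures by clearly more than the thermoconforming curve
predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TorporBout",
    "ArousalEvent",
    "GroupLabel",
    "detect_torpor_entry",
    "detect_arousal",
    "classify_group",
    "flag_thermoregulation",
]


@dataclass(frozen=True)
class TorporBout:
    entry_minute: int
    entry_delay_min: int
    reference_euthermic_vo2: float


@dataclass(frozen=True)
class ArousalEvent:
    onset_minute: int
    onset_ta: float
    peak_minute: int
    duration_min: int
    delta_vo2: float
    pre_onset_vo2: float
    mass_at_onset: float | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.peak_minute > self.onset_minute:
            raise ValueError("peak must follow onset")
        if not self.delta_vo2 > 0:
            raise ValueError("delta_vo2 must be positive")


@dataclass(frozen=True)
class GroupLabel:
    label: str  # group1_tnz_thermoconformer | group2_aroused_below_tlc | undetermined
    thermoregulated_at_low_ta: bool | None = None


def _nongap(series: pd.DataFrame):
    ok = ~series["is_gap"].to_numpy() & np.isfinite(
        series["vo2_ml_h"].to_numpy(dtype=float)
    )
    return (
        series["minute"].to_numpy()[ok],
        series["vo2_ml_h"].to_numpy(dtype=float)[ok],
        series["ta_c"].to_numpy(dtype=float)[ok],
    )


def detect_torpor_entry(
    series: pd.DataFrame, frac_threshold: float = 0.5, sustain: int = 10
) -> TorporBout | None:
    """Detect torpor entry as a sustained drop below the euthermic reference.

    The reference is the median V̇O2 of the first 30 non-gap minutes (the
    exploration phase); entry is the first minute from which V̇O2 stays below
    ``frac_threshold`` x reference for at least ``sustain`` consecutive
    non-gap minutes.  Returns ``None`` if the criterion is never met.
    """
    minute, vo2, _ = _nongap(series)
    if minute.size < 30 + sustain:
        return None
    reference = float(np.median(vo2[:30]))
    below = vo2 < frac_threshold * reference
    run = 0
    for i in range(vo2.size):
        run = run + 1 if below[i] else 0
        if run >= sustain:
            entry = int(minute[i - sustain + 1])
            return TorporBout(
                entry_minute=entry,
                entry_delay_min=entry,
                reference_euthermic_vo2=reference,
            )
    return None


def detect_arousal(
    series: pd.DataFrame,
    bout: TorporBout,
    rise_factor: float = 3.0,
    sustain: int = 3,
    trailing: int = 15,
    mass_trajectory: pd.DataFrame | None = None,
    plateau_tol: float = 0.02,
    min_rise: float = 5.0,
    rise_cap: float = 20.0,
    ta_cooling_tol: float = -0.04,
) -> ArousalEvent | None:
    """Detect and quantify the arousal from torpor.

    Onset: the first post-entry minute whose V̇O2 exceeds the trailing
    ``trailing``-sample torpid median by a required rise of
    ``(rise_factor - 1) x median``, clamped between ``min_rise`` and
    ``rise_cap`` mL O2/h — the absolute floor keeps analyzer noise around
    near-zero torpid values from triggering, the cap keeps warm-temperature
    arousals (large torpid baseline, modest overshoot) detectable — and that
    keeps increasing for at least ``sustain`` further non-gap samples,
    backtracked to the last local minimum before the crossing.  A rise while
    the chamber is actively cooling (trailing Ta slope below
    ``ta_cooling_tol`` deg C/min) is torpid thermoregulatory heat production,
    not arousal, and is not accepted as an onset.  Peak: the first subsequent running
    3-sample maximum whose forward 5-sample slope is non-positive within
    ``plateau_tol`` of the peak value ("peaked or stabilized").  The cost
    proxy ``delta_vo2`` is V̇O2(peak) minus the last pre-onset V̇O2 and is by
    construction invariant to adding a constant to the whole series (as long
    as the threshold crossing still occurs).

    If the rise began inside a baseline gap the onset temperature is taken
    from the nearest non-gap minute and the event is flagged low-confidence,
    mirroring runs where arousal happened during baseline measurements.
    Returns ``None`` when no sustained rise exists.
    """
    minute, vo2, ta = _nongap(series)
    post = minute > bout.entry_minute
    m, v, t = minute[post], vo2[post], ta[post]
    if m.size < trailing + sustain + 2:
        return None

    cross = None
    med = 0.0
    for i in range(trailing, v.size - sustain):
        med = float(np.median(v[i - trailing : i]))
        required = min(max((rise_factor - 1.0) * med, min_rise), rise_cap)
        if v[i] > med + required and np.all(
            np.diff(v[i : i + sustain + 1]) > 0
        ):
            ta_slope = np.polyfit(
                m[i - trailing : i + 1].astype(float), t[i - trailing : i + 1], 1
            )[0]
            if ta_slope < ta_cooling_tol:
                continue
            cross = i
            break
    if cross is None:
        return None

    # Backtrack to the pre-rise local minimum.  Torpid V̇O2 itself drifts
    # upward while the chamber warms, so a pure "keep descending" rule would
    # walk down the whole warming ramp; stop once the minute-to-minute
    # increase falls back to the trailing torpid drift rate or the level
    # reaches the trailing median.
    trail_x = m[cross - trailing : cross].astype(float)
    trail_v = v[cross - trailing : cross]
    drift_slope = float(np.polyfit(trail_x, trail_v, 1)[0]) if trail_x.size > 1 else 0.0
    drift_tol = 2.0 * max(drift_slope, 0.0)
    onset = cross
    while (
        onset > 0
        and m[onset] - m[onset - 1] == 1  # never backtrack across a gap
        and v[onset - 1] < v[onset]
        and v[onset - 1] > med
        and v[onset] - v[onset - 1] > drift_tol
    ):
        onset -= 1

    peak = None
    for j in range(max(onset + 1, cross), v.size):
        lo = max(j - 1, 0)
        if v[j] < v[lo : min(j + 2, v.size)].max():
            continue
        fwd_m, fwd_v = m[j : j + 6], v[j : j + 6]
        if fwd_v.size >= 2:
            slope = np.polyfit(fwd_m.astype(float), fwd_v, 1)[0]
            if slope <= plateau_tol * v[j]:
                peak = j
                break
        else:
            peak = j
            break
    if peak is None or peak <= onset:
        return None

    pre_idx = onset - 1 if onset > 0 else onset
    # did the rise begin inside a baseline gap?  Then the true onset Ta is
    # bracketed by the last pre-gap and first post-gap readings.
    gap_before = onset > 0 and (m[onset] - m[onset - 1]) > 1
    onset_ta = float(t[onset])
    if gap_before:
        onset_ta = float(0.5 * (t[onset - 1] + t[onset]))
    mass_at_onset = None
    if mass_trajectory is not None:
        row = mass_trajectory["minute"].to_numpy() == m[onset]
        if row.any():
            mass_at_onset = float(mass_trajectory["mass_g"].to_numpy()[row][0])
    delta = float(v[peak] - v[pre_idx])
    if delta <= 0:
        return None
    return ArousalEvent(
        onset_minute=int(m[onset]),
        onset_ta=onset_ta,
        peak_minute=int(m[peak]),
        duration_min=int(m[peak] - m[onset]),
        delta_vo2=delta,
        pre_onset_vo2=float(v[pre_idx]),
        mass_at_onset=mass_at_onset,
        low_confidence=bool(gap_before),
    )


def classify_group(
    event: ArousalEvent | None,
    t_lc: float,
    torpid_ta_max: float | None = None,
    thermoregulated: bool | None = None,
) -> GroupLabel:
    """Assign the study's two-group label.

    Arousal below the lower critical temperature -> group 2; arousal at or
    above it (the boundary tie is assigned to "within the TNZ"), or no
    apparent arousal while torpid readings exist above ``t_lc`` -> group 1;
    anything else is undetermined.
    """
    if event is not None:
        label = (
            "group2_aroused_below_tlc"
            if event.onset_ta < t_lc
            else "group1_tnz_thermoconformer"
        )
    elif torpid_ta_max is not None and torpid_ta_max >= t_lc:
        label = "group1_tnz_thermoconformer"
    else:
        label = "undetermined"
    return GroupLabel(label=label, thermoregulated_at_low_ta=thermoregulated)


def flag_thermoregulation(
    summaries: pd.DataFrame,
    ta_ceiling: float = 8.0,
    tmr_curve=None,
    excess_factor: float = 1.5,
) -> tuple[bool | None, float | None]:
    """Flag active thermoregulation from low-temperature segment summaries.

    Qualifying points are segment minima with mean Ta at or below
    ``ta_ceiling`` (default 8 deg C, just above the population's fitted
    critical temperature so the flag does not presuppose the intersection)
    that span at least 1 deg C.  The bat is flagged when V̇O2 rises as Ta
    falls and — when a thermoconforming TMR curve is supplied — the rise from
    the warmest to the coldest qualifying point exceeds ``excess_factor``
    times the drop the curve itself predicts.  Returns ``(flag, slope)``
    where ``slope`` is the per-deg-C magnitude of the fitted V̇O2-on-Ta line;
    ``(None, None)`` means undetermined (too few or too close points).
    """
    q = summaries[summaries["mean_ta"] <= ta_ceiling]
    if len(q) < 2:
        return None, None
    ta = q["mean_ta"].to_numpy(dtype=float)
    vo2 = q["min5_vo2"].to_numpy(dtype=float)
    if ta.max() - ta.min() < 1.0:
        return None, None
    slope = float(np.polyfit(ta, vo2, 1)[0])
    flagged = slope < 0
    if flagged and tmr_curve is not None:
        i_cold, i_warm = int(np.argmin(ta)), int(np.argmax(ta))
        observed_rise = vo2[i_cold] - vo2[i_warm]
        predicted_drop = tmr_curve.predict(ta[i_warm]) - tmr_curve.predict(ta[i_cold])
        flagged = observed_rise > excess_factor * float(predicted_drop)
    return bool(flagged), abs(slope)
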