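"""End-to-end pipeline: trace -> V̇O2 -> events -> thermal profile -> report.

`process_experiment` turns one raw trace (plus the two weighings and the
set-temperature schedule) into the per-minute series, segment minima, mass
trajectory and detected events.  `fit_thermal_profile` pools processed
experiments into the cohort-level thermal energetics profile (T_lc, BMR/RMR,
group TMR curves, thermoregulation line, critical Ta), assigning group labels
and thermoregulation flags along the way.  `build_report` assembles everything
into one deterministic, JSON-serializable bundle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._version import __version__
from .events import (
    ArousalEvent,
    GroupLabel,
    TorporBout,
    classify_group,
    detect_arousal,
    detect_torpor_entry,
    flag_thermoregulation,
)
from .stats import simple_ols, welch_t
from .thermal import (
    BrokenStickFit,
    ExponentialFit,
    ThermoregLine,
    estimate_thermoreg_line,
    find_critical_ta,
    fit_broken_stick,
    fit_exponential,
    fit_random_intercept,
)
from .trace import (
    compute_vo2,
    extract_segment_minima,
    fit_baseline_model,
    interpolate_mass,
    validate_trace,
)

__all__ = [
    "ProcessingConfig",
    "ProcessedExperiment",
    "ThermalProfile",
    "ProfileError",
    "process_experiment",
    "label_segments",
    "fit_thermal_profile",
    "build_report",
]


class ProfileError(RuntimeError):
    """A thermal-profile invariant was violated (e.g. t_crit >= t_lc)."""


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunable thresholds of the per-experiment pipeline (defaults documented
    in docs/methods.md)."""

    baseline_trim_min: int = 2
    settle_min: int = 10
    window_min: int = 5
    entry_frac_threshold: float = 0.5
    entry_sustain_min: int = 10
    arousal_rise_factor: float = 3.0
    arousal_sustain_min: int = 3
    arousal_min_rise: float = 5.0
    thermoreg_ta_ceiling: float = 8.0
    thermoreg_excess_factor: float = 1.5
    euthermic_settle_min: int = 60  # arousal-overshoot decay excluded


@dataclass
class ProcessedExperiment:
    """Everything the pipeline extracted from one experiment."""

    bat_id: str
    vo2: pd.DataFrame
    segments: pd.DataFrame  # with a 'state' column once labeled
    mass: pd.DataFrame
    bout: TorporBout | None
    arousal: ArousalEvent | None
    mass_start: float
    mass_end: float
    group: GroupLabel | None = None
    thermoregulated: bool | None = None
    thermoreg_slope: float | None = None


def process_experiment(
    trace: pd.DataFrame,
    mass_start: float,
    mass_end: float,
    tset_schedule,
    duration: int | None = None,
    bat_id: str = "bat",
    config: ProcessingConfig | None = None,
) -> ProcessedExperiment:
    """Run the single-experiment pipeline on a validated raw trace."""
    cfg = config or ProcessingConfig()
    trace = validate_trace(trace)
    baseline = fit_baseline_model(trace, trim=cfg.baseline_trim_min)
    series = compute_vo2(trace, baseline)
    segments = extract_segment_minima(
        series,
        tset_schedule,
        duration=duration,
        window=cfg.window_min,
        settle=cfg.settle_min,
    )
    mass = interpolate_mass(series, mass_start, mass_end)
    bout = detect_torpor_entry(
        series, frac_threshold=cfg.entry_frac_threshold,
        sustain=cfg.entry_sustain_min,
    )
    arousal = None
    if bout is not None:
        arousal = detect_arousal(
            series,
            bout,
            rise_factor=cfg.arousal_rise_factor,
            sustain=cfg.arousal_sustain_min,
            min_rise=cfg.arousal_min_rise,
            mass_trajectory=mass,
        )
    proc = ProcessedExperiment(
        bat_id=bat_id,
        vo2=series,
        segments=segments,
        mass=mass,
        bout=bout,
        arousal=arousal,
        mass_start=mass_start,
        mass_end=mass_end,
    )
    label_segments(proc, euthermic_settle_min=cfg.euthermic_settle_min)
    return proc


def label_segments(proc: ProcessedExperiment, euthermic_settle_min: int = 60) -> None:
    """Attribute each segment summary to a metabolic state in place.

    A segment's chosen 5-min window is `torpid` if it lies strictly inside
    the torpor bout (after entry, before arousal onset), `euthermic` if it
    starts at least ``euthermic_settle_min`` minutes after the arousal peak
    (the overshoot decay is excluded from every estimator, as the source
    study excluded the decrease phase of arousals), `pre` before entry, and
    `transition` otherwise; only `torpid` and `euthermic` points enter the
    curve fits.
    """
    seg = proc.segments
    if seg.empty:
        seg["state"] = pd.Series(dtype=object)
        return
    states = []
    entry = proc.bout.entry_minute if proc.bout else None
    onset = proc.arousal.onset_minute if proc.arousal else None
    peak = proc.arousal.peak_minute if proc.arousal else None
    for _, row in seg.iterrows():
        s, e = int(row["start_minute"]), int(row["start_minute"]) + 5
        if entry is None:
            states.append("pre")
        elif e <= entry:
            states.append("pre")
        elif s > entry and (onset is None or e <= onset):
            states.append("torpid")
        elif peak is not None and s >= peak + euthermic_settle_min:
            states.append("euthermic")
        else:
            states.append("transition")
    seg["state"] = states


@dataclass
class ThermalProfile:
    """Cohort thermal-energetics profile; missing components are None."""

    bmr: float | None
    bmr_se: float | None
    rmr_intercept: float | None
    rmr_slope: float | None
    t_lc: float | None
    tnz_upper_observed: float | None
    broken_stick: BrokenStickFit | None
    broken_stick_plateau: BrokenStickFit | None
    tmr_fit_group1: ExponentialFit | None
    tmr_fit_group2: ExponentialFit | None
    tmr_fit_pooled: ExponentialFit | None
    thermoreg_line: ThermoregLine | None
    t_crit: float | None
    min_tmr: float | None
    min_tmr_ta: float | None
    n_bats: int = 0

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if hasattr(v, "__dict__") and v is not None:
                out[k] = {kk: _py(vv) for kk, vv in v.__dict__.items()}
            else:
                out[k] = _py(v)
        return out


def _py(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not math.isfinite(v):
        return None
    return v


def _euthermic_points(processed):
    rows = []
    for p in processed:
        seg = p.segments
        sel = seg[seg["state"] == "euthermic"]
        for _, r in sel.iterrows():
            rows.append((p.bat_id, r["mean_ta"], r["min5_vo2"]))
    return pd.DataFrame(rows, columns=["bat_id", "ta", "vo2"])


def _torpid_points(processed):
    rows = []
    for p in processed:
        seg = p.segments
        sel = seg[seg["state"] == "torpid"]
        for _, r in sel.iterrows():
            rows.append((p.bat_id, r["mean_ta"], r["min5_vo2"]))
    return pd.DataFrame(rows, columns=["bat_id", "ta", "vo2"])


def fit_thermal_profile(
    processed: list[ProcessedExperiment],
    config: ProcessingConfig | None = None,
    breakpoint_n_boot: int = 0,
    seed: int = 0,
) -> ThermalProfile:
    """Pool processed experiments into the cohort thermal profile.

    Steps: broken-stick regression on the pooled euthermic points (free-slope
    fit for the linearity test, plateau variant for the BMR definition; the
    plateau breakpoint is the reported T_lc), random-intercept fits for BMR
    and the RMR line split at the breakpoint, per-group exponential TMR fits
    over torpid points (excluding the low-Ta points of bats flagged as
    actively thermoregulating), the thermoregulation line over flagged bats,
    and the critical temperature where that line meets the pooled TMR curve.
    Missing components are left as explicit Nones; a fitted t_crit at or
    above T_lc is surfaced as :class:`ProfileError`, never stored.
    """
    cfg = config or ProcessingConfig()
    euth = _euthermic_points(processed)
    torpid = _torpid_points(processed)

    bs_free = bs_plateau = None
    t_lc = bmr = bmr_se = rmr_int = rmr_slope = None
    tnz_upper = None
    if len(euth) >= 6 and euth["ta"].nunique() >= 4:
        try:
            bs_free = fit_broken_stick(
                euth["ta"], euth["vo2"], right_slope_zero=False,
                n_boot=breakpoint_n_boot, seed=seed,
            )
            bs_plateau = fit_broken_stick(
                euth["ta"], euth["vo2"], right_slope_zero=True, n_boot=0,
            )
            t_lc = bs_plateau.breakpoint
        except ValueError as err:
            warnings.warn(f"broken-stick fit unavailable: {err}", stacklevel=2)
    if t_lc is not None:
        above = euth[euth["ta"] >= t_lc]
        below = euth[euth["ta"] < t_lc]
        if len(above) >= 3 and above["bat_id"].nunique() >= 2:
            fit = fit_random_intercept(
                above["vo2"], np.ones((len(above), 1)), above["bat_id"],
                names=["bmr"],
            )
            bmr, bmr_se = fit.coefficients["bmr"], fit.fixed_effects[0][2]
            plateau_ok = above[above["vo2"] <= 1.5 * bmr]
            if len(plateau_ok):
                tnz_upper = float(plateau_ok["ta"].max())
        if len(below) >= 3 and below["bat_id"].nunique() >= 2:
            X = np.column_stack([np.ones(len(below)), below["ta"].to_numpy()])
            fit = fit_random_intercept(
                below["vo2"], X, below["bat_id"], names=["intercept", "ta"]
            )
            rmr_int = fit.coefficients["intercept"]
            rmr_slope = fit.coefficients["ta"]

    # preliminary pooled TMR curve over points warm enough to be conforming;
    # non-positive minima (noise around near-zero torpid values) are excluded
    pooled_fit = None
    warm = torpid[(torpid["ta"] > cfg.thermoreg_ta_ceiling) & (torpid["vo2"] > 0)]
    if len(warm) >= 4:
        pooled_fit = fit_exponential(
            warm["ta"], warm["vo2"], n_individuals=warm["bat_id"].nunique()
        )

    # per-bat thermoregulation flags against the pooled conforming curve
    thermo_points = []
    for p in processed:
        flagged, slope = flag_thermoregulation(
            p.segments[p.segments["state"] == "torpid"].rename(
                columns={"mean_ta": "mean_ta", "min5_vo2": "min5_vo2"}
            ),
            ta_ceiling=cfg.thermoreg_ta_ceiling,
            tmr_curve=pooled_fit,
            excess_factor=cfg.thermoreg_excess_factor,
        )
        p.thermoregulated, p.thermoreg_slope = flagged, slope
        if flagged:
            seg = p.segments
            q = seg[(seg["state"] == "torpid")
                    & (seg["mean_ta"] <= cfg.thermoreg_ta_ceiling)]
            for _, r in q.iterrows():
                thermo_points.append((p.bat_id, r["mean_ta"], r["min5_vo2"]))
    thermo_points = pd.DataFrame(thermo_points, columns=["bat_id", "ta", "vo2"])

    # group labels need t_lc; fall back to the population value only if asked
    for p in processed:
        torp = p.segments[p.segments["state"] == "torpid"]
        ta_max = float(torp["mean_ta"].max()) if len(torp) else None
        p.group = (
            classify_group(p.arousal, t_lc, torpid_ta_max=ta_max,
                           thermoregulated=p.thermoregulated)
            if t_lc is not None
            else None
        )

    def conforming(df, bat_ids_flagged):
        drop = df["bat_id"].isin(bat_ids_flagged) & (
            df["ta"] <= cfg.thermoreg_ta_ceiling
        )
        return df[~drop]

    flagged_ids = {p.bat_id for p in processed if p.thermoregulated}
    tmr1 = tmr2 = tmr_pooled = None
    if t_lc is not None:
        conf = conforming(torpid, flagged_ids)
        g1_ids = {
            p.bat_id for p in processed
            if p.group and p.group.label == "group1_tnz_thermoconformer"
        }
        g2_ids = {
            p.bat_id for p in processed
            if p.group and p.group.label == "group2_aroused_below_tlc"
        }
        for ids, name in ((g1_ids, "tmr1"), (g2_ids, "tmr2")):
            sub = conf[conf["bat_id"].isin(ids) & (conf["vo2"] > 0)]
            if len(sub) >= 4:
                fit = fit_exponential(
                    sub["ta"], sub["vo2"],
                    n_individuals=sub["bat_id"].nunique(),
                )
                if name == "tmr1":
                    tmr1 = fit
                else:
                    tmr2 = fit
        sub = conf[conf["vo2"] > 0]
        if len(sub) >= 4:
            tmr_pooled = fit_exponential(
                sub["ta"], sub["vo2"], n_individuals=sub["bat_id"].nunique()
            )

    line = None
    if not thermo_points.empty and thermo_points["bat_id"].nunique() >= 2:
        line = estimate_thermoreg_line(thermo_points)

    t_crit = None
    curve_for_crit = tmr_pooled or tmr1 or tmr2
    if line is not None and curve_for_crit is not None and t_lc is not None:
        try:
            t_crit = find_critical_ta(line, curve_for_crit, bracket=(0.0, t_lc))
        except ValueError as err:
            warnings.warn(f"critical Ta not identifiable: {err}", stacklevel=2)
    if t_crit is not None and t_lc is not None and not t_crit < t_lc:
        raise ProfileError(
            f"fitted critical Ta {t_crit:.2f} is not below T_lc {t_lc:.2f}"
        )

    # per-bat minimum torpid metabolic rate and the Ta at which it occurred
    mins, min_tas = [], []
    for p in processed:
        torp = p.segments[p.segments["state"] == "torpid"]
        if len(torp):
            i = torp["min5_vo2"].idxmin()
            mins.append(float(torp.loc[i, "min5_vo2"]))
            min_tas.append(float(torp.loc[i, "mean_ta"]))
    min_tmr = float(np.mean(mins)) if mins else None
    min_tmr_ta = float(np.mean(min_tas)) if min_tas else None

    return ThermalProfile(
        bmr=bmr,
        bmr_se=bmr_se,
        rmr_intercept=rmr_int,
        rmr_slope=rmr_slope,
        t_lc=t_lc,
        tnz_upper_observed=tnz_upper,
        broken_stick=bs_free,
        broken_stick_plateau=bs_plateau,
        tmr_fit_group1=tmr1,
        tmr_fit_group2=tmr2,
        tmr_fit_pooled=tmr_pooled,
        thermoreg_line=line,
        t_crit=t_crit,
        min_tmr=min_tmr,
        min_tmr_ta=min_tmr_ta,
        n_bats=len(processed),
    )


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------


def _per_bat_row(p: ProcessedExperiment) -> dict:
    ev = p.arousal
    return {
        "bat_id": p.bat_id,
        "mass_start_g": _py(p.mass_start),
        "mass_end_g": _py(p.mass_end),
        "entry_minute": p.bout.entry_minute if p.bout else None,
        "entry_delay_min": p.bout.entry_delay_min if p.bout else None,
        "onset_minute": ev.onset_minute if ev else None,
        "onset_ta_c": _py(ev.onset_ta) if ev else None,
        "peak_minute": ev.peak_minute if ev else None,
        "duration_min": ev.duration_min if ev else None,
        "delta_vo2_ml_h": _py(ev.delta_vo2) if ev else None,
        "pre_onset_vo2_ml_h": _py(ev.pre_onset_vo2) if ev else None,
        "mass_at_onset_g": _py(ev.mass_at_onset) if ev else None,
        "low_confidence_arousal": ev.low_confidence if ev else None,
        "group": p.group.label if p.group else None,
        "thermoregulated": p.thermoregulated,
        "thermoreg_slope_ml_h_c": _py(p.thermoreg_slope),
    }


def build_report(
    processed: list[ProcessedExperiment],
    profile: ThermalProfile | None = None,
    config: ProcessingConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble the cohort report bundle (JSON-serializable, deterministic).

    Contains the per-bat event table, group summaries, the state-dependence
    regression table (entry delay ~ start mass; arousal Ta ~ start mass;
    arousal Ta ~ mass at onset; end mass ~ start mass; arousal cost ~ Ta),
    Welch comparisons between the two groups (computed only when both have at
    least two members), the thermal profile, and a configuration echo.
    """
    if not processed:
        raise ValueError("report needs at least one processed experiment")
    table = pd.DataFrame([_per_bat_row(p) for p in processed])

    def reg(xcol, ycol):
        sub = table.dropna(subset=[xcol, ycol])
        if len(sub) < 3 or sub[xcol].nunique() < 2:
            return None
        return simple_ols(sub[xcol], sub[ycol]).to_dict()

    regressions = {
        "entry_delay_vs_mass_start": reg("mass_start_g", "entry_delay_min"),
        "onset_ta_vs_mass_start": reg("mass_start_g", "onset_ta_c"),
        "onset_ta_vs_mass_at_onset": reg("mass_at_onset_g", "onset_ta_c"),
        "mass_end_vs_mass_start": reg("mass_start_g", "mass_end_g"),
        "delta_vo2_vs_onset_ta": reg("onset_ta_c", "delta_vo2_ml_h"),
    }

    g1 = table[table["group"] == "group1_tnz_thermoconformer"]
    g2 = table[table["group"] == "group2_aroused_below_tlc"]

    def summarize(g):
        return {
            "n": int(len(g)),
            "mass_start_mean_g": _py(g["mass_start_g"].mean()) if len(g) else None,
            "onset_ta_mean_c": _py(g["onset_ta_c"].mean()) if len(g) else None,
            "onset_ta_sd_c": _py(g["onset_ta_c"].std()) if len(g) > 1 else None,
            "delta_vo2_mean_ml_h": _py(g["delta_vo2_ml_h"].mean()) if len(g) else None,
            "duration_mean_min": _py(g["duration_min"].mean()) if len(g) else None,
        }

    comparisons = {}
    for col, key in (
        ("delta_vo2_ml_h", "delta_vo2_group2_vs_group1"),
        ("duration_min", "duration_group2_vs_group1"),
        ("mass_start_g", "mass_start_group2_vs_group1"),
    ):
        a = g2[col].dropna().to_numpy(dtype=float)
        b = g1[col].dropna().to_numpy(dtype=float)
        comparisons[key] = (
            welch_t(a, b).to_dict() if a.size >= 2 and b.size >= 2
            else "not_computable"
        )

    cfg = config or ProcessingConfig()
    return {
        "software": {"package": "torporflow", "version": __version__},
        "seed": seed,
        "config": {k: _py(v) for k, v in cfg.__dict__.items()},
        "n_bats": len(processed),
        "per_bat": [
            {k: (None if pd.isna(v) else _py(v)) for k, v in rec.items()}
            for rec in table.to_dict(orient="records")
        ],
        "group_summaries": {
            "group1_tnz_thermoconformer": summarize(g1),
            "group2_aroused_below_tlc": summarize(g2),
        },
        "regressions": regressions,
        "comparisons": comparisons,
        "thermal_profile": profile.to_dict() if profile is not None else None,
    }
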