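"""Raw-trace processing: drift-corrected V̇O2, segment minima, mass trajectory.

The input is a per-minute open-flow respirometry trace (animal and baseline
channels interleaved).  Processing follows the standard flow-through
bookkeeping: incurrent gas fractions are anchored by the hourly baseline
windows and interpolated linearly between them (drift correction), oxygen
consumption is computed from the flow equation

    V̇O2 = FR_i [ (FiO2 - FeO2) - FeO2 (FeCO2 - FiCO2) ] / (1 - FeO2)

with FR_i the incurrent flow, and per-temperature-step summaries take the
lowest 5-min running mean within the most stable stretch of each set-point
level.  Body mass between the start and end weighings is apportioned minute
by minute in proportion to oxygen consumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraceSchemaError",
    "BaselineModel",
    "lighton_vo2",
    "lighton_vco2",
    "read_trace",
    "write_trace",
    "validate_trace",
    "fit_baseline_model",
    "compute_vo2",
    "extract_segment_minima",
    "fill_gaps",
    "interpolate_mass",
]

TRACE_COLUMNS = ["minute", "channel", "feo2", "feco2", "flow_ml_min", "ta_c"]


class TraceSchemaError(ValueError):
    """A raw trace violated the expected schema; carries row/field context."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        ctx = ""
        if row is not None:
            ctx += f" (row {row}"
            ctx += f", field {field!r})" if field else ")"
        elif field:
            ctx += f" (field {field!r})"
        super().__init__(message + ctx)


def lighton_vo2(flow_ml_min, fio2, feo2, fico2, feco2):
    """Oxygen consumption (mL O2/h) from incurrent-flow respirometry fractions."""
    num = (fio2 - feo2) - feo2 * (feco2 - fico2)
    return 60.0 * flow_ml_min * num / (1.0 - feo2)

def lighton_vco2(flow_ml_min, fio2, feo2, fico2, feco2):
    """CO2 production (mL/h), the analogous flow equation for the CO2 channel."""
    num = (feco2 - fico2) + feco2 * (fio2 - feo2)
    return 60.0 * flow_ml_min * num / (1.0 + feco2)


# ---------------------------------------------------------------------------
# trace I/O and validation
# ---------------------------------------------------------------------------


def validate_trace(trace: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw trace against the schema; returns the frame unchanged.

    Rules: all required columns present; minutes are 0-based, strictly
    increasing, and gap-free; gas fractions lie in (0, 1); flow is positive;
    at least two baseline windows exist.
    """
    for col in TRACE_COLUMNS:
        if col not in trace.columns:
            raise TraceSchemaError(f"missing required column {col!r}", field=col)
    minute = trace["minute"].to_numpy()
    dup = np.flatnonzero(np.diff(minute) == 0)
    if dup.size:
        raise TraceSchemaError(
            f"duplicated minute {int(minute[dup[0] + 1])}", row=int(dup[0] + 1),
            field="minute",
        )
    if np.any(np.diff(minute) < 0):
        row = int(np.flatnonzero(np.diff(minute) < 0)[0] + 1)
        raise TraceSchemaError("minutes must be strictly increasing", row=row,
                               field="minute")
    if np.any(np.diff(minute) > 1):
        row = int(np.flatnonzero(np.diff(minute) > 1)[0] + 1)
        raise TraceSchemaError(
            f"gap in the minute index before minute {int(minute[row])}; gaps "
            "are rejected, not filled", row=row, field="minute",
        )
    for col in ("feo2", "feco2"):
        vals = trace[col].to_numpy(dtype=float)
        bad = ~((vals > 0.0) & (vals < 1.0) & np.isfinite(vals))
        if np.any(bad):
            row = int(np.flatnonzero(bad)[0])
            raise TraceSchemaError(
                f"{col} = {vals[row]} out of (0, 1)", row=row, field=col
            )
    flow = trace["flow_ml_min"].to_numpy(dtype=float)
    if np.any(~(flow > 0)):
        row = int(np.flatnonzero(~(flow > 0))[0])
        raise TraceSchemaError("flow must be positive", row=row, field="flow_ml_min")
    channel = trace["channel"].to_numpy()
    unknown = ~np.isin(channel, ("animal", "baseline"))
    if np.any(unknown):
        row = int(np.flatnonzero(unknown)[0])
        raise TraceSchemaError(
            f"unknown channel label {channel[row]!r}", row=row, field="channel"
        )
    if len(_baseline_runs(channel == "baseline")) < 2:
        raise TraceSchemaError("trace must contain at least two baseline windows")
    return trace


def read_trace(path) -> pd.DataFrame:
    """Read and validate a trace CSV (schema: minute, clock, channel, feo2,
    feco2, flow_ml_min, ta_c)."""
    trace = pd.read_csv(path)
    return validate_trace(trace)


def write_trace(trace: pd.DataFrame, path, fraction_decimals: int = 6) -> None:
    """Write a trace CSV; gas fractions at 6 decimals, Ta at 3, by convention."""
    out = trace.copy()
    for col in ("feo2", "feco2"):
        out[col] = out[col].round(fraction_decimals)
    out["ta_c"] = out["ta_c"].round(3)
    out.to_csv(path, index=False)


def _baseline_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start_index, end_index_exclusive)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[splits + 1]))
    ends = np.concatenate((idx[splits] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# baseline / drift model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaselineModel:
    """Incurrent-fraction model anchored at baseline-window means.

    ``fio2_at``/``fico2_at`` interpolate linearly between window means and
    hold the first/last mean constant outside the anchored span, which
    recovers an affine analyzer drift exactly wherever baselines bracket the
    animal minutes.
    """

    window_means: pd.DataFrame  # columns: center_minute, fio2, fico2, n
    trim: int

    @property
    def fio2_at(self) -> Callable[[np.ndarray], np.ndarray]:
        c = self.window_means["center_minute"].to_numpy(dtype=float)
        v = self.window_means["fio2"].to_numpy(dtype=float)
        return lambda m: np.interp(np.asarray(m, dtype=float), c, v)

    @property
    def fico2_at(self) -> Callable[[np.ndarray], np.ndarray]:
        c = self.window_means["center_minute"].to_numpy(dtype=float)
        v = self.window_means["fico2"].to_numpy(dtype=float)
        return lambda m: np.interp(np.asarray(m, dtype=float), c, v)


def fit_baseline_model(trace: pd.DataFrame, trim: int = 2) -> BaselineModel:
    """Average each baseline window (after trimming ``trim`` washout-guard
    minutes at both edges) and interpolate between the window means.

    Windows retaining fewer than 5 samples after trimming are excluded with a
    warning; fewer than two usable windows is an error.
    """
    mask = (trace["channel"] == "baseline").to_numpy()
    runs = _baseline_runs(mask)
    if len(runs) >= 1 and trim * 2 >= min(e - s for s, e in runs):
        raise ValueError("trim must be less than half the shortest baseline window")
    minute = trace["minute"].to_numpy()
    rows = []
    for s, e in runs:
        lo, hi = s + trim, e - trim
        if hi - lo < 5:
            warnings.warn(
                f"baseline window at minute {int(minute[s])} retains "
                f"{max(hi - lo, 0)} samples after trimming; excluded",
                stacklevel=2,
            )
            continue
        sl = trace.iloc[lo:hi]
        rows.append(
            {
                "center_minute": float(sl["minute"].mean()),
                "fio2": float(sl["feo2"].mean()),
                "fico2": float(sl["feco2"].mean()),
                "n": hi - lo,
            }
        )
    if len(rows) < 2:
        raise ValueError("need at least two usable baseline windows")
    return BaselineModel(window_means=pd.DataFrame(rows), trim=trim)


# ---------------------------------------------------------------------------
# V̇O2 computation
# ---------------------------------------------------------------------------


def compute_vo2(trace: pd.DataFrame, baseline: BaselineModel) -> pd.DataFrame:
    """Drift-corrected per-minute V̇O2/V̇CO2 series.

    Baseline minutes are marked ``is_gap`` (no animal signal); animal minutes
    with FeO2 >= 1 are flagged as gaps with a warning.  Negative values are
    retained — they are honest measurement noise, not clamped.

    Returns a DataFrame with columns ``minute, vo2_ml_h, vco2_ml_h, ta_c,
    is_gap`` spanning the whole trace.
    """
    minute = trace["minute"].to_numpy()
    feo2 = trace["feo2"].to_numpy(dtype=float)
    feco2 = trace["feco2"].to_numpy(dtype=float)
    flow = trace["flow_ml_min"].to_numpy(dtype=float)
    is_gap = (trace["channel"] == "baseline").to_numpy().copy()

    fio2 = baseline.fio2_at(minute)
    fico2 = baseline.fico2_at(minute)
    undefined = (feo2 >= 1.0) & ~is_gap
    if np.any(undefined):
        warnings.warn(
            f"{int(undefined.sum())} animal minutes have FeO2 >= 1; flagged as gaps",
            stacklevel=2,
        )
        is_gap |= undefined

    with np.errstate(divide="ignore", invalid="ignore"):
        vo2 = lighton_vo2(flow, fio2, feo2, fico2, feco2)
        vco2 = lighton_vco2(flow, fio2, feo2, fico2, feco2)
    vo2 = np.where(is_gap, np.nan, vo2)
    vco2 = np.where(is_gap, np.nan, vco2)
    return pd.DataFrame(
        {
            "minute": minute,
            "vo2_ml_h": vo2,
            "vco2_ml_h": vco2,
            "ta_c": trace["ta_c"].to_numpy(dtype=float),
            "is_gap": is_gap,
        }
    )


# ---------------------------------------------------------------------------
# per-temperature-step summaries
# ---------------------------------------------------------------------------


def _consecutive_runs(minutes: np.ndarray) -> list[np.ndarray]:
    """Split an increasing minute index into maximal consecutive runs."""
    if minutes.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(minutes) > 1)
    return np.split(np.arange(minutes.size), breaks + 1)


def extract_segment_minima(
    series: pd.DataFrame,
    tset_schedule: Sequence[tuple[int, float]],
    duration: int | None = None,
    window: int = 5,
    settle: int = 10,
    prefer_cold_at_lowest: bool = True,
) -> pd.DataFrame:
    """Lowest ``window``-minute running mean per set-temperature level.

    For every schedule entry, candidate stretches are maximal runs of at
    least ``window`` consecutive non-gap minutes, excluding the first
    ``settle`` minutes after the set-point change (equilibration allowance).
    The stable stretch is the run with the smallest |OLS slope| of V̇O2 on
    minute; within it the lowest running mean over ``window`` minutes is
    reported together with the mean Ta over the same minutes.  At the coldest
    level the selection instead prefers the minutes where Ta is lowest, which
    is where active thermoregulation is quantified.

    Levels without a qualifying stretch are omitted with a warning.  Columns:
    ``tset_level, min5_vo2, mean_ta, start_minute, stability_score,
    run_start, run_end``.
    """
    sched = list(tset_schedule)
    if duration is None:
        duration = int(series["minute"].max()) + 1
    bounds = [s for s, _ in sched] + [duration]
    lowest = min(lv for _, lv in sched)

    minute = series["minute"].to_numpy()
    vo2 = series["vo2_ml_h"].to_numpy(dtype=float)
    ta = series["ta_c"].to_numpy(dtype=float)
    ok = ~series["is_gap"].to_numpy() & np.isfinite(vo2)

    out = []
    for (seg_start, level), seg_end in zip(sched, bounds[1:]):
        sel = ok & (minute >= seg_start + settle) & (minute < seg_end)
        mins = minute[sel]
        runs = [r for r in _consecutive_runs(mins) if r.size >= window]
        if not runs:
            warnings.warn(
                f"no stable stretch of {window} consecutive minutes at set "
                f"temperature {level} deg C (start minute {seg_start}); omitted",
                stacklevel=2,
            )
            continue
        v_sel, t_sel, m_sel = vo2[sel], ta[sel], mins

        def run_stats(r):
            x, y = m_sel[r].astype(float), v_sel[r]
            slope = np.polyfit(x, y, 1)[0] if r.size > 1 else 0.0
            return abs(float(slope))

        cold_rule = prefer_cold_at_lowest and level == lowest
        if cold_rule:
            run = min(runs, key=lambda r: _min_running_mean(t_sel[r], window)[0])
        else:
            run = min(runs, key=run_stats)
        stability = run_stats(run)
        if cold_rule:
            _, idx = _min_running_mean(t_sel[run], window)
        else:
            _, idx = _min_running_mean(v_sel[run], window)
        win = run[idx : idx + window]
        out.append(
            {
                "tset_level": level,
                "min5_vo2": float(v_sel[win].mean()),
                "mean_ta": float(t_sel[win].mean()),
                "start_minute": int(m_sel[win[0]]),
                "stability_score": stability,
                "run_start": int(m_sel[run[0]]),
                "run_end": int(m_sel[run[-1]]) + 1,
            }
        )
    return pd.DataFrame(out)


def _min_running_mean(values: np.ndarray, window: int) -> tuple[float, int]:
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    idx = int(np.argmin(means))
    return float(means[idx]), idx


# ---------------------------------------------------------------------------
# body-mass trajectory
# ---------------------------------------------------------------------------


def fill_gaps(vo2: np.ndarray, is_gap: np.ndarray, k: int = 5) -> np.ndarray:
    """Fill gap minutes with the mean of the ``k`` non-gap minutes before and
    after each gap run (fewer at trace edges, at least one side required)."""
    vo2 = np.asarray(vo2, dtype=float).copy()
    is_gap = np.asarray(is_gap, dtype=bool) | ~np.isfinite(vo2)
    good_idx = np.flatnonzero(~is_gap)
    if good_idx.size == 0:
        raise ValueError("series contains no usable minutes")
    for start, end in _baseline_runs(is_gap):
        before = good_idx[good_idx < start][-k:]
        after = good_idx[good_idx >= end][:k]
        pool = np.concatenate((before, after))
        vo2[start:end] = vo2[pool].mean()
    return vo2


def interpolate_mass(
    series: pd.DataFrame, mass_start: float, mass_end: float
) -> pd.DataFrame:
    """Minute-resolved body mass between the start and end weighings.

    Gap minutes are filled via :func:`fill_gaps`; negative values are floored
    at zero for apportionment only (the decrement rule is a weighting scheme,
    not a noise model).  ``mass_g[t]`` is the mass at the start of minute
    ``t``: the first minute equals the start weighing exactly, each later
    minute loses its share ``w_t / sum(w)`` of the total loss, and the last
    minute lands on the end weighing exactly.
    """
    if not mass_start > mass_end > 0:
        raise ValueError("need mass_start > mass_end > 0")
    filled = fill_gaps(
        series["vo2_ml_h"].to_numpy(dtype=float), series["is_gap"].to_numpy()
    )
    w = np.clip(filled, 0.0, None)
    w[0] = 0.0  # minute 0 is the weighing instant
    total = w.sum()
    if total == 0:
        raise ValueError("total V̇O2 is zero; cannot apportion mass loss")
    mass = mass_start - np.cumsum(w / total) * (mass_start - mass_end)
    return pd.DataFrame({"minute": series["minute"].to_numpy(), "mass_g": mass})
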