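"""Trace processing tests: I/O validation, drift model, the flow equation,
segment minima, and the mass trajectory."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import torporflow as tf
from torporflow.trace import TraceSchemaError, fill_gaps


def _toy_trace(n=200, baseline_every=60, baseline_len=15):
    minute = np.arange(n)
    base = (minute % baseline_every) < baseline_len
    return pd.DataFrame(
        {
            "minute": minute,
            "channel": np.where(base, "baseline", "animal"),
            "feo2": np.where(base, 0.2095, 0.2045),
            "feco2": np.where(base, 0.0004, 0.0054),
            "flow_ml_min": 315.0,
            "ta_c": 5.0,
        }
    )


def _series(vo2, is_gap=None, ta=None):
    vo2 = np.asarray(vo2, dtype=float)
    return pd.DataFrame(
        {
            "minute": np.arange(vo2.size),
            "vo2_ml_h": vo2,
            "vco2_ml_h": vo2 * 0.85,
            "ta_c": np.full(vo2.size, 5.0) if ta is None else np.asarray(ta),
            "is_gap": np.zeros(vo2.size, bool) if is_gap is None else np.asarray(is_gap),
        }
    )


class TestTraceIO:
    def test_write_read_roundtrip(self, clean_experiment, tmp_path):
        path = tmp_path / "trace.csv"
        tf.write_trace(clean_experiment.trace, path)
        back = tf.read_trace(path)
        assert len(back) == len(clean_experiment.trace)
        # writing what was read reproduces the file byte-for-byte
        path2 = tmp_path / "trace2.csv"
        tf.write_trace(back, path2)
        assert path.read_text() == path2.read_text()

    def test_duplicate_minute_named(self):
        t = _toy_trace()
        t.loc[50, "minute"] = 49
        with pytest.raises(TraceSchemaError, match="49"):
            tf.validate_trace(t)

    def test_minute_gap_rejected(self):
        t = _toy_trace()
        t.loc[50:, "minute"] = t.loc[50:, "minute"] + 3
        with pytest.raises(TraceSchemaError, match="gap"):
            tf.validate_trace(t)

    def test_fraction_out_of_range_names_row(self):
        t = _toy_trace()
        t.loc[17, "feo2"] = 1.2
        with pytest.raises(TraceSchemaError, match="row 17"):
            tf.validate_trace(t)

    def test_missing_column(self):
        t = _toy_trace().drop(columns=["flow_ml_min"])
        with pytest.raises(TraceSchemaError, match="flow_ml_min"):
            tf.validate_trace(t)

    def test_unknown_channel(self):
        t = _toy_trace()
        t.loc[3, "channel"] = "reference"
        with pytest.raises(TraceSchemaError, match="reference"):
            tf.validate_trace(t)

    def test_needs_two_baseline_windows(self):
        t = _toy_trace(n=50)
        with pytest.raises(TraceSchemaError, match="baseline"):
            tf.validate_trace(t)


class TestBaselineModel:
    def test_constant_baseline(self):
        t = _toy_trace()
        model = tf.fit_baseline_model(t, trim=2)
        m = np.arange(200)
        assert np.allclose(model.fio2_at(m), 0.2095)
        assert np.allclose(model.fico2_at(m), 0.0004)

    def test_linear_interpolation_between_windows(self):
        t = _toy_trace(n=130, baseline_every=65, baseline_len=15)
        t.loc[t["minute"] >= 65, "feo2"] = np.where(
            t.loc[t["minute"] >= 65, "channel"] == "baseline", 0.2091, 0.2045
        )
        model = tf.fit_baseline_model(t, trim=2)
        c = model.window_means["center_minute"].to_numpy()
        assert np.allclose(np.diff(c), 65.0)
        midpoint = c.mean()
        assert model.fio2_at([midpoint])[0] == pytest.approx(0.2093, abs=1e-12)

    def test_trim_too_large(self):
        with pytest.raises(ValueError, match="trim"):
            tf.fit_baseline_model(_toy_trace(), trim=8)

    def test_short_window_excluded_with_warning(self):
        t = _toy_trace(n=200)
        # shrink the second window to 6 minutes: 6 - 2*2 < 5 retained
        sel = (t["minute"] >= 66) & (t["minute"] < 75)
        t.loc[sel, "channel"] = "animal"
        with pytest.warns(UserWarning, match="excluded"):
            model = tf.fit_baseline_model(t, trim=2)
        assert len(model.window_means) == 3


class TestComputeVo2:
    def test_zero_when_excurrent_equals_incurrent(self):
        assert tf.lighton_vo2(315.0, 0.2095, 0.2095, 0.0004, 0.0004) == 0.0

    def test_hand_evaluations(self):
        assert tf.lighton_vo2(315.0, 0.2095, 0.2045, 0.0004, 0.0054) == pytest.approx(
            94.5, abs=1e-9
        )
        # CO2-free reduction: FR (FiO2 - FeO2) / (1 - FeO2)
        assert tf.lighton_vo2(100.0, 0.2095, 0.2, 0.0004, 0.0004) == pytest.approx(
            71.25, abs=1e-9
        )

    def test_negative_values_retained(self):
        t = _toy_trace()
        t.loc[t["channel"] == "animal", "feo2"] = 0.2096  # above incurrent
        series = tf.compute_vo2(t, tf.fit_baseline_model(t))
        animal = ~series["is_gap"]
        assert (series.loc[animal, "vo2_ml_h"] < 0).all()

    def test_feo2_at_one_flagged_as_gap(self):
        t = _toy_trace()
        t["feo2"] = t["feo2"].astype(float)
        # validate_trace would reject >= 1, but compute_vo2 must also defend
        t.loc[20, "feo2"] = 1.0
        with pytest.warns(UserWarning, match="FeO2"):
            series = tf.compute_vo2(t, tf.fit_baseline_model(t))
        assert bool(series.loc[20, "is_gap"])


class TestSegmentMinima:
    def test_constant_level(self):
        s = _series(np.full(120, 7.5))
        out = tf.extract_segment_minima(s, [(0, 10.0)], duration=120)
        assert len(out) == 1
        assert out.loc[0, "min5_vo2"] == pytest.approx(7.5)

    def test_v_shape_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        v = np.abs(np.arange(100) - 60) * 0.3 + 2 + rng.normal(0, 0.05, 100)
        s = _series(v)
        out = tf.extract_segment_minima(
            s, [(0, 10.0)], duration=100, settle=0, prefer_cold_at_lowest=False
        )
        run = s[(s["minute"] >= out.loc[0, "run_start"]) & (s["minute"] < out.loc[0, "run_end"])]
        vals = run["vo2_ml_h"].to_numpy()
        brute = min(vals[i : i + 5].mean() for i in range(vals.size - 4))
        assert out.loc[0, "min5_vo2"] == pytest.approx(brute, abs=1e-12)

    def test_settle_minutes_excluded(self):
        v = np.full(100, 5.0)
        v[:10] = 0.1  # artificially low equilibration values must be ignored
        out = tf.extract_segment_minima(_series(v), [(0, 10.0)], duration=100, settle=10)
        assert out.loc[0, "min5_vo2"] == pytest.approx(5.0)

    def test_lowest_level_prefers_cold_minutes(self):
        ta = np.concatenate([np.linspace(2, 0.2, 50), np.linspace(0.2, 2, 50)])
        v = np.linspace(8.0, 7.0, 100)  # vo2 drifts down while ta re-warms
        out = tf.extract_segment_minima(
            _series(v, ta=ta), [(0, 0.0)], duration=100, settle=0
        )
        # the chosen window sits at the Ta trough, not at the V̇O2 minimum
        assert out.loc[0, "mean_ta"] < 0.5
        assert out.loc[0, "min5_vo2"] > 7.2

    def test_level_without_stable_stretch_omitted(self):
        gaps = np.ones(60, bool)
        gaps[:30] = False
        s = _series(np.full(60, 3.0), is_gap=gaps)
        with pytest.warns(UserWarning, match="omitted"):
            out = tf.extract_segment_minima(
                s, [(0, 5.0), (30, 10.0)], duration=60, settle=0
            )
        assert list(out["tset_level"]) == [5.0]


class TestMassTrajectory:
    def test_gap_fill_rule(self):
        v = np.arange(20, dtype=float)
        gap = np.zeros(20, bool)
        gap[8:12] = True
        filled = fill_gaps(v, gap, k=5)
        expected = np.mean([3, 4, 5, 6, 7, 12, 13, 14, 15, 16])
        assert np.allclose(filled[8:12], expected)
        assert np.allclose(filled[~gap], v[~gap])

    def test_leading_gap_uses_following_minutes(self):
        v = np.array([np.nan, np.nan, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
        gap = np.zeros(8, bool)
        gap[:2] = True
        filled = fill_gaps(v, gap, k=5)
        assert np.allclose(filled[:2], np.mean([4, 6, 8, 10, 12]))

    def test_uniform_series_linear_decline(self):
        s = _series(np.full(960, 20.0))
        traj = tf.interpolate_mass(s, 8.0, 7.04)
        d = np.diff(traj["mass_g"].to_numpy())
        assert np.allclose(d, -0.96 / 959, atol=1e-12)
        assert d.mean() == pytest.approx(-0.001, rel=2e-3)
        assert traj["mass_g"].iloc[0] == 8.0
        assert traj["mass_g"].iloc[-1] == pytest.approx(7.04, abs=1e-9)

    def test_two_phase_apportionment(self):
        v = np.concatenate([np.full(100, 10.0), np.full(100, 90.0)])
        traj = tf.interpolate_mass(_series(v), 8.0, 7.0)
        m = traj["mass_g"].to_numpy()
        phase_one_loss = 8.0 - m[99]
        assert phase_one_loss == pytest.approx(0.1, rel=0.02)
        assert m[99] - m[-1] == pytest.approx(0.9, rel=0.01)

    def test_errors(self):
        s = _series(np.full(50, 5.0))
        with pytest.raises(ValueError, match="mass_start"):
            tf.interpolate_mass(s, 7.0, 7.5)
        with pytest.raises(ValueError, match="apportion"):
            tf.interpolate_mass(_series(np.zeros(50)), 8.0, 7.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_conservation_property(self, seed):
        """Mass loss is conserved exactly and the trajectory never increases
        for any series, including ones with gaps and negative noise."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 300))
        v = rng.normal(5.0, 6.0, n)  # includes negative values
        gap = rng.random(n) < 0.2
        gap[0] = False
        s = _series(v, is_gap=gap)
        traj = tf.interpolate_mass(s, 9.0, 8.2)
        m = traj["mass_g"].to_numpy()
        assert m[0] == 9.0
        assert m[-1] == pytest.approx(8.2, abs=1e-9)
        assert (np.diff(m) <= 1e-15).all()
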