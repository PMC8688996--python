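"""Micro-variable extraction: hand-computed oracles and catalogue checks."""

import numpy as np
import pytest

from swimphase import features as feat
from swimphase import orientation as ori
from swimphase import segmentation as seg
from swimphase.features import (
    UndefinedFeature,
    catalogue_columns,
    distance_per_stroke,
    efficiency_ratios,
    extract_micro_variables,
    integral_and_momentum,
    signal_stats,
    swim_velocity_profile,
)


def _grid(T=2.0, fs=1000.0):
    n = int(T * fs)
    return np.arange(n) / fs


class TestSignalStats:
    def test_constant_signal(self):
        t = _grid()
        st = signal_stats(t, np.full_like(t, 2.0), (0.0, 2.0))
        assert st == {"mean": 2.0, "range": 0.0, "sd": 0.0, "max": 2.0}

    def test_three_point_hand_computation(self):
        t = np.arange(3) / 500.0
        x = np.array([-1.0, 0.0, 1.0])
        st = signal_stats(t, x, (0.0, 1.0))
        assert st["mean"] == pytest.approx(0.0)
        assert st["range"] == pytest.approx(2.0)
        assert st["sd"] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert st["max"] == pytest.approx(1.0)

    def test_sine_over_whole_periods(self):
        t = _grid(T=4.0)
        x = 3.0 * np.sin(2 * np.pi * 1.0 * t)
        st = signal_stats(t, x, (0.0, 4.0))
        assert abs(st["mean"]) < 1e-3
        assert st["range"] == pytest.approx(6.0, rel=1e-3)

    def test_empty_interval_raises(self):
        t = _grid()
        with pytest.raises(ValueError, match="empty interval"):
            signal_stats(t, t, (5.0, 6.0))


class TestIntegralAndMomentum:
    def test_constant_acceleration(self):
        t = _grid(T=2.0)
        out = integral_and_momentum(t, np.ones_like(t), (0.0, 2.0))
        assert out["int"] == pytest.approx(2.0, rel=1e-3)
        assert out["momentum"] == pytest.approx(2.0, rel=1e-3)

    def test_positive_then_negative_square_wave(self):
        t = _grid(T=2.0)
        a = np.where(t < 1.0, 1.0, -1.0)
        out = integral_and_momentum(t, a, (0.0, 2.0))
        assert out["int"] == pytest.approx(0.0, abs=2e-3)
        assert out["momentum"] == pytest.approx(1.0, rel=2e-3)

    def test_zero_signal(self):
        t = _grid()
        out = integral_and_momentum(t, np.zeros_like(t), (0.0, 2.0))
        assert out["int"] == 0.0 and out["momentum"] == 0.0


class TestEfficiencyRatios:
    def test_symmetric_square_wave(self):
        t = _grid(T=2.0)
        acc = np.zeros((len(t), 3))
        acc[:, 1] = np.where((t * 2).astype(int) % 2 == 0, 1.0, -1.0)
        out = efficiency_ratios(t, acc, (0.0, 2.0))
        assert out["eff"] == pytest.approx(1.0, rel=5e-3)
        assert out["eff_dir"] == pytest.approx(0.5, rel=5e-3)

    def test_all_positive_forward_acceleration_is_undefined(self):
        t = _grid()
        acc = np.zeros((len(t), 3))
        acc[:, 1] = 1.0
        with pytest.raises(UndefinedFeature, match="Eff undefined"):
            efficiency_ratios(t, acc, (0.0, 2.0))

    def test_pure_forward_positive_gives_eff_dir_one(self):
        t = _grid()
        acc = np.zeros((len(t), 3))
        acc[:, 1] = np.where(t < 1.9, 2.0, -0.1)  # tiny negative tail defines Eff
        out = efficiency_ratios(t, acc, (0.0, 2.0))
        assert out["eff_dir"] == pytest.approx(
            (2.0 * 1.9) / (2.0 * 1.9 + 0.1 * 0.1), rel=1e-2
        )

    def test_ranges_when_defined(self, rng):
        t = _grid()
        acc = rng.normal(size=(len(t), 3))
        out = efficiency_ratios(t, acc, (0.0, 2.0))
        assert out["eff"] > 0
        assert 0 < out["eff_dir"] <= 1


class TestDistancePerStroke:
    def test_constant_velocity(self):
        t = _grid(T=2.0)
        assert distance_per_stroke(t, np.full_like(t, 1.5), (0.0, 1.2)) == pytest.approx(
            1.8, rel=1e-3
        )

    def test_sinusoidal_velocity_over_full_cycle(self):
        t = _grid(T=2.0)
        v = 1.5 + 0.2 * np.sin(2 * np.pi * 1.0 * t)
        assert distance_per_stroke(t, v, (0.0, 1.0)) == pytest.approx(1.5, rel=1e-3)

    def test_short_cycle_warns(self):
        t = _grid()
        with pytest.warns(RuntimeWarning, match="0.3 s"):
            distance_per_stroke(t, np.ones_like(t), (0.0, 0.2))


def _full_extraction(lap):
    rec_a = ori.apply_calibration(lap.imu_sensor, lap.calibration)
    q0 = ori.estimate_initial_orientation(rec_a.slice(0.5, 5.5))
    tr = ori.fuse_orientation(rec_a, q0)
    rec_g = ori.rotate_to_global(rec_a, tr)
    cyc = seg.separate_cycles(
        rec_a, lap.annotation.phases["Swim"], lap.scenario.technique
    )
    return extract_micro_variables(
        rec_g, rec_a, tr, lap.annotation, cyc, lap.scenario.technique
    ), cyc


class TestExtractMicroVariables:
    def test_catalogue_complete_and_exact(self, default_lap):
        fx, _ = _full_extraction(default_lap)
        assert set(fx.lap_row.index) == set(catalogue_columns())
        assert len(fx.lap_row) == 126
        assert fx.lap_row.notna().all()

    def test_cycle_rows_cover_cycle_catalogue(self, default_lap):
        fx, cyc = _full_extraction(default_lap)
        assert list(fx.cycle_rows.columns) == ["cycle_index", *feat.CYCLE_COLUMNS]
        assert len(fx.cycle_rows) == cyc.n_cycles

    def test_stroke_count_and_rate_consistent(self, default_lap):
        fx, cyc = _full_extraction(default_lap)
        row = fx.lap_row
        assert row["Swim.StrokeCount"] == cyc.n_cycles
        dur = default_lap.annotation.duration("Swim")
        assert row["Swim.StrokeRate"] == pytest.approx(60.0 * cyc.n_cycles / dur)

    def test_stroke_rate_tracks_generator(self, default_lap):
        fx, _ = _full_extraction(default_lap)
        # rate in 1/min vs the generating stroke frequency in Hz
        assert fx.lap_row["Swim.StrokeRate"] == pytest.approx(
            60.0 * default_lap.scenario.stroke_rate, rel=0.10
        )

    def test_kick_count_tracks_generator(self, quiet_lap):
        fx, _ = _full_extraction(quiet_lap)
        sc = quiet_lap.scenario
        expected = sc.kick_rate * sc.stpr_duration
        assert abs(fx.lap_row["StPr.KickCount"] - expected) <= 1.5

    def test_dps_within_5_percent_of_generator(self, default_lap):
        lap = default_lap
        rec_a = ori.apply_calibration(lap.imu_sensor, lap.calibration)
        q0 = ori.estimate_initial_orientation(rec_a.slice(0.5, 5.5))
        tr = ori.fuse_orientation(rec_a, q0)
        from swimphase.pipeline import _strapdown_global

        rec_gv = _strapdown_global(rec_a, tr, lap.annotation.lap[0] - 1.0)
        ts, vs = swim_velocity_profile(rec_gv, lap.annotation)
        cyc = lap.cycles_true
        dps = np.mean([distance_per_stroke(ts, vs, c) for c in cyc.intervals()])
        dps_true = np.mean(
            np.asarray(lap.goals_true.swim_vavg_cycle) * np.diff(cyc.boundaries)
        )
        assert dps == pytest.approx(dps_true, rel=0.05)

    def test_reference_trace_path_for_velocity(self, default_lap):
        lap = default_lap
        rec_a = ori.apply_calibration(lap.imu_sensor, lap.calibration)
        q0 = ori.estimate_initial_orientation(rec_a.slice(0.5, 5.5))
        tr = ori.fuse_orientation(rec_a, q0)
        rec_g = ori.rotate_to_global(rec_a, tr)
        ts, vs = swim_velocity_profile(rec_g, lap.annotation, lap.reference)
        v_true = np.interp(
            ts - lap.annotation.lap[0], lap.reference.t, lap.reference.v
        )
        assert np.allclose(vs, v_true)

    def test_stats_invariant_to_sampling_rate_doubling(self):
        # band-limited signal sampled at fs and 2 fs: integral-based features agree
        for fs in (500.0, 1000.0):
            t = np.arange(int(4 * fs)) / fs
            acc = np.zeros((len(t), 3))
            acc[:, 1] = np.sin(2 * np.pi * 2.0 * t) + 0.3
            out = efficiency_ratios(t, acc, (0.0, 4.0))
            im = integral_and_momentum(t, acc[:, 1], (0.0, 4.0))
            if fs == 500.0:
                ref = (out, im)
        assert out["eff"] == pytest.approx(ref[0]["eff"], rel=0.01)
        assert out["eff_dir"] == pytest.approx(ref[0]["eff_dir"], rel=0.01)
        assert im["int"] == pytest.approx(ref[1]["int"], rel=0.01)
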