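"""Waveform-derived variables, trimmed means, exclusions and 30-s binning,
each checked against an independent brute-force oracle where one exists."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import zero_noise_disc, zero_noise_traj
from svagree import beats as bp
from svagree import cohort
from svagree.errors import InvalidArgumentError


def brute_trapz(trace, fs):
    """Independent trapezoidal integral by explicit summation."""
    total = 0.0
    for a, b in zip(trace[:-1], trace[1:]):
        total += 0.5 * (a + b) / fs
    return total


class TestTimeWeightedMap:
    def test_constant_pressure(self):
        assert bp.time_weighted_map(np.full(500, 100.0), 1000.0) == pytest.approx(100.0)

    def test_linear_ramp_symmetry(self):
        p = np.linspace(80.0, 120.0, 701)
        assert bp.time_weighted_map(p, 1000.0) == pytest.approx(100.0)

    def test_triangular_pulse_matches_brute_force(self, rng):
        p = 80.0 + 40.0 * np.concatenate([np.linspace(0, 1, 300),
                                          np.linspace(1, 0, 500)])
        fs = 1000.0
        expected = brute_trapz(p, fs) / ((p.size - 1) / fs)
        assert bp.time_weighted_map(p, fs) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_random_traces_match_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 400))
        p = r.normal(90.0, 15.0, n)
        fs = float(r.choice([250.0, 500.0, 1000.0]))
        expected = brute_trapz(p, fs) / ((n - 1) / fs)
        assert bp.time_weighted_map(p, fs) == pytest.approx(expected, rel=1e-9)

    def test_window_selection_and_errors(self):
        p = np.full(1000, 90.0)
        assert bp.time_weighted_map(p, 1000.0, window=(0.2, 0.7)) == pytest.approx(90.0)
        with pytest.raises(InvalidArgumentError):
            bp.time_weighted_map(p, 1000.0, window=(0.5, 0.5005))  # < 2 samples
        with pytest.raises(InvalidArgumentError):
            bp.time_weighted_map(p, 1000.0, window=(0.9, 1.4))


class TestVelocityTimeIntegral:
    def test_constant_velocity(self):
        v = np.full(401, 0.5)  # 0.4 s at 1000 Hz
        assert bp.velocity_time_integral(v, 1000.0) == pytest.approx(20.0, rel=1e-6)

    def test_half_sine_closed_form(self):
        # VTI of a half-sine with peak A over duration T is 2 A T / pi
        fs = 10_000.0
        t = np.arange(int(0.3 * fs) + 1) / fs
        v = np.sin(np.pi * t / 0.3)
        expected = 2 * 1.0 * 0.3 / np.pi * 100.0  # 19.10 cm
        assert bp.velocity_time_integral(v, fs) == pytest.approx(expected, rel=1e-4)
        assert bp.velocity_time_integral(v, fs) == pytest.approx(19.10, abs=0.01)

    def test_zero_and_negative_traces(self, caplog):
        assert bp.velocity_time_integral(np.zeros(100), 1000.0) == 0.0
        with caplog.at_level(logging.WARNING, logger="svagree.beats"):
            out = bp.velocity_time_integral(np.full(100, -0.2), 1000.0)
        assert out == 0.0
        assert any("negative" in r.message for r in caplog.records)

    def test_negative_part_clipped(self):
        v = np.concatenate([np.full(100, 0.5), np.full(100, -0.3)])
        pos = bp.velocity_time_integral(np.clip(v, 0, None), 1000.0)
        assert bp.velocity_time_integral(v, 1000.0) == pytest.approx(pos)


class TestLvotAndSv:
    def test_area_examples(self):
        assert bp.lvot_area(2.0) == pytest.approx(math.pi)
        assert bp.lvot_area(2.3) == pytest.approx(4.1548, abs=1e-4)
        with pytest.raises(InvalidArgumentError):
            bp.lvot_area(0.0)

    def test_geometry_dataclass(self):
        geo = bp.LvotGeometry(diameter=2.3)
        assert geo.area == pytest.approx(bp.lvot_area(2.3))
        with pytest.raises(InvalidArgumentError):
            bp.LvotGeometry(diameter=-1.0)

    def test_sv_from_vti(self):
        assert bp.sv_from_vti(20.0, 3.5) == pytest.approx(70.0)
        assert bp.sv_from_vti(0.0, 3.5) == 0.0
        # composition of the half-sine VTI and the d=2.3 area examples
        vti = 2 * 0.3 / np.pi * 100.0
        assert bp.sv_from_vti(vti, bp.lvot_area(2.3)) == pytest.approx(79.35, abs=0.02)
        with pytest.raises(InvalidArgumentError):
            bp.sv_from_vti(-1.0, 3.5)


class TestWaveformRoundTrip:
    """Synthesized beat waveforms reproduce MAP and SV when re-analyzed."""

    class Beat:
        rr, map, sv_us = 0.9, 95.0, 70.0

    def test_pressure_round_trip(self):
        p, _ = cohort.synthesize_beat_waveforms(self.Beat, 1000.0)
        assert bp.time_weighted_map(p, 1000.0) == pytest.approx(95.0, rel=5e-3)

    def test_constant_pressure_limit(self):
        beat = self.Beat()
        p, _ = cohort.synthesize_beat_waveforms(beat, 500.0, pulse_pressure=0.0)
        assert np.allclose(p, beat.map)
        assert bp.time_weighted_map(p, 500.0) == pytest.approx(beat.map)

    def test_velocity_round_trip(self):
        _, v = cohort.synthesize_beat_waveforms(self.Beat, 1000.0,
                                                lvot_area_cm2=3.5)
        vti = bp.velocity_time_integral(v, 1000.0)
        assert bp.sv_from_vti(vti, 3.5) == pytest.approx(70.0, rel=5e-3)

    def test_too_short_beat_rejected(self):
        class Short:
            rr, map, sv_us = 0.005, 90.0, 70.0
        with pytest.raises(InvalidArgumentError):
            cohort.synthesize_beat_waveforms(Short, 100.0)
        with pytest.raises(InvalidArgumentError):
            cohort.synthesize_beat_waveforms(self.Beat, 50.0)


def brute_trimmed_mean(values, trim):
    v = sorted(values)
    k = math.ceil(trim * len(v))
    if 2 * k >= len(v):
        return sum(v) / len(v)
    kept = v[k:len(v) - k]
    return sum(kept) / len(kept)


class TestTrimmedMean:
    def test_hand_computed_examples(self):
        assert bp.trimmed_mean(range(1, 21)) == pytest.approx(10.5)
        assert bp.trimmed_mean([7.0] * 13) == pytest.approx(7.0)
        vals = list(range(1, 11)) + [1000.0]
        # ceil(0.05 * 11) = 1 per tail: removes 1000 and the minimum
        assert bp.trimmed_mean(vals) == pytest.approx(np.mean(range(2, 11)))

    @given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=120),
           st.floats(0.0, 0.49))
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force(self, values, trim):
        assert bp.trimmed_mean(values, trim) == pytest.approx(
            brute_trimmed_mean(values, trim), rel=1e-9, abs=1e-9)

    def test_errors(self):
        with pytest.raises(InvalidArgumentError):
            bp.trimmed_mean([])
        with pytest.raises(InvalidArgumentError):
            bp.trimmed_mean([1.0, 2.0], trim_fraction=0.5)


def _toy_cohort(n=2, seed=4, **disc_kw):
    traj = zero_noise_traj()
    disc = zero_noise_disc(**disc_kw)
    config = cohort.ProtocolConfig()
    beats, profiles = cohort.simulate_cohort(
        n, config, traj, disc, dropout_dist={60.0: 1.0}, rng_seed=seed)
    sched = cohort.schedules_for_profiles(config, profiles)
    return beats, profiles, sched


class TestExcludePostIhg:
    def test_half_open_window_boundaries(self):
        beats = pd.DataFrame({
            "subject_id": ["A"] * 3,
            "t_onset": [239.9, 240.0 + 29.9, 240.0 + 30.0],
            "x": [1, 2, 3],
        })
        out = bp.exclude_post_ihg(beats, {"A": [240.0]})
        assert list(out["t_onset"]) == [239.9, 270.0]

    def test_matches_brute_force_interval_scan(self):
        beats, profiles, sched = _toy_cohort(n=1)
        releases = next(iter(sched.values())).ihg_release_times
        assert len(releases) >= 2
        out = bp.exclude_post_ihg(beats, sched)
        removed = len(beats) - len(out)
        brute = sum(
            any(rel <= t < rel + 30.0 for rel in releases)
            for t in beats["t_onset"])
        assert removed == brute
        kept_mask = [not any(rel <= t < rel + 30.0 for rel in releases)
                     for t in beats["t_onset"]]
        assert np.array_equal(out["t_onset"].to_numpy(),
                              beats.loc[kept_mask, "t_onset"].to_numpy())

    def test_idempotent_and_empty(self):
        beats, _, sched = _toy_cohort(n=1)
        once = bp.exclude_post_ihg(beats, sched)
        twice = bp.exclude_post_ihg(once, sched)
        pd.testing.assert_frame_equal(once, twice)
        empty = bp.exclude_post_ihg(beats.iloc[0:0], sched)
        assert empty.empty


class TestDropIncompleteLevels:
    def test_levels_above_stop_removed(self):
        beats = pd.DataFrame({"subject_id": ["A", "A", "B"],
                              "lbnp": [40.0, 60.0, 80.0]})
        profiles = pd.DataFrame({"subject_id": ["A", "B"],
                                 "decompensation_level": [40.0, 80.0]})
        out = bp.drop_incomplete_levels(beats, profiles)
        assert list(zip(out["subject_id"], out["lbnp"])) == [("A", 40.0), ("B", 80.0)]

    def test_retained_level_sets_match_profiles(self):
        beats, profiles, _ = _toy_cohort(n=4, seed=9)
        # push one subject's stop level down to mix completion patterns
        profiles = profiles.copy()
        profiles.loc[0, "decompensation_level"] = 20.0
        out = bp.drop_incomplete_levels(beats, profiles)
        for _, row in profiles.iterrows():
            levels = set(out.loc[out["subject_id"] == row["subject_id"], "lbnp"])
            expected = {x for x in (0.0, 20.0, 40.0, 60.0, 80.0)
                        if x <= row["decompensation_level"]} & set(beats["lbnp"])
            assert levels == expected

    def test_unknown_subject_rejected(self):
        beats = pd.DataFrame({"subject_id": ["Z"], "lbnp": [0.0]})
        profiles = pd.DataFrame({"subject_id": ["A"], "decompensation_level": [80.0]})
        with pytest.raises(InvalidArgumentError):
            bp.drop_incomplete_levels(beats, profiles)


class TestBin30s:
    def test_four_bins_per_period(self):
        beats, _, sched = _toy_cohort(n=1)
        bins = bp.bin_30s(beats, sched)
        one_period = bins.loc[(bins["level_index"] == 0) & (bins["phase"] == "ihg")]
        assert list(one_period["period_time_bin"]) == [0, 1, 2, 3]

    def test_constant_signals_give_constants(self):
        beats, _, sched = _toy_cohort(n=1, delta0=10.0)
        lvl0 = beats.loc[beats["level_index"] == 0]
        bins = bp.bin_30s(lvl0, sched)
        rest = bins.loc[bins["phase"] == "rest"]
        traj = zero_noise_traj()
        assert np.allclose(rest["sv_us"], traj.sv_baseline)
        assert np.allclose(rest["sv_pwa"] - rest["sv_us"], rest["diff"])
        assert np.allclose(rest["hr"], traj.hr_baseline)

    def test_noisy_bins_match_brute_force(self):
        config = cohort.ProtocolConfig()
        beats, profiles = cohort.simulate_cohort(2, config, rng_seed=21)
        bins = bp.bin_30s(beats)
        # re-aggregate one variable per bin with the scalar trimmed mean
        for _, row in bins.sample(12, random_state=0).iterrows():
            sel = beats.loc[
                (beats["subject_id"] == row["subject_id"])
                & (beats["t_onset"] >= row["bin_start"])
                & (beats["t_onset"] < row["bin_start"] + 30.0)]
            assert len(sel) == row["n_beats_used"]
            assert row["sv_us"] == pytest.approx(bp.trimmed_mean(sel["sv_us"]))
            assert row["map"] == pytest.approx(bp.trimmed_mean(sel["map"]))
            assert row["hr"] == pytest.approx(bp.trimmed_mean(60.0 / sel["rr"]))

    def test_derived_columns_consistent(self, small_bins):
        b = small_bins
        assert np.allclose(b["diff"], b["sv_pwa"] - b["sv_us"])
        assert np.allclose(b["mean"], (b["sv_pwa"] + b["sv_us"]) / 2)
        assert np.allclose(b["co_us"], b["sv_us"] * b["hr"] / 1000.0)
        assert np.allclose(b["svr_us"], b["map"] / b["co_us"])

    def test_zero_noise_svr_matches_latent(self):
        beats, profiles, sched = _toy_cohort(n=2)
        bins = bp.bin_30s(beats, sched)
        traj = zero_noise_traj()
        config = cohort.ProtocolConfig()
        mid = bins["bin_start"].to_numpy() % config.period_duration + 15.0
        svr_lat = traj.latent_svr(bins["level_index"], mid,
                                  bins["phase"] == "ihg", config.period_duration)
        assert np.allclose(bins["svr_us"], svr_lat, rtol=1e-3)

    def test_sparse_bins_dropped(self):
        beats, _, sched = _toy_cohort(n=1)
        sparse = beats.groupby(
            beats["t_onset"] // 30).head(3)  # keep only 3 beats per 30 s
        bins = bp.bin_30s(sparse, None)
        assert bins.empty

    def test_overlapping_schedule_rejected(self):
        from svagree.cohort import Period, ProtocolSchedule
        bad = ProtocolSchedule("A", (
            Period(0.0, 0, 0, "stabilization", 0.0, 120.0),
            Period(0.0, 0, 1, "ihg", 100.0, 220.0)), (220.0,))
        beats, _, _ = _toy_cohort(n=1)
        with pytest.raises(Exception):
            bp.bin_30s(beats, bad)
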