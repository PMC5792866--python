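import numpy as np
import pandas as pd
import pytest

from movebreak import SimConfig, response_profile, simulate_depth_series, simulate_track
from movebreak.diveprofile import detect_dives
from movebreak.geotrack import compute_steps


class TestSimConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(duration_h=100.0, exposure_time_h=120.0)
        with pytest.raises(ValueError):
            SimConfig(gps_fix_prob=0.0)
        with pytest.raises(ValueError):
            SimConfig(noise_recovery_h=-1.0)
        with pytest.raises(ValueError):
            SimConfig(ar1_phi=1.0)

    def test_round_trips_through_json(self, tmp_path):
        cfg = SimConfig(rng_seed=5, exposure_time_h=77.0)
        cfg.to_json(tmp_path / "c.json")
        assert SimConfig.from_json(tmp_path / "c.json") == cfg


class TestResponseProfile:
    def test_capture_decay_shape(self):
        cfg = SimConfig()
        c = cfg.capture_effect["speed"]
        assert response_profile(0.0, cfg, "speed") == pytest.approx(c)
        mid = response_profile(cfg.capture_recovery_h / 2, cfg, "speed")
        assert mid == pytest.approx(c / 2)
        assert response_profile(cfg.capture_recovery_h + 1.0, cfg, "speed") == 0.0

    def test_noise_plateau_and_ramp(self):
        cfg = SimConfig(noise_effect={"dive_duration": -5.0, "max_depth": -4.0})
        e, pl, nr = cfg.exposure_time_h, cfg.noise_plateau_h, cfg.noise_recovery_h
        assert response_profile(e, cfg, "dive_duration") == pytest.approx(-5.0)
        assert response_profile(e + pl, cfg, "dive_duration") == pytest.approx(-5.0)
        # halfway down the recovery ramp: half the offset remains
        assert response_profile(e + pl + nr / 2, cfg, "max_depth") == pytest.approx(-2.0)
        assert response_profile(e + pl + nr + 0.1, cfg, "max_depth") == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            response_profile(-0.5, SimConfig(), "speed")

    def test_baseline_between_disturbances(self):
        cfg = SimConfig()
        t = np.linspace(cfg.capture_recovery_h + 0.1, cfg.exposure_time_h - 0.1, 50)
        assert np.all(response_profile(t, cfg, "speed") == 0.0)


class TestSimulateTrack:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(duration_h=30.0, exposure_time_h=20.0, capture_recovery_h=6.0, rng_seed=3)
        t1, _ = simulate_track(cfg)
        t2, _ = simulate_track(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_quiet_config_constant_speed_and_turning(self, quiet_sim_config):
        track, _ = simulate_track(quiet_sim_config)
        steps = compute_steps(track)
        # speeds constant at the baseline, turning angles constant too
        assert steps["speed_mps"].std() < 1e-3
        assert steps["speed_mps"].mean() == pytest.approx(
            quiet_sim_config.baseline["speed"], rel=1e-3
        )
        turning = steps["turning_angle_deg"].dropna()
        assert turning.std() < 1e-3

    def test_capture_speed_offset_recovered(self):
        # Monte-Carlo: mean speed in the first hour should exceed the
        # late-baseline mean by the injected effect (decay-adjusted)
        diffs = []
        for seed in range(20):
            cfg = SimConfig(
                duration_h=60.0, exposure_time_h=50.0, capture_recovery_h=18.0,
                diel_amplitude={"speed": 0.0, "turning_angle": 0.0},
                noise_effect={}, rng_seed=seed, gps_fix_prob=1.0,
            )
            track, _ = simulate_track(cfg)
            steps = compute_steps(track)
            t = steps["time_since_release_h"]
            first = steps.loc[t < 1.0, "speed_mps"].mean()
            base = steps.loc[(t > 24) & (t < 48), "speed_mps"].mean()
            diffs.append(first - base)
        diffs = np.asarray(diffs)
        # mean injected offset over the first hour: 5 * (1 - 0.5/18)
        expected = 5.0 * (1.0 - 0.5 / 18.0)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - expected) < 3 * se + 0.05

    def test_gps_thinning_rate(self):
        cfg = SimConfig(duration_h=48.0, exposure_time_h=40.0, capture_recovery_h=6.0,
                        gps_fix_prob=0.25, rng_seed=1)
        thinned, _ = simulate_track(cfg)
        full, _ = simulate_track(
            SimConfig(**{**cfg.to_dict(), "gps_fix_prob": 1.0})
        )
        ratio = len(thinned) / len(full)
        assert ratio == pytest.approx(0.25, abs=0.02)

    def test_truth_breakpoints(self):
        cfg = SimConfig()
        _, truth = simulate_track(cfg)
        e, pl, nr = cfg.exposure_time_h, cfg.noise_plateau_h, cfg.noise_recovery_h
        assert truth.breakpoints["speed"] == [cfg.capture_recovery_h, e, e + pl, e + pl + nr]
        assert truth.breakpoints["speed"] == sorted(truth.breakpoints["speed"])
        assert truth.slopes["speed"][0] == pytest.approx(-5.0 / cfg.capture_recovery_h)


class TestSimulateDepthSeries:
    def test_deterministic_and_continuous_1hz(self):
        cfg = SimConfig(duration_h=26.0, exposure_time_h=25.0, capture_recovery_h=5.0, rng_seed=9)
        d1, _ = simulate_depth_series(cfg)
        d2, _ = simulate_depth_series(cfg)
        pd.testing.assert_frame_equal(d1, d2)
        dt = d1["timestamp"].diff().dropna().dt.total_seconds()
        assert (dt == 1.0).all()
        assert (d1["depth_m"] >= 0).all()

    def test_quiet_config_identical_dives(self, quiet_sim_config):
        depth, _ = simulate_depth_series(quiet_sim_config)
        dives = detect_dives(depth)
        assert len(dives) > 100
        assert dives["max_depth_m"].std() < 1e-9
        assert dives["duration_s"].std() < 1e-9

    def test_noise_depth_offset_recovered(self):
        # mean max depth in the plateau window drops by the injected ~2 m
        deltas = []
        for seed in range(8):
            cfg = SimConfig(
                duration_h=140.0, exposure_time_h=96.0,
                diel_amplitude={p: 0.0 for p in ("dive_duration", "max_depth", "wiggliness", "post_dive_duration")},
                capture_effect={}, noise_effect={"max_depth": -2.0},
                noise_plateau_h=8.0, rng_seed=seed,
            )
            depth, _ = simulate_depth_series(cfg)
            dives = detect_dives(depth)
            t = dives["time_since_release_h"]
            plateau = dives.loc[(t >= 96) & (t <= 104), "max_depth_m"].mean()
            base = dives.loc[(t > 30) & (t < 90), "max_depth_m"].mean()
            deltas.append(plateau - base)
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean() - (-2.0)) < 3 * se + 0.1

    def test_truth_for_dive_duration(self):
        cfg = SimConfig()
        _, truth = simulate_depth_series(cfg)
        e, pl, nr = cfg.exposure_time_h, cfg.noise_plateau_h, cfg.noise_recovery_h
        assert truth.breakpoints["dive_duration"] == [
            cfg.capture_recovery_h, e, e + pl, e + pl + nr,
        ]
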