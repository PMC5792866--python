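import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from movebreak import geotrack as gt
from conftest import track_from_points

coord = st.tuples(
    st.floats(min_value=-80, max_value=80),
    st.floats(min_value=-179, max_value=179),
)


class TestHaversine:
    def test_one_degree_latitude_at_equator(self):
        # closed form: pi * R / 180
        d = gt.haversine_m(0.0, 0.0, 1.0, 0.0)
        assert d == pytest.approx(111_194.9, abs=100)

    def test_one_degree_longitude_at_55N(self):
        d = gt.haversine_m(55.0, 11.0, 55.0, 12.0)
        assert d == pytest.approx(111_194.9 * np.cos(np.radians(55.0)), rel=1e-4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=coord, b=coord, c=coord)
    def test_symmetry_and_triangle_inequality(self, a, b, c):
        dab = gt.haversine_m(*a, *b)
        assert dab == pytest.approx(gt.haversine_m(*b, *a), rel=1e-12, abs=1e-9)
        assert dab <= gt.haversine_m(*a, *c) + gt.haversine_m(*c, *b) + 1e-6

    def test_destination_point_round_trip(self):
        lat, lon = gt.destination_point(56.0, 11.0, 37.0, 5000.0)
        assert gt.haversine_m(56.0, 11.0, lat, lon) == pytest.approx(5000.0, rel=1e-9)
        assert gt.initial_bearing_deg(56.0, 11.0, lat, lon) == pytest.approx(37.0, abs=1e-6)


class TestScreenOutliers:
    def test_stationary_track_untouched(self):
        track = track_from_points([(56.0, 11.0)] * 5)
        screened, removed = gt.screen_outliers(track)
        assert removed == 0 and len(screened) == 5

    def test_out_and_back_spike_removed(self):
        # B is ~5 km north reached in 60 s (300 km/h), track returns to A
        a = (56.0, 11.0)
        b = gt.destination_point(*a, 0.0, 5000.0)
        track = track_from_points([a, b, a], step_s=60)
        screened, removed = gt.screen_outliers(track)
        assert removed == 1
        assert screened["lat"].tolist() == [a[0], a[0]]

    def test_steady_transit_untouched(self):
        # 10 km/h straight-line transit is below the 15 km/h threshold
        pts = [gt.destination_point(56.0, 11.0, 90.0, 10_000.0 / 3600 * 60 * i) for i in range(20)]
        track = track_from_points(pts, step_s=60)
        screened, removed = gt.screen_outliers(track)
        assert removed == 0

    def test_fast_transit_without_return_kept(self):
        # fast but consistently directed movement is not an outlier
        pts = [gt.destination_point(56.0, 11.0, 90.0, 400.0 * 60 * i) for i in range(5)]
        track = track_from_points(pts, step_s=60)  # 24 km/h, no return
        _, removed = gt.screen_outliers(track)
        assert removed == 0

    def test_iterative_removal_of_masked_spike(self):
        # b (300 m out, 18 km/h) is only exposed as an out-and-back spike
        # after the larger spike c (4 km out) has been removed
        a = (56.0, 11.0)
        b = gt.destination_point(*a, 0.0, 300.0)
        c = gt.destination_point(*a, 0.0, 4000.0)
        track = track_from_points([a, b, c, a, a], step_s=60)
        screened, removed = gt.screen_outliers(track)
        assert removed == 2
        assert np.allclose(screened["lat"], a[0])
        # idempotent once converged
        _, removed2 = gt.screen_outliers(screened)
        assert removed2 == 0

    def test_short_track_noop_with_warning(self):
        track = track_from_points([(56.0, 11.0), (56.1, 11.0)])
        with pytest.warns(UserWarning):
            _, removed = gt.screen_outliers(track)
        assert removed == 0


class TestComputeSteps:
    def test_collinear_meridian_fixes_have_zero_turning(self):
        track = track_from_points([(56.0, 11.0), (56.1, 11.0), (56.2, 11.0), (56.3, 11.0)])
        steps = gt.compute_steps(track)
        assert np.isnan(steps["turning_angle_deg"].iloc[0])
        assert steps["turning_angle_deg"].iloc[1:].abs().max() < 1e-6

    def test_out_and_back_turning_angle_180(self):
        track = track_from_points([(56.0, 11.0), (56.1, 11.0), (56.0, 11.0)])
        steps = gt.compute_steps(track)
        assert steps["turning_angle_deg"].iloc[1] == pytest.approx(180.0, abs=1e-6)

    def test_speed_is_length_over_elapsed(self):
        track = track_from_points([(0.0, 0.0), (1.0, 0.0)], step_s=3600)
        steps = gt.compute_steps(track)
        assert steps["speed_mps"].iloc[0] == pytest.approx(
            steps["step_length_m"].iloc[0] / 3600.0
        )
        assert steps["step_length_m"].iloc[0] == pytest.approx(111_194.9, abs=100)

    def test_turning_invariant_under_rotation(self):
        rng = np.random.default_rng(3)
        headings = rng.uniform(0, 360, 8)
        lengths = rng.uniform(500, 3000, 8)

        def build(offset):
            pts = [(10.0, 20.0)]
            for h, d in zip(headings, lengths):
                pts.append(gt.destination_point(*pts[-1], (h + offset) % 360.0, d))
            return gt.compute_steps(track_from_points(pts, step_s=600))

        base = build(0.0)["turning_angle_deg"].to_numpy()[1:]
        rotated = build(117.0)["turning_angle_deg"].to_numpy()[1:]
        np.testing.assert_allclose(base, rotated, atol=1e-3)

    def test_zero_elapsed_step_rejected(self):
        t0 = pd.Timestamp("2014-06-02T12:00:00Z")
        track = pd.DataFrame(
            {
                "timestamp": [t0, t0 + pd.Timedelta("1h"), t0 + pd.Timedelta("1h")],
                "lat": [56.0, 56.1, 56.2],
                "lon": [11.0, 11.0, 11.0],
            }
        )
        with pytest.raises(ValueError):
            gt.compute_steps(track)  # duplicate timestamp violates track invariant


class TestDisplacement:
    def test_reference_at_first_fix(self):
        track = track_from_points([(56.0, 11.0), (56.2, 11.0), (56.4, 11.0)])
        per_fix, _ = gt.displacement(track, (56.0, 11.0))
        assert per_fix["distance_km"].iloc[0] == 0.0
        assert per_fix["distance_km"].is_monotonic_increasing

    def test_longitude_offset_at_55N(self):
        track = track_from_points([(55.0, 12.0)])
        per_fix, _ = gt.displacement(track, (55.0, 11.0))
        assert per_fix["distance_km"].iloc[0] == pytest.approx(63.78, abs=0.05)

    def test_windowed_headings(self):
        # 21 hourly fixes moving steadily east: every 10 h window heads ~90 deg
        pts = [gt.destination_point(56.0, 11.0, 90.0, 2000.0 * i) for i in range(21)]
        _, windows = gt.displacement(track_from_points(pts), (56.0, 11.0))
        assert len(windows) >= 2
        assert np.allclose(windows["heading_deg"], 90.0, atol=1.0)
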