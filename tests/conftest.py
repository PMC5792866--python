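import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def quiet_sim_config():
    """Simulation config with all variability and effects switched off."""
    from movebreak import SimConfig

    zero = {p: 0.0 for p in (
        "speed", "turning_angle", "dive_duration", "max_depth", "wiggliness",
        "post_dive_duration",
    )}
    return SimConfig(
        duration_h=48.0,
        exposure_time_h=24.0,
        capture_recovery_h=6.0,
        gps_fix_prob=1.0,  # keep every surfacing: apparent speed == true speed
        diel_amplitude=dict(zero),
        residual_sd=dict(zero),
        capture_effect=dict(zero),
        noise_effect=dict(zero),
        rng_seed=7,
    )


def piecewise_signal(x, psi, slopes, intercept=0.0):
    """Continuous broken-line signal used as ground truth in several tests."""
    x = np.asarray(x, dtype=float)
    y = intercept + slopes[0] * x
    for j, p in enumerate(psi):
        y = y + (slopes[j + 1] - slopes[j]) * np.clip(x - p, 0.0, None)
    return y


@pytest.fixture
def fig2_hourly():
    """Noise-free hourly residuals with the canonical 4-breakpoint response.

    Capture offset decaying to zero at 18 h, baseline until the exposure at
    96 h, an abrupt shift held to 102 h, recovery ramp to 126 h, then
    baseline to 240 h.
    """
    x = np.arange(240, dtype=float) + 0.5
    psi = np.array([18.0, 96.0, 102.0, 126.0])
    slopes = np.array([-5.0 / 18.0, 0.0, 2.0 / 6.0, -2.0 / 24.0, 0.0])
    return x, piecewise_signal(x, psi, slopes, intercept=5.0), psi, slopes


def track_from_points(points, start="2014-06-02T12:00:00Z", step_s=3600):
    """GeoTrack DataFrame from a list of (lat, lon), hourly by default."""
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "timestamp": [t0 + pd.Timedelta(seconds=i * step_s) for i in range(len(points))],
            "lat": [p[0] for p in points],
            "lon": [p[1] for p in points],
        }
    )
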