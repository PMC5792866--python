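"""GPS track screening and horizontal movement parameters.

A track is a pandas DataFrame with columns ``timestamp`` (UTC), ``lat``
and ``lon`` (WGS84 degrees), one row per retained GPS fix, strictly
increasing in time. From consecutive fixes three movement parameters are
extracted: step length (m), speed (m/s) and absolute turning angle
(0-180 degrees, 0 = directed linear movement, 180 = full reversal).
Distances are great-circle (haversine, spherical Earth R = 6371 km) and
bearings use the initial-bearing convention on the same sphere; at step
lengths of a few kilometres the spherical approximation differs from an
ellipsoidal one by far less than GPS fix error.

Positional outliers are screened with an impossible-movement rule: a fix
is removed when it implies an unlikely swimming speed (> 15 km/h by
default) AND the track returns essentially to where it came from in the
next move. Screening is re-applied until no fix qualifies, because a
single spike can mask a second.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_m",
    "initial_bearing_deg",
    "destination_point",
    "validate_track",
    "screen_outliers",
    "compute_steps",
    "displacement",
    "read_track_csv",
    "write_track_csv",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance in metres between WGS84 coordinates (degrees).

    Accepts scalars or numpy arrays (broadcast).
    """
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return radius * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial (forward) bearing from point 1 to point 2, degrees in [0, 360)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    y = np.sin(dlmb) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlmb)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination_point(lat, lon, bearing_deg, distance_m, radius: float = EARTH_RADIUS_M):
    """Point reached from (lat, lon) along an initial bearing for a distance.

    Spherical direct geodesic; used by the track simulator.
    """
    delta = distance_m / radius
    theta = np.radians(bearing_deg)
    phi1, lmb1 = np.radians(lat), np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lmb2 = lmb1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return np.degrees(phi2), (np.degrees(lmb2) + 540.0) % 360.0 - 180.0


def validate_track(track: pd.DataFrame) -> pd.DataFrame:
    """Check track invariants; returns the frame with parsed UTC timestamps."""
    required = {"timestamp", "lat", "lon"}
    missing = required - set(track.columns)
    if missing:
        raise ValueError(f"track missing columns: {sorted(missing)}")
    out = track.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)
    if not out["timestamp"].is_monotonic_increasing or out["timestamp"].duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    if (out["lat"].abs() > 90).any() or (out["lon"].abs() > 180).any():
        raise ValueError("coordinates outside valid WGS84 bounds")
    return out.reset_index(drop=True)


def screen_outliers(
    track: pd.DataFrame,
    speed_threshold_kmh: float = 15.0,
    return_fraction: float = 0.1,
    return_floor_m: float = 100.0,
) -> tuple[pd.DataFrame, int]:
    """Remove positional outliers by the impossible-movement rule.

    Fix i is removed iff the speed on the incoming step i-1 -> i exceeds
    ``speed_threshold_kmh`` AND the track returns to (nearly) the same
    site in the subsequent move: dist(i-1, i+1) < max(return_floor_m,
    return_fraction * dist(i-1, i)). Removal is repeated until no fix
    qualifies. Returns the screened track and the number removed.
    """
    track = validate_track(track)
    if len(track) < 3:
        warnings.warn("fewer than 3 fixes: outlier screening skipped", stacklevel=2)
        return track, 0
    removed = 0
    thresh_ms = speed_threshold_kmh / 3.6
    while len(track) >= 3:
        lat = track["lat"].to_numpy()
        lon = track["lon"].to_numpy()
        t = track["timestamp"].astype("int64").to_numpy() / 1e9
        d_in = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])  # step i-1 -> i
        dt = np.diff(t)
        speed = d_in / dt
        # candidate interior fixes i = 1..n-2
        d_skip = haversine_m(lat[:-2], lon[:-2], lat[2:], lon[2:])  # i-1 -> i+1
        excursion = d_in[:-1]
        ret_radius = np.maximum(return_floor_m, return_fraction * excursion)
        bad = (speed[:-1] > thresh_ms) & (d_skip < ret_radius)
        if not bad.any():
            break
        i = int(np.argmax(bad)) + 1  # leftmost offender, one at a time
        logger.info(
            "removing fix %s at %s: speed %.1f km/h, return distance %.0f m",
            i,
            track["timestamp"].iloc[i],
            speed[i - 1] * 3.6,
            d_skip[i - 1],
        )
        track = track.drop(track.index[i]).reset_index(drop=True)
        removed += 1
    return track, removed


def compute_steps(
    track: pd.DataFrame, release_time: pd.Timestamp | None = None
) -> pd.DataFrame:
    """Per-step horizontal movement parameters from a screened track.

    One row per step between consecutive fixes with step_length_m,
    elapsed_s, speed_mps, heading_deg, and turning_angle_deg (absolute
    change in heading folded into [0, 180]; undefined for the first step).
    ``time_since_release_h`` is the step midpoint relative to
    ``release_time`` (default: first fix). Steps with zero elapsed time are
    rejected with a warning.
    """
    track = validate_track(track)
    if len(track) < 2:
        raise ValueError("need at least 2 fixes to compute steps")
    lat = track["lat"].to_numpy()
    lon = track["lon"].to_numpy()
    ts = track["timestamp"]
    t = ts.astype("int64").to_numpy() / 1e9
    elapsed = np.diff(t)
    if (elapsed <= 0).any():
        n_bad = int((elapsed <= 0).sum())
        warnings.warn(f"{n_bad} step(s) with non-positive elapsed time rejected", stacklevel=2)
    length = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    heading = initial_bearing_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dh = np.abs(np.diff(heading))
    turning = np.concatenate([[np.nan], np.minimum(dh, 360.0 - dh)])
    release = pd.Timestamp(release_time) if release_time is not None else ts.iloc[0]
    if release.tzinfo is None:
        release = release.tz_localize("UTC")
    rel_s = release.value / 1e9
    mid_h = ((t[:-1] + t[1:]) / 2.0 - rel_s) / 3600.0
    steps = pd.DataFrame(
        {
            "start": ts.iloc[:-1].to_numpy(),
            "end": ts.iloc[1:].to_numpy(),
            "step_length_m": length,
            "elapsed_s": elapsed,
            "speed_mps": np.where(elapsed > 0, length / np.where(elapsed > 0, elapsed, 1.0), np.nan),
            "heading_deg": heading,
            "turning_angle_deg": turning,
            "time_since_release_h": mid_h,
        }
    )
    return steps[elapsed > 0].reset_index(drop=True)


def displacement(
    track: pd.DataFrame,
    reference: tuple[float, float],
    heading_window_h: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Displacement from a reference site and windowed net-movement headings.

    Returns ``(per_fix, per_window)``: per fix the great-circle distance
    (km) to ``reference`` (e.g. release or exposure site); per consecutive
    ``heading_window_h``-hour window the compass heading of the net
    movement from the first to the last fix inside the window (windows
    with fewer than 2 fixes are skipped). These serve as diagnostics
    independent of the statistical response modelling.
    """
    track = validate_track(track)
    dist_km = haversine_m(
        track["lat"].to_numpy(), track["lon"].to_numpy(), reference[0], reference[1]
    ) / 1000.0
    per_fix = pd.DataFrame(
        {"timestamp": track["timestamp"], "distance_km": dist_km}
    )
    t0 = track["timestamp"].iloc[0]
    hours = (track["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    rows = []
    for w in range(int(np.floor(hours[-1] / heading_window_h)) + 1):
        mask = (hours >= w * heading_window_h) & (hours < (w + 1) * heading_window_h)
        idx = np.flatnonzero(mask)
        if len(idx) < 2:
            continue
        a, b = idx[0], idx[-1]
        rows.append(
            {
                "window_start_h": w * heading_window_h,
                "heading_deg": float(
                    initial_bearing_deg(
                        track["lat"].iloc[a],
                        track["lon"].iloc[a],
                        track["lat"].iloc[b],
                        track["lon"].iloc[b],
                    )
                ),
                "net_distance_km": float(
                    haversine_m(
                        track["lat"].iloc[a],
                        track["lon"].iloc[a],
                        track["lat"].iloc[b],
                        track["lon"].iloc[b],
                    )
                )
                / 1000.0,
            }
        )
    return per_fix, pd.DataFrame(rows, columns=["window_start_h", "heading_deg", "net_distance_km"])


def read_track_csv(path) -> pd.DataFrame:
    """Read a GPS track CSV (timestamp, lat, lon; ISO-8601 UTC timestamps)."""
    return validate_track(pd.read_csv(path))


def write_track_csv(track: pd.DataFrame, path) -> None:
    out = track.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f%z"
    )
    out.to_csv(path, index=False)
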