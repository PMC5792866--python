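"""Dive detection and vertical movement parameters from 1 Hz depth traces.

A depth series is a DataFrame with ``timestamp`` (UTC) and ``depth_m``
(positive down), nominally one sample per second. A dive is a maximal run
of samples at or below the dive threshold depth (default 2 m) lasting at
least ``min_duration`` seconds. For each dive four parameters are
extracted: total duration (s), maximum depth (m), wiggliness (m; the
summed absolute vertical displacement within the bottom phase, a common
index of prey-chasing intensity) and the post-dive surface duration (s,
undefined for the last dive).

The bottom phase is the contiguous window from the first to the last
sample at >= ``bottom_fraction`` (default 0.8) of the dive's maximum
depth. Sampling gaps longer than ``max_gap_s`` split the record; putative
dives containing internal gaps are flagged and excluded rather than
patched. No zero-offset (surface drift) correction is applied by default;
a simple linear-drift corrector is available but off, as transducer drift
over deployments of a few days is typically negligible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "validate_depth_series",
    "detect_dives",
    "bottom_phase",
    "wiggliness",
    "correct_linear_drift",
    "read_depth_csv",
    "write_depth_csv",
]


def validate_depth_series(series: pd.DataFrame) -> pd.DataFrame:
    required = {"timestamp", "depth_m"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"depth series missing columns: {sorted(missing)}")
    out = series.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)
    if not out["timestamp"].is_monotonic_increasing or out["timestamp"].duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    if (out["depth_m"] < -0.5).any():
        raise ValueError("depths below -0.5 m: sensor offset too large")
    return out.reset_index(drop=True)


def bottom_phase(depths: np.ndarray, fraction: float = 0.8) -> tuple[int, int]:
    """Index window [i0, i1] from first to last sample >= fraction * max depth.

    The window is contiguous by construction (it spans any interior
    excursions above the cutoff).
    """
    depths = np.asarray(depths, dtype=float)
    if len(depths) < 3:
        raise ValueError("bottom phase requires at least 3 samples")
    cutoff = fraction * depths.max()
    at_bottom = np.flatnonzero(depths >= cutoff)
    return int(at_bottom[0]), int(at_bottom[-1])


def wiggliness(depths: np.ndarray, fraction: float = 0.8) -> float:
    """Summed absolute vertical displacement (m) within the bottom phase."""
    depths = np.asarray(depths, dtype=float)
    i0, i1 = bottom_phase(depths, fraction)
    return float(np.abs(np.diff(depths[i0 : i1 + 1])).sum())


def detect_dives(
    series: pd.DataFrame,
    dive_threshold: float = 2.0,
    min_duration: float = 5.0,
    bottom_fraction: float = 0.8,
    max_gap_s: float = 5.0,
    release_time: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Detect dives and compute the four vertical movement parameters.

    Returns one row per dive: start, end, duration_s, max_depth_m,
    wiggliness_m, post_dive_duration_s (gap to the next dive's start; NaN
    for the last dive) and time_since_release_h (dive start relative to
    ``release_time``, default first sample). An empty or all-surface
    series yields an empty frame. Gaps > ``max_gap_s`` split the series;
    dives truncated by a gap are excluded.
    """
    series = validate_depth_series(series)
    cols = [
        "start",
        "end",
        "duration_s",
        "max_depth_m",
        "wiggliness_m",
        "post_dive_duration_s",
        "time_since_release_h",
    ]
    if len(series) < 2:
        return pd.DataFrame(columns=cols)
    t = series["timestamp"].astype("int64").to_numpy() / 1e9
    depth = series["depth_m"].to_numpy(dtype=float)
    release = (
        pd.Timestamp(release_time) if release_time is not None else series["timestamp"].iloc[0]
    )
    if release.tzinfo is None:
        release = release.tz_localize("UTC")
    rel_s = release.value / 1e9

    gap_after = np.diff(t) > max_gap_s
    seg_starts = np.concatenate([[0], np.flatnonzero(gap_after) + 1])
    seg_ends = np.concatenate([np.flatnonzero(gap_after), [len(t) - 1]])

    rows = []
    for s0, s1 in zip(seg_starts, seg_ends):
        sub_depth = depth[s0 : s1 + 1]
        sub_t = t[s0 : s1 + 1]
        deep = sub_depth >= dive_threshold
        if not deep.any():
            continue
        edges = np.diff(deep.astype(int))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1)
        if deep[0]:
            starts = np.concatenate([[0], starts])
        if deep[-1]:
            ends = np.concatenate([ends, [len(deep) - 1]])
        for a, b in zip(starts, ends):
            # a dive touching a segment boundary may be truncated by a gap
            if (a == 0 and s0 != 0) or (b == len(deep) - 1 and s1 != len(t) - 1):
                continue
            duration = sub_t[b] - sub_t[a]
            if duration < min_duration:
                continue
            dive_depths = sub_depth[a : b + 1]
            rows.append(
                {
                    "start": pd.Timestamp(sub_t[a], unit="s", tz="UTC"),
                    "end": pd.Timestamp(sub_t[b], unit="s", tz="UTC"),
                    "duration_s": float(duration),
                    "max_depth_m": float(dive_depths.max()),
                    "wiggliness_m": wiggliness(dive_depths, bottom_fraction)
                    if len(dive_depths) >= 3
                    else 0.0,
                    "start_s": sub_t[a],
                    "end_s": sub_t[b],
                }
            )
    if not rows:
        return pd.DataFrame(columns=cols)
    dives = pd.DataFrame(rows).sort_values("start_s").reset_index(drop=True)
    post = dives["start_s"].to_numpy()[1:] - dives["end_s"].to_numpy()[:-1]
    dives["post_dive_duration_s"] = np.concatenate([post, [np.nan]])
    dives["time_since_release_h"] = (dives["start_s"] - rel_s) / 3600.0
    return dives[cols]


def correct_linear_drift(
    series: pd.DataFrame, surface_quantile: float = 0.1
) -> pd.DataFrame:
    """Remove a linear transducer drift estimated from near-surface samples.

    Fits depth ~ time on the shallowest ``surface_quantile`` of samples
    within each hour and subtracts the fitted line from all samples
    (clipping at -0.5 m). Off by default in the pipeline.
    """
    series = validate_depth_series(series)
    t = series["timestamp"].astype("int64").to_numpy() / 1e9
    depth = series["depth_m"].to_numpy(dtype=float)
    hours = np.floor((t - t[0]) / 3600.0)
    anchors_t, anchors_d = [], []
    for h in np.unique(hours):
        m = hours == h
        q = np.quantile(depth[m], surface_quantile)
        sel = m & (depth <= q)
        anchors_t.append(t[sel].mean())
        anchors_d.append(depth[sel].mean())
    if len(anchors_t) >= 2:
        slope, intercept = np.polyfit(anchors_t, anchors_d, 1)
        drift = slope * t + intercept
    else:
        drift = np.full_like(depth, float(np.mean(anchors_d)))
    out = series.copy()
    out["depth_m"] = np.maximum(depth - drift, -0.5)
    return out


def read_depth_csv(path) -> pd.DataFrame:
    return validate_depth_series(pd.read_csv(path))


def write_depth_csv(series: pd.DataFrame, path) -> None:
    out = series.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    out.to_csv(path, index=False)
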