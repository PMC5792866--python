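"""Received airgun noise-level estimation from range and source levels.

A single small airgun is characterised by back-calculated source levels at
1 m in three metrics — peak-to-peak sound pressure level (L_pp), RMS level
over a 125 ms window approximating the porpoise auditory integration time
(L_eq-fast), and sound exposure level (SEL, the pressure-squared time
integral over 1 s) — and an empirical log-range transmission-loss model
TL(r) = coeff * log10(r), with r in metres, fitted for shallow water.

The received level of each metric at range r is simply source - TL(r).
Because GPS fixes are intermittent, the animal's true range at exposure is
taken to lie within +/-50 % of the nominal fix-derived range; levels are
reported as (mean at r, min at the far bound, max at the near bound),
rounded to the nearest integer dB for tabulation.

Audiogram (frequency) weighting of SELs requires band-level spectra that
this package does not model; a scalar ``weighting_offset_db`` hook is
provided so that an externally derived broadband weighting correction can
be applied, but no weighted levels are claimed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SourceLevels",
    "ExposureEstimate",
    "transmission_loss",
    "received_levels",
    "exposure_with_range_error",
    "range_to_exposure",
    "exposure_table",
    "round_db",
]

#: metric keys in canonical report order
METRICS = ("L_pp", "L_eq_fast", "SEL")


@dataclass(frozen=True)
class SourceLevels:
    """Airgun source levels at 1 m and the transmission-loss coefficient.

    Defaults are for a 10 cubic-inch sleeve airgun fired at ~125 bar in
    shallow (~15 m) water: 216 dB re 1 uPa peak-peak, 195 dB re 1 uPa RMS
    over 125 ms, 186 dB re 1 uPa^2 s, with TL = 17 log10(r).
    """

    l_pp: float = 216.0
    l_eq_fast: float = 195.0
    sel: float = 186.0
    tl_coefficient: float = 17.0
    #: optional scalar correction (dB) subtracted from received levels to
    #: approximate audiogram weighting; 0 = unweighted.
    weighting_offset_db: float = 0.0

    def __post_init__(self) -> None:
        for name in ("l_pp", "l_eq_fast", "sel", "weighting_offset_db"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (self.tl_coefficient > 0 and math.isfinite(self.tl_coefficient)):
            raise ValueError("tl_coefficient must be positive and finite")

    def as_dict(self) -> dict[str, float]:
        return {"L_pp": self.l_pp, "L_eq_fast": self.l_eq_fast, "SEL": self.sel}


def round_db(x: float) -> int:
    """Round to the nearest integer dB, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def transmission_loss(r: float, coeff: float = 17.0) -> float:
    """Log-range transmission loss coeff * log10(r), r in metres.

    The model is calibrated from a 1 m source level, so ranges below 1 m
    are outside its domain.
    """
    if r < 1.0:
        raise ValueError(f"range {r} m < 1 m: transmission-loss model undefined")
    return coeff * math.log10(r)


@dataclass
class ExposureEstimate:
    """Received levels at a nominal range with a fractional range error.

    ``levels`` maps each metric to (mean, min, max) unrounded dB where the
    mean is evaluated at ``range_m``, the max at the near bound and the min
    at the far bound. ``rounded`` holds the same triple rounded to integer
    dB for reporting.
    """

    range_m: float
    range_bounds_m: tuple[float, float]
    levels: dict[str, tuple[float, float, float]]
    rounded: dict[str, tuple[int, int, int]] = field(init=False)

    def __post_init__(self) -> None:
        for metric, (mean, lo, hi) in self.levels.items():
            if not (lo <= mean <= hi):
                raise ValueError(f"{metric}: min <= mean <= max violated")
        self.rounded = {
            m: tuple(round_db(v) for v in triple) for m, triple in self.levels.items()
        }


def received_levels(src: SourceLevels, r: float) -> ExposureEstimate:
    """Received L_pp / L_eq-fast / SEL at a single range (no range error)."""
    return exposure_with_range_error(src, r, frac=0.0)


def exposure_with_range_error(
    src: SourceLevels, r: float, frac: float = 0.5
) -> ExposureEstimate:
    """Received levels at r with bounds at (1 +/- frac) * r.

    The maximum level is attained at the near bound (1-frac)*r and the
    minimum at the far bound (1+frac)*r.
    """
    if not 0.0 <= frac < 1.0:
        raise ValueError("frac must be in [0, 1)")
    near, far = (1.0 - frac) * r, (1.0 + frac) * r
    if near < 1.0:
        raise ValueError(f"near range bound {near} m < 1 m")
    levels: dict[str, tuple[float, float, float]] = {}
    for metric, source in src.as_dict().items():
        mean = source - transmission_loss(r, src.tl_coefficient)
        hi = source - transmission_loss(near, src.tl_coefficient)
        lo = source - transmission_loss(far, src.tl_coefficient)
        offset = src.weighting_offset_db
        levels[metric] = (mean - offset, lo - offset, hi - offset)
    return ExposureEstimate(range_m=r, range_bounds_m=(near, far), levels=levels)


def range_to_exposure(
    track: pd.DataFrame,
    exposure_site: tuple[float, float],
    exposure_time: pd.Timestamp,
    max_offset_h: float = 6.0,
) -> tuple[float, float]:
    """Great-circle range (m) from the fix nearest in time to the exposure.

    Returns ``(range_m, time_offset_s)`` where the offset is signed
    (fix time minus exposure time). Ties between two equidistant fixes go
    to the earlier one. A warning is issued when the nearest fix is more
    than ``max_offset_h`` hours from the exposure.
    """
    from .geotrack import haversine_m

    if len(track) < 1:
        raise ValueError("track must contain at least one fix")
    ts = pd.to_datetime(track["timestamp"])
    offsets = (ts - pd.Timestamp(exposure_time)).dt.total_seconds().to_numpy()
    # stable argmin on |offset| prefers the earlier fix on exact ties
    idx = int(np.lexsort((offsets, np.abs(offsets)))[0])
    row = track.iloc[idx]
    r = haversine_m(
        row["lat"], row["lon"], exposure_site[0], exposure_site[1]
    )
    if abs(offsets[idx]) > max_offset_h * 3600.0:
        warnings.warn(
            f"nearest fix is {offsets[idx] / 3600.0:.1f} h from the exposure; "
            "range estimate unreliable",
            stacklevel=2,
        )
    return float(r), float(offsets[idx])


def exposure_table(
    ranges_m: dict[str, float],
    src: SourceLevels | None = None,
    frac: float = 0.5,
) -> pd.DataFrame:
    """Tabulate received levels for several individuals.

    ``ranges_m`` maps individual id -> nominal range. One row per
    individual with the rounded mean and [min-max] for each metric,
    mirroring the exposure-summary layout used in field reports.
    """
    src = src or SourceLevels()
    rows = []
    for ind, r in ranges_m.items():
        est = exposure_with_range_error(src, r, frac=frac)
        row: dict[str, object] = {
            "id": ind,
            "range_m": est.range_m,
            "range_near_m": est.range_bounds_m[0],
            "range_far_m": est.range_bounds_m[1],
        }
        for metric in METRICS:
            mean, lo, hi = est.rounded[metric]
            row[f"{metric}_mean_dB"] = mean
            row[f"{metric}_min_dB"] = lo
            row[f"{metric}_max_dB"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
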