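"""Translate validated breakpoints into disturbance-response durations.

The expected response pattern to the two disturbances is: (1) altered
behaviour immediately after capture/tagging that decays back to baseline —
its duration is the time from release (hour 0) to the first validated
breakpoint; (2) an abrupt noise-induced change whose onset breakpoint
coincides with the exposure time, lasting until the next breakpoint, with a
further recovery ramp back to baseline ending at the breakpoint after
that. Animals may show only some (or none) of these; absence of a response
is a valid outcome, and breakpoints far from either event are reported as
unrelated behavioural changes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .breakpoints import BreakpointEstimate, BreakpointValidation, PiecewiseFit

__all__ = ["DisturbanceTimes", "ResponseSummary", "classify"]


@dataclass(frozen=True)
class DisturbanceTimes:
    """Disturbance schedule on the hours-since-release clock (release = 0)."""

    exposure_h: float
    release_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.exposure_h > self.release_h:
            raise ValueError("exposure must occur after release")


@dataclass
class ResponseSummary:
    """Per-parameter response durations implied by the validated breakpoints."""

    capture_recovery_h: float | None = None
    noise_response: bool = False
    noise_onset_h: float | None = None
    noise_response_h: float | None = None
    noise_recovery_h: float | None = None
    coinciding_breakpoint: int | None = None  # index into the sorted breakpoints
    unrelated_breakpoints_h: list[float] | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def classify(
    estimates: list[BreakpointEstimate],
    times: DisturbanceTimes,
    validation: BreakpointValidation | None = None,
    fit: PiecewiseFit | None = None,
    tolerance_h: float = 2.0,
    strict: bool = True,
) -> ResponseSummary:
    """Derive capture-recovery and noise-response durations from breakpoints.

    ``estimates`` must be sorted by location; their ``validated`` flags are
    taken from ``validation`` when given (otherwise from the estimates
    themselves). The capture-recovery duration is the earliest validated
    breakpoint minus the release time. A noise response is declared iff
    some validated breakpoint psi_j lies within ``tolerance_h`` of the
    exposure time OR its bootstrap CI contains the exposure, AND the
    segment slope after psi_j is significantly non-zero. The response
    duration is then psi_{j+1} - psi_j and the recovery duration
    psi_{j+2} - psi_{j+1}, when those later breakpoints exist (and, in
    ``strict`` mode, are themselves validated); otherwise the field is
    absent (None).
    """
    if tolerance_h < 0:
        raise ValueError("tolerance must be >= 0")
    psi = np.array([e.psi for e in estimates], dtype=float)
    if np.any(np.diff(psi) < 0):
        raise ValueError("breakpoint estimates must be sorted by location")
    if validation is not None:
        validated = np.asarray(validation.accepted, dtype=bool)
        slope_sig = np.asarray(validation.slope_significant, dtype=bool)
    else:
        validated = np.array([e.validated for e in estimates], dtype=bool)
        slope_sig = None

    summary = ResponseSummary(unrelated_breakpoints_h=[])
    if len(psi) == 0:
        return summary

    val_idx = np.flatnonzero(validated)
    if len(val_idx):
        summary.capture_recovery_h = float(psi[val_idx[0]] - times.release_h)

    exposure = times.exposure_h
    onset = None
    for j in val_idx:
        coincides = abs(psi[j] - exposure) <= tolerance_h
        ci_covers = (
            np.isfinite(estimates[j].ci_low)
            and np.isfinite(estimates[j].ci_high)
            and estimates[j].ci_low <= exposure <= estimates[j].ci_high
        )
        if not (coincides or ci_covers):
            continue
        post_slope_ok = bool(slope_sig[j + 1]) if slope_sig is not None else True
        if post_slope_ok:
            onset = int(j)
            break

    if onset is not None:
        summary.noise_response = True
        summary.coinciding_breakpoint = onset
        summary.noise_onset_h = float(psi[onset])

        def _usable(i: int) -> bool:
            if i >= len(psi):
                return False
            return bool(validated[i]) if strict else True

        if _usable(onset + 1):
            summary.noise_response_h = float(psi[onset + 1] - psi[onset])
            if _usable(onset + 2):
                summary.noise_recovery_h = float(psi[onset + 2] - psi[onset + 1])

    related = set()
    if len(val_idx):
        related.add(int(val_idx[0]))
    if onset is not None:
        related.update({onset, onset + 1, onset + 2})
    summary.unrelated_breakpoints_h = [
        float(psi[j]) for j in val_idx if int(j) not in related
    ]
    return summary
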