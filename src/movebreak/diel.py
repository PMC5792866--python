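"""Diel-baseline removal: cyclic hour-of-day smoother and hourly residuals.

Free-ranging animals show pronounced 24 h (diel) cycles and strong
individual differences in movement behaviour. Before any disturbance
response can be timed, each movement parameter is therefore regressed, per
individual, on local hour of the day using a cyclic smoother, and the
analysis proceeds on the raw residuals (data minus fitted values): a
residual of zero is the individual's undisturbed baseline.

The smoother is a truncated Fourier (harmonic) regression on hour of day,

    m(h) = a0 + sum_{j=1..k} [ a_j cos(2 pi j h / 24) + b_j sin(2 pi j h / 24) ],

which is exactly periodic with matching derivatives at h = 0/24 by
construction. The number of harmonics k (0..max_harmonics) is chosen by
generalized cross-validation, GCV(k) = n * RSS / (n - p)^2 with
p = 2k + 1 coefficients. Because consecutive steps or dives are serially
correlated, coefficients are optionally re-estimated by iterative feasible
GLS under an AR(1) error process on the observation (event) scale; the
reported residuals are always on the raw scale regardless.

Residuals are then averaged within whole hours since release — the finest
scale that avoids gaps from intermittent GPS sampling, and a step that
further dilutes serial correlation — giving the hourly residual series
that the breakpoint model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BaselineFit", "fit_cyclic_baseline", "hourly_mean_residuals", "harmonic_design"]


class DielSpanError(ValueError):
    """Series too short to identify a 24 h cycle."""


def harmonic_design(hour_of_day: np.ndarray, k: int) -> np.ndarray:
    """Design matrix [1, cos(2pi j h/24), sin(2pi j h/24)] for j = 1..k."""
    h = np.asarray(hour_of_day, dtype=float)
    cols = [np.ones_like(h)]
    for j in range(1, k + 1):
        w = 2.0 * np.pi * j * h / 24.0
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


@dataclass
class BaselineFit:
    """Fitted cyclic diel baseline for one movement parameter and individual."""

    parameter: str
    n_harmonics: int
    coef: np.ndarray
    gcv: float
    phi: float  # AR(1) coefficient of the event-scale residuals (0 if not used)
    time_since_release_h: np.ndarray
    hour_of_day: np.ndarray
    values: np.ndarray
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, hour_of_day) -> np.ndarray:
        """Evaluate the fitted cyclic mean function m(hour)."""
        return harmonic_design(np.atleast_1d(hour_of_day), self.n_harmonics) @ self.coef


def _estimate_phi(resid: np.ndarray) -> float:
    """Lag-1 autocorrelation of a residual sequence, clipped to [0, 0.99]."""
    r = resid - resid.mean()
    denom = float(r @ r)
    if denom <= 0:
        return 0.0
    phi = float(r[:-1] @ r[1:]) / denom
    return float(np.clip(phi, 0.0, 0.99))


def fit_cyclic_baseline(
    series: pd.DataFrame,
    parameter: str | None = None,
    max_harmonics: int = 6,
    use_ar1: bool = True,
    max_fgls_iter: int = 50,
    phi_tol: float = 1e-4,
) -> BaselineFit:
    """Fit the GCV-selected cyclic harmonic baseline to one movement series.

    ``series`` needs columns ``time_since_release_h``, ``hour_of_day`` and
    ``value`` (one parameter per series, times increasing). Requires at
    least 48 observations spanning at least 24 h, otherwise the diel cycle
    is unidentifiable and a :class:`DielSpanError` is raised.

    With ``use_ar1`` the coefficients are re-estimated by Prais-Winsten
    feasible GLS, iterating between the AR(1) coefficient phi (lag-1
    autocorrelation of the raw residuals in event order) and the
    transformed least-squares fit until phi changes by < ``phi_tol``.
    Residuals returned are raw (value minus m(hour)) either way.
    """
    t = series["time_since_release_h"].to_numpy(dtype=float)
    h = series["hour_of_day"].to_numpy(dtype=float)
    y = series["value"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("observations must be ordered in time")
    if len(y) < 48:
        raise DielSpanError(f"need >= 48 observations, got {len(y)}")
    if t[-1] - t[0] < 24.0:
        raise DielSpanError(
            f"series spans {t[-1] - t[0]:.1f} h < 24 h: diel cycle unidentifiable"
        )

    n = len(y)
    best = None
    for k in range(0, max_harmonics + 1):
        p = 2 * k + 1
        if n <= p:
            break
        X = harmonic_design(h, k)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        gcv = n * rss / (n - p) ** 2
        if best is None or gcv < best[0] - 1e-12:
            best = (gcv, k, coef)
    gcv, k, coef = best
    X = harmonic_design(h, k)
    resid = y - X @ coef
    phi = 0.0

    if use_ar1:
        phi = _estimate_phi(resid)
        for _ in range(max_fgls_iter):
            # Prais-Winsten transform assuming event-scale AR(1)
            Xt = X.copy()
            yt = y.copy()
            Xt[1:] = X[1:] - phi * X[:-1]
            yt[1:] = y[1:] - phi * y[:-1]
            s = np.sqrt(1.0 - phi**2)
            Xt[0] *= s
            yt[0] *= s
            coef, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
            resid = y - X @ coef
            phi_new = _estimate_phi(resid)
            if abs(phi_new - phi) < phi_tol:
                phi = phi_new
                break
            phi = phi_new

    fitted = X @ coef
    resid = y - fitted
    return BaselineFit(
        parameter=parameter or str(series.get("parameter", pd.Series(["value"])).iloc[0]),
        n_harmonics=k,
        coef=coef,
        gcv=gcv,
        phi=phi,
        time_since_release_h=t,
        hour_of_day=h,
        values=y,
        fitted=fitted,
        residuals=resid,
    )


def hourly_mean_residuals(fit: BaselineFit) -> pd.DataFrame:
    """Mean raw residual per whole hour since release.

    Bins are half-open [h, h+1); hours with no observations are absent
    (a gap), never zero-filled. Returns columns ``hour`` (bin start, int),
    ``mean_residual`` and ``n_obs``.
    """
    hours = np.floor(fit.time_since_release_h).astype(int)
    df = pd.DataFrame({"hour": hours, "residual": fit.residuals})
    out = (
        df.groupby("hour")["residual"]
        .agg(mean_residual="mean", n_obs="size")
        .reset_index()
        .sort_values("hour")
        .reset_index(drop=True)
    )
    out["n_obs"] = out["n_obs"].astype(int)
    return out
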