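"""Static diagnostic plots: hourly residuals with fitted broken-line segments."""

from __future__ import annotations

import numpy as np

from .breakpoints import BreakpointEstimate, PiecewiseFit

__all__ = ["plot_fit"]


def plot_fit(
    hourly,
    fit: PiecewiseFit,
    estimates: list[BreakpointEstimate] | None = None,
    exposure_h: float | None = None,
    parameter: str = "residual",
    ax=None,
):
    """Residuals, fitted segments, breakpoint CIs and the exposure time.

    ``hourly`` is the hourly-residual frame (columns ``hour`` and
    ``mean_residual``). Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.2))
    x = hourly["hour"].to_numpy(dtype=float)
    y = hourly["mean_residual"].to_numpy(dtype=float)
    ax.scatter(x, y, s=8, color="0.6", label="hourly residuals")
    grid = np.linspace(x.min(), x.max(), 500)
    ax.plot(grid, fit.predict(grid), color="C3", lw=1.8, label=f"{fit.k}-breakpoint fit")
    for est in estimates or []:
        ax.axvline(est.psi, color="C0", lw=1.0, alpha=0.8)
        if np.isfinite(est.ci_low) and np.isfinite(est.ci_high):
            ax.axvspan(est.ci_low, est.ci_high, color="C0", alpha=0.15)
    if exposure_h is not None:
        ax.axvline(exposure_h, color="k", ls="--", lw=1.0, label="exposure")
    ax.axhline(0.0, color="0.8", lw=0.8, zorder=0)
    ax.set_xlabel("time since release (h)")
    ax.set_ylabel(f"{parameter} residual")
    ax.legend(loc="best", fontsize=8)
    return ax
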