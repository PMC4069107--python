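"""Static figures for rate maps, single-run fits and summary scatters."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_rate_map", "plot_run_fit", "plot_slope_scatter"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_rate_map(rm, fields=None, ax=None):
    ax = _ax(ax)
    extent = [rm.x_edges[0], rm.x_edges[-1], rm.y_edges[0], rm.y_edges[-1]]
    im = ax.imshow(rm.rate, origin="lower", extent=extent, cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label="rate (Hz)")
    if fields:
        for f in fields:
            ax.contour(f.mask, levels=[0.5], extent=extent, colors="w", linewidths=0.8)
            ax.plot(*f.peak_xy, "r+")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    return ax


def plot_run_fit(run, fit, ax=None):
    """Spike phases vs distance with the fitted circular-linear line
    (plotted twice, shifted by 360 deg, as is conventional)."""
    ax = _ax(ax)
    ax.plot(run.spike_dist_cm, run.spike_phase_deg, "k.", ms=8)
    xs = np.linspace(0, run.path_length, 100)
    line = (fit.offset_deg + fit.slope * xs) % 360.0
    for shift in (0.0, 360.0):
        ax.plot(xs, line + shift, "r-", lw=1)
    ax.set_ylim(0, 720)
    ax.set_xlabel("distance in field (cm)")
    ax.set_ylabel("theta phase (deg)")
    ax.set_title(f"m = {fit.slope:.1f} deg/cm, r = {fit.r:.2f}")
    return ax


def plot_slope_scatter(fits, prop, ax=None):
    ax = _ax(ax)
    ax.plot(fits[prop], fits["slope"], ".", alpha=0.5)
    ax.set_xlabel(prop)
    ax.set_ylabel("slope (deg/cm)")
    return ax
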