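"""Rendering of rate maps and drift curves to standard image files."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from conjgrid.analysis import RateMap

__all__ = ["plot_rate_map", "plot_drift", "plot_speed_curve"]


def plot_rate_map(rm: RateMap, path, title: str = "", cmap: str = "viridis"):
    """Render a 1D or 2D rate map; non-sampled bins are shown in white."""
    fig, ax = plt.subplots(figsize=(4, 3.2))
    if rm.rate.ndim == 1:
        x = rm.centers[0]
        ax.plot(x, rm.rate, lw=1.5)
        ax.set_xlabel("position (cm)")
        ax.set_ylabel("rate")
    else:
        cm = plt.get_cmap(cmap).copy()
        cm.set_bad("white")
        data = np.ma.masked_invalid(rm.rate.T)
        ex = [rm.edges[0][0], rm.edges[0][-1], rm.edges[1][0], rm.edges[1][-1]]
        im = ax.imshow(data, origin="lower", extent=ex, aspect="auto", cmap=cm)
        fig.colorbar(im, ax=ax, label="rate")
        ax.set_xlabel("x (cm)")
        ax.set_ylabel("y (cm)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_drift(t_ms, drift_cm, path, spacing: float | None = None):
    """Drift (|tracking error|) over time, with the half-spacing reference."""
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(np.asarray(t_ms) / 1000.0, drift_cm, lw=1.0)
    if spacing is not None:
        ax.axhline(spacing / 2.0, color="gray", lw=0.8, ls="--",
                   label="half spacing")
        ax.legend(frameon=False)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("drift (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_speed_curve(vhat, measured, predicted, path):
    """Intrinsic bump speed vs velocity-axis position with the ring law."""
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.plot(vhat, predicted, "k-", lw=1.2, label="ring law")
    ax.plot(vhat, measured, "o", ms=4, label="network")
    ax.set_xlabel("velocity-axis position")
    ax.set_ylabel("bump speed (rad/ms)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
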