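"""Rendering of high-resolution bullseye plots.

One polar panel per slice, drawn as 600 concentric-ring wedge patches
(10 transmural rings by 60 angular bins).  The subendocardium is the
innermost ring; angle zero (the anterior RV insertion point) points up
and angles increase clockwise, so the septum sits to the viewer's left
for a standard short-axis orientation.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib import cm, colors  # noqa: E402

from .bullseye import N_ANGLES, N_LAYERS, BullseyeGrid

__all__ = ["plot_bullseye"]


def plot_bullseye(grid: BullseyeGrid, path=None, vmin=None, vmax=None,
                  cmap="inferno", title=None):
    """Render a three-panel bullseye figure; optionally save to ``path``."""
    values = grid.values
    finite = values[np.isfinite(values)]
    if vmin is None:
        vmin = float(finite.min()) if finite.size else 0.0
    if vmax is None:
        vmax = float(finite.max()) if finite.size else 1.0
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    mapper = cm.ScalarMappable(norm=norm, cmap=cmap)

    fig, axes = plt.subplots(
        1, 3, subplot_kw={"projection": "polar"}, figsize=(12, 4.2)
    )
    dtheta = 2 * np.pi / N_ANGLES
    ii, jj = np.meshgrid(np.arange(N_LAYERS), np.arange(N_ANGLES), indexing="ij")
    angles = (jj.ravel() + 0.5) * dtheta
    bottoms = 0.3 + 0.7 * ii.ravel() / N_LAYERS
    for ax, sl, label in zip(axes, values, ("basal", "mid", "apical")):
        ax.set_theta_zero_location("N")
        ax.set_theta_direction(-1)
        flat = sl.ravel()
        color = mapper.to_rgba(flat)
        color[~np.isfinite(flat)] = (0.8, 0.8, 0.8, 1.0)
        ax.bar(angles, 0.7 / N_LAYERS, width=dtheta, bottom=bottoms,
               color=color, edgecolor="none")
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_ylim(0, 1)
        ax.set_title(label)
    fig.colorbar(mapper, ax=axes, shrink=0.8, label="MBF [mL/min/g]")
    if title:
        fig.suptitle(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
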