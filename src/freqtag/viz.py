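"""Minimal topography plotting on the planar sensor layout."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .simulate import SensorArray

__all__ = ["plot_topography"]


def plot_topography(
    array: SensorArray,
    values: np.ndarray,
    title: str = "",
    mask: np.ndarray | None = None,
    cmap: str = "RdBu_r",
):
    """Scatter heatmap of per-chipset values; masked chipsets ringed in black."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    pos = array.positions
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=values, s=90, cmap=cmap)
    if mask is not None and np.any(mask):
        m = np.asarray(mask, dtype=bool)
        ax.scatter(
            pos[m, 0], pos[m, 1], facecolors="none", edgecolors="k", s=150, linewidths=1.5
        )
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    return fig
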