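"""Hexagonal map figures: per-neuron heatmaps and pathway traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import RegularPolygon

from .som import SOMModel

__all__ = ["plot_hex_map", "plot_trace"]


def plot_hex_map(model: SOMModel, values: np.ndarray, ax=None, cmap="viridis", label=""):
    """Colour each neuron hexagon by a per-neuron value (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(model.cols * 0.8, model.rows * 0.8))
    pos = model.positions
    finite = np.isfinite(values)
    vmin = np.nanmin(values) if finite.any() else 0.0
    vmax = np.nanmax(values) if finite.any() else 1.0
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(vmin, vmax))
    for n in range(model.n_neurons):
        color = sm.to_rgba(values[n]) if np.isfinite(values[n]) else (0.9, 0.9, 0.9, 1.0)
        ax.add_patch(
            RegularPolygon(pos[n], numVertices=6, radius=1 / np.sqrt(3), orientation=0,
                           facecolor=color, edgecolor="k", linewidth=0.5)
        )
        ax.text(*pos[n], str(n), ha="center", va="center", fontsize=6)
    ax.set_xlim(-1, model.cols + 1)
    ax.set_ylim(-1, model.rows * np.sqrt(3) / 2 + 1)
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sm, ax=ax, label=label, shrink=0.8)
    return ax


def plot_trace(model: SOMModel, bmus: np.ndarray, ax=None):
    """Overlay a replica's route (time-coloured circles joined by lines)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(model.cols * 0.8, model.rows * 0.8))
    pos = model.positions
    bmus = np.asarray(bmus, dtype=int)
    xy = pos[bmus]
    t = np.linspace(0, 1, len(bmus))
    ax.plot(xy[:, 0], xy[:, 1], "-", color="0.4", lw=0.8, zorder=1)
    ax.scatter(xy[:, 0], xy[:, 1], c=t, cmap="bwr", s=30, zorder=2, edgecolors="k", linewidths=0.3)
    ax.set_aspect("equal")
    return ax
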