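"""Static rendering of the hyperbolic disk (polar -> Cartesian scatter)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

LAYER_COLORS = {"protein": "black", "lipid": "cyan", "metabolite": "red"}


def plot_disk(coords, path, highlight=None, title=None):
    """Scatter the map on the disk, coloring nodes by omics layer.

    ``highlight`` is an optional iterable of node ids drawn larger on top.
    """
    x = coords.r * np.cos(coords.theta)
    y = coords.r * np.sin(coords.theta)
    fig, ax = plt.subplots(figsize=(7, 7))
    for layer, color in LAYER_COLORS.items():
        mask = coords.layers == layer
        if mask.any():
            ax.scatter(x[mask], y[mask], s=6, c=color, label=layer,
                       alpha=0.6, linewidths=0)
    if highlight:
        hi = set(highlight)
        mask = np.asarray([i in hi for i in coords.ids])
        if mask.any():
            ax.scatter(x[mask], y[mask], s=40, facecolors="none",
                       edgecolors="orange", label="highlighted")
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("r cos(theta)")
    ax.set_ylabel("r sin(theta)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
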