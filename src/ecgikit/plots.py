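"""Diagnostic plots: isochrone maps and Bland-Altman agreement."""

from __future__ import annotations

import numpy as np

from .geometry import SurfaceMesh
from .repeatability import BlandAltmanSummary


def plot_isochrones(mesh: SurfaceMesh, values: np.ndarray, ax=None,
                    label: str = "AT (ms)", view: str = "anterior"):
    """Scatter the marker map on a 2-D projection of the epicardial surface."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    v = mesh.vertices
    front = v[:, 1] >= 0 if view == "anterior" else v[:, 1] < 0
    sc = ax.scatter(v[front, 0], v[front, 2], c=np.asarray(values)[front],
                    s=8, cmap="turbo")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_aspect("equal")
    ax.figure.colorbar(sc, ax=ax, label=label)
    return ax


def plot_bland_altman(means: np.ndarray, diffs: np.ndarray,
                      summary: BlandAltmanSummary | None = None, ax=None):
    """Difference-vs-mean plot with non-parametric bias and 5th/95th limits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=6, alpha=0.5)
    if summary is not None:
        ax.axhline(summary.bias, color="k", label=f"bias {summary.bias:.2f}")
        ax.axhline(summary.lower, color="r", ls="--",
                   label=f"5th pct {summary.lower:.2f}")
        ax.axhline(summary.upper, color="r", ls="--",
                   label=f"95th pct {summary.upper:.2f}")
        ax.legend(fontsize=8)
    ax.set_xlabel("pairwise mean")
    ax.set_ylabel("difference")
    return ax
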