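"""Optional visualization of distribution analyses.

Contour rendering is a presentation layer over the 4x4 quartile statistics
grid: the Gaussian smoothing bandwidth affects the plots only, never any
statistic.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage

from .distribution import DifferenceMap, DistributionMap, QUARTILE_EDGES

_CENTERS = [(QUARTILE_EDGES[i] + QUARTILE_EDGES[i + 1]) / 2 for i in range(4)]


def _smooth(grid: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(grid, sigma=sigma, mode="nearest") if sigma > 0 else grid


def plot_distribution_map(
    dmap: DistributionMap, path: str | Path, title: str = "", sigma: float = 0.6
) -> None:
    """Contour plot of a proportion map (participant or group mean)."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    z = _smooth(dmap.grid.T, sigma)
    cs = ax.contourf(_CENTERS, _CENTERS, z, levels=10, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="proportion of words")
    ax.set_xlabel(dmap.axes[0])
    ax.set_ylabel(dmap.axes[1])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_difference_map(
    dmap: DifferenceMap, path: str | Path, title: str = "", sigma: float = 0.6,
    alpha: float = 0.05,
) -> None:
    """Group-minus-control difference contour; cells with uncorrected
    p < alpha are marked with an asterisk."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    z = _smooth(dmap.grid.T, sigma)
    lim = np.abs(z).max() or 1.0
    cs = ax.contourf(_CENTERS, _CENTERS, z, levels=10, cmap="RdBu_r", vmin=-lim, vmax=lim)
    fig.colorbar(cs, ax=ax, label="difference in proportion")
    for i in range(4):
        for j in range(4):
            if np.isfinite(dmap.p[i, j]) and dmap.p[i, j] < alpha:
                ax.text(_CENTERS[i], _CENTERS[j], "*", ha="center", va="center")
    ax.set_xlabel(dmap.axes[0])
    ax.set_ylabel(dmap.axes[1])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scree(eigenvalues, k: int, path: str | Path, title: str = "scree") -> None:
    """Human-readable scree curve with the retained-component cut marked."""
    eig = np.asarray(eigenvalues, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(np.arange(1, eig.size + 1), eig, "o-")
    ax.axvline(k + 0.5, color="grey", linestyle="--", label=f"k = {k}")
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
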