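"""Landscape and force-field visualization on the embedded coordinates."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dynamics import ForceField, LandscapeGrid, histogram_on_grid

__all__ = ["plot_landscape", "plot_force_field"]


def plot_landscape(
    coords_by_treatment: dict[str, np.ndarray],
    grid: LandscapeGrid,
    out: str | Path | None = None,
):
    """Per-treatment occupancy landscapes (log density, shared grid)."""
    names = sorted(coords_by_treatment)
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 4), squeeze=False)
    extent = (
        grid.edges[0][0], grid.edges[0][-1], grid.edges[1][0], grid.edges[1][-1]
    )
    for ax, name in zip(axes[0], names):
        h = histogram_on_grid(coords_by_treatment[name], grid)
        ax.imshow(
            np.log10(h.T + 1e-6), origin="lower", extent=extent, cmap="gray_r",
            aspect="auto",
        )
        ax.set_title(name)
        ax.set_xlabel("embedding 1")
    axes[0][0].set_ylabel("embedding 2")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def plot_force_field(
    ff: ForceField,
    out: str | Path | None = None,
    min_prob_drawn: float = 0.0,
):
    """Cell density (grayscale) with mean-displacement arrows (quiver).

    ``min_prob_drawn`` suppresses arrows from bins holding less than that
    fraction of all transitions — a display filter only, the model is not
    truncated.
    """
    grid = ff.grid
    cx = 0.5 * (grid.edges[0][:-1] + grid.edges[0][1:])
    cy = 0.5 * (grid.edges[1][:-1] + grid.edges[1][1:])
    XX, YY = np.meshgrid(cx, cy, indexing="ij")
    occ = ff.occupancy / max(ff.occupancy.sum(), 1)
    U = ff.mean_displacement[..., 0].copy()
    V = ff.mean_displacement[..., 1].copy()
    hide = occ < min_prob_drawn
    U[hide] = np.nan
    V[hide] = np.nan
    fig, ax = plt.subplots(figsize=(5, 5))
    extent = (grid.edges[0][0], grid.edges[0][-1], grid.edges[1][0], grid.edges[1][-1])
    ax.imshow(np.log10(occ.T + 1e-6), origin="lower", extent=extent, cmap="gray_r",
              aspect="auto")
    ax.quiver(XX, YY, U, V, color="tab:orange", angles="xy")
    ax.set_xlabel("embedding 1")
    ax.set_ylabel("embedding 2")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
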