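"""Plain plotting helpers for interaction grids and design-space surfaces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .doe import Surface  # noqa: E402

__all__ = ["plot_interaction_heatmaps", "plot_surface"]


def plot_interaction_heatmaps(grids: dict[str, pd.DataFrame], path) -> None:
    """One heatmap per muscle of a two-factor interaction grid."""
    muscles = list(grids)
    fig, axes = plt.subplots(1, len(muscles),
                             figsize=(3.2 * len(muscles), 3.0), squeeze=False)
    for ax, muscle in zip(axes[0], muscles):
        grid = grids[muscle]
        im = ax.imshow(grid.to_numpy(dtype=float), cmap="viridis", aspect="auto")
        ax.set_xticks(range(grid.shape[1]), [f"{c:g}" for c in grid.columns])
        ax.set_yticks(range(grid.shape[0]), [f"{r:g}" for r in grid.index])
        ax.set_xlabel(grid.columns.name)
        ax.set_ylabel(grid.index.name)
        ax.set_title(muscle)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_surface(surface: Surface, path, muscle: str = "") -> None:
    """3-D view of one muscle's two-factor response surface."""
    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    xx, yy = np.meshgrid(surface.x, surface.y, indexing="ij")
    ax.plot_surface(xx, yy, surface.values, cmap="viridis")
    ax.set_xlabel(surface.factor_x)
    ax.set_ylabel(surface.factor_y)
    ax.set_zlabel("MVC (a.u.)")
    if muscle:
        ax.set_title(muscle)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
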