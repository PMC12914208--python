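"""Heatmap rendering for density and height-change maps (optional outputs)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def save_heatmap(grid: np.ndarray, path: str | Path, title: str = "",
                 cmap: str = "Greys", cell: float = 0.5) -> None:
    """Render a lateral grid with darker colour = higher value."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    extent = (0, grid.shape[1] * cell, 0, grid.shape[0] * cell)
    im = ax.imshow(grid.T, origin="lower", cmap=cmap, extent=extent,
                   interpolation="nearest")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_run_dir(run_dir: Path) -> list[Path]:
    """Render every density_*.csv and height_change_*.csv as PNG."""
    written = []
    for csv in sorted(run_dir.glob("density_*.csv")):
        grid = np.loadtxt(csv, delimiter=",")
        out = csv.with_suffix(".png")
        save_heatmap(grid, out, title=csv.stem, cmap="Greys")
        written.append(out)
    for csv in sorted(run_dir.glob("height_change_*.csv")):
        grid = np.loadtxt(csv, delimiter=",")
        out = csv.with_suffix(".png")
        save_heatmap(np.nan_to_num(grid), out, title=csv.stem, cmap="Blues_r")
        written.append(out)
    return written
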