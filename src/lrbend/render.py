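"""Snapshot rendering of tissue meshes (matplotlib; SVG or PNG output)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Tissue


def plot_tissue(tissue: Tissue, ax=None, color_by: str = "zone"):
    """Draw the cell polygons; color by zone or by current axial length."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    polys = [tissue.positions[tissue.cell_edges[c, :, 0]]
             for c in range(tissue.n_cells)]
    if color_by == "zone":
        colors = np.where(tissue.cell_tip, 0.2, np.where(tissue.elongating, 1.0, 0.6))
        cmap = "viridis"
    else:
        colors = tissue.cell_axial_lengths()
        cmap = "plasma"
    pc = PolyCollection(polys, array=colors, cmap=cmap, edgecolor="k",
                        linewidth=0.4)
    ax.add_collection(pc)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"t = {tissue.sim_time:.2f} h")
    return ax


def save_snapshot(tissue: Tissue, path: str | Path, color_by: str = "zone") -> None:
    """Render one tissue snapshot to an image file (format from suffix)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ax = plot_tissue(tissue, color_by=color_by)
    fig = ax.figure
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
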