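"""Figure-style rendering of matrices and traces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .corrmatrix import CorrelationMatrix
from .traces import NodeMetrics, NodeTrace

__all__ = ["plot_matrix", "plot_trace"]


def plot_matrix(matrix: CorrelationMatrix, path: str | Path | None = None, ax=None):
    """Heatmap of a correlation matrix on the 0-1 colormap, axes in μm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    extent = [0, matrix.values.shape[1] * matrix.bin_length,
              matrix.values.shape[0] * matrix.bin_length, 0]
    im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap="viridis", extent=extent)
    ax.set_xlabel("AP position (μm)")
    ax.set_ylabel("AP position (μm)")
    plt.colorbar(im, ax=ax, label="correlation")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_trace(
    trace: NodeTrace,
    metrics: NodeMetrics | None = None,
    individual: list[NodeTrace] | None = None,
    path: str | Path | None = None,
    ax=None,
):
    """Correlation trace: gray individual profiles, black mean, red ±SD,
    green bars at the node maxima."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    if individual:
        for t in individual:
            ax.plot(t.positions, t.values, color="0.7", lw=0.8)
    ax.plot(trace.positions, trace.values, color="k", lw=1.5, label="mean")
    if trace.sd is not None and np.any(~np.isnan(trace.sd)):
        ax.plot(trace.positions, trace.values + trace.sd, color="r", lw=0.8)
        ax.plot(trace.positions, trace.values - trace.sd, color="r", lw=0.8)
    if metrics is not None:
        for x in metrics.node_positions:
            ax.axvline(x, color="g", lw=2, alpha=0.6)
    ax.set_xlabel("AP position (μm)")
    ax.set_ylabel("correlation")
    ax.set_ylim(0, 1.05)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
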