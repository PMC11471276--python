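"""Diagnostic plots for grid selection and embedding inspection.

Static matplotlib figures meant for a quick look at the advisory grids
(Silhouette over k, distance preservation over perplexity) and the 2-D
embedding coloured by cluster. All functions save to a path and return the
figure for further tweaking.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import ClusterSolution, KGridResult
from .embedding import Embedding2D, PerplexityGrid

__all__ = ["plot_k_grid", "plot_perplexity_grid", "plot_embedding"]


def plot_k_grid(grid: KGridResult, path: str | None = None):
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(grid.k_values, grid.silhouettes, "o-")
    ax1.set_xlabel("k")
    ax1.set_ylabel("mean Silhouette")
    ax2.plot(grid.k_values, grid.costs, "o-", color="tab:orange")
    ax2.set_xlabel("k")
    ax2.set_ylabel("total cost")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_perplexity_grid(grid: PerplexityGrid, path: str | None = None):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(grid.perplexities, grid.preservation, "o-")
    ax.set_xlabel("perplexity")
    ax.set_ylabel("distance preservation (Pearson r)")
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_embedding(emb: Embedding2D, clusters: ClusterSolution | None = None, path: str | None = None):
    fig, ax = plt.subplots(figsize=(5, 5))
    if clusters is not None:
        labels = np.array([clusters.assignment[f] for f in emb.feature_ids])
        sc = ax.scatter(emb.coords[:, 0], emb.coords[:, 1], c=labels, cmap="tab10", s=30)
        fig.colorbar(sc, ax=ax, label="cluster")
    else:
        ax.scatter(emb.coords[:, 0], emb.coords[:, 1], s=30)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
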