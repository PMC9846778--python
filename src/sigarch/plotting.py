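"""Simple heatmap / dendrogram exports for similarity and alpha matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .profile_metrics import ClusterMap, SimilarityMatrix

__all__ = ["save_similarity_heatmap", "save_dendrogram", "save_alpha_heatmap"]


def save_similarity_heatmap(
    simm: SimilarityMatrix, path, cluster_map: ClusterMap | None = None
) -> None:
    """Write a cosine-similarity heatmap, optionally leaf-ordered."""
    order = cluster_map.leaf_order if cluster_map is not None else range(len(simm.names))
    order = list(order)
    mat = simm.sim[np.ix_(order, order)]
    names = [simm.names[i] for i in order]
    fig, ax = plt.subplots(figsize=(0.18 * len(names) + 2,) * 2)
    im = ax.imshow(mat, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=5)
    ax.set_yticks(range(len(names)), names, fontsize=5)
    fig.colorbar(im, ax=ax, label="cosine similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_dendrogram(cluster_map: ClusterMap, path) -> None:
    """Write the average-linkage merge tree as a dendrogram."""
    fig, ax = plt.subplots(figsize=(0.25 * len(cluster_map.names) + 2, 4))
    hierarchy.dendrogram(
        cluster_map.linkage, labels=cluster_map.names, ax=ax, leaf_font_size=6
    )
    ax.set_ylabel("cosine distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_alpha_heatmap(table, path) -> None:
    """Write a masked alpha-coefficient heatmap (signatures x archetypes)."""
    fig, ax = plt.subplots(
        figsize=(0.3 * table.shape[1] + 2, 0.22 * table.shape[0] + 2)
    )
    im = ax.imshow(table.to_numpy(), cmap="magma_r", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="alpha")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
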