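"""Basic figure exports: landscape scatter and CTP heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_landscape(embedding, labels, path) -> None:
    """Scatter of the 2-D embedding coloured by cluster label."""
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        m = labels == lab
        ax.scatter(embedding[m, 0], embedding[m, 1], s=4, label=str(lab), alpha=0.6)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(markerscale=3, fontsize=8, title="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ctp_heatmap(graph, path) -> None:
    """Heatmap of the conditional transition probability matrix."""
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(graph.ctp_matrix, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(graph.nodes)), graph.nodes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(graph.nodes)), graph.nodes, fontsize=7)
    ax.set_xlabel("to phenotype")
    ax.set_ylabel("from phenotype")
    fig.colorbar(im, label="CTP")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
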