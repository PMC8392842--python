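"""Basic diagnostic plots: embedding scatter and severity bars."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .profiles import SeveritySummary  # noqa: E402


def plot_embedding(coords: np.ndarray, labels: np.ndarray, path=None,
                   centroids: np.ndarray | None = None):
    """2-D embedding scatter colored by cluster, centroids starred."""
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(labels)
    for c in np.unique(labels):
        m = labels == c
        name = "noise" if c == -1 else f"cluster {c}"
        ax.scatter(coords[m, 0], coords[m, 1], s=12, label=name, alpha=0.7)
    if centroids is not None:
        ax.scatter(centroids[:, 0], centroids[:, 1], marker="*", s=220,
                   c="red", edgecolors="k", label="centroid")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_severity(summary: SeveritySummary, path=None):
    """Grouped bars of per-cluster cognition/volume mean fold changes ± sd."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(summary.clusters))
    w = 0.38
    cog = [summary.cognition_mean[c] for c in summary.clusters]
    cog_sd = [summary.cognition_sd[c] for c in summary.clusters]
    vol = [summary.volume_mean[c] for c in summary.clusters]
    vol_sd = [summary.volume_sd[c] for c in summary.clusters]
    ax.bar(x - w / 2, cog, w, yerr=cog_sd, capsize=3, label="cognition")
    ax.bar(x + w / 2, vol, w, yerr=vol_sd, capsize=3, label="brain volume")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(x, [f"cluster {c}" for c in summary.clusters])
    ax.set_ylabel("standardized mean fold change (%)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
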