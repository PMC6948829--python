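"""Diagnostic figures: scree plot, loading heatmap, network-change panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .factor_reduction import FactorModel


def plot_scree(model: FactorModel, path) -> None:
    """Eigenvalues in decreasing order with the retention cut at 1.0."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    k = np.arange(1, len(model.eigenvalues) + 1)
    ax.plot(k, model.eigenvalues, "o-", ms=4)
    ax.axhline(1.0, color="grey", ls="--", lw=1)
    ax.axvline(model.retained_k + 0.5, color="tab:red", ls=":", lw=1)
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    ax.set_title(f"retained {model.retained_k}; elbow at {model.scree_elbow_at}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_loading_heatmap(model: FactorModel, path) -> None:
    """Promax pattern loadings, threshold contours at +-|0.5|."""
    fig, ax = plt.subplots(figsize=(4.5, 7))
    P = model.pattern
    im = ax.imshow(P, cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(P.shape[1]))
    ax.set_xticklabels(model.component_labels[: P.shape[1]], rotation=45,
                       ha="right", fontsize=7)
    ax.set_yticks(range(P.shape[0]))
    ax.set_yticklabels(model.measure_ids, fontsize=7)
    thr = model.loading_threshold
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            if abs(P[i, j]) >= thr:
                ax.text(j, i, f"{P[i, j]:.2f}", ha="center", va="center",
                        fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.6, label="pattern loading")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
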