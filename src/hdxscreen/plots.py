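"""Optional figure helpers (heat map, correlogram, dendrogram).

Requires matplotlib (``pip install hdxscreen[plot]``); imported lazily so
the analysis stack has no hard plotting dependency.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def perturbation_heatmap(matrix, path, vmax=None):
    """Compounds x peptide-timepoints d%D heat map (blue = protection)."""
    plt = _plt()
    data = matrix.to_numpy(float)
    if vmax is None:
        vmax = np.nanmax(np.abs(data)) or 1.0
    fig, ax = plt.subplots(figsize=(max(6, 0.18 * data.shape[1]), max(4, 0.18 * data.shape[0])))
    im = ax.imshow(data, cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=6)
    ax.set_xticks(range(data.shape[1]),
                  [f"{p}@{t:g}" for p, t in matrix.columns],
                  rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label=r"$\Delta$%D (pp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlogram(covariation_result, path):
    """R^2 grid with non-significant pairs blanked out."""
    plt = _plt()
    r2 = covariation_result.r_squared.to_numpy(float).copy()
    r2[~covariation_result.mask.to_numpy(bool)] = np.nan
    fig, ax = plt.subplots(figsize=(0.16 * r2.shape[0] + 2,) * 2)
    im = ax.imshow(r2, cmap="viridis", vmin=0, vmax=1)
    labels = covariation_result.r_squared.index
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=5)
    ax.set_yticks(range(len(labels)), labels, fontsize=5)
    fig.colorbar(im, ax=ax, label=r"$R^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dendrogram_plot(tree, path):
    plt = _plt()
    from scipy.cluster.hierarchy import dendrogram
    fig, ax = plt.subplots(figsize=(8, 0.22 * len(tree.labels) + 1))
    dendrogram(tree.linkage_matrix, labels=list(tree.labels),
               orientation="left", ax=ax)
    ax.set_xlabel("Ward merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
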