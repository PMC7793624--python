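"""Figure helpers: UMAP scatters of latent repertoires."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["umap_scatter"]


def umap_scatter(
    embedding: np.ndarray,
    color,
    path: str | Path | None = None,
    label: str = "",
    categorical: bool | None = None,
    ax: "plt.Axes | None" = None,
):
    """Scatter a 2-D embedding colored by condition or an acoustic feature.

    ``color`` may be categorical (condition labels) or continuous (e.g.
    total energy or bandwidth per syllable).  Returns the axes; saves to
    ``path`` (PNG/SVG by extension) when given.
    """
    emb = np.asarray(embedding, dtype=float)
    if emb.ndim != 2 or emb.shape[1] != 2:
        raise ValueError("embedding must be (n, 2)")
    color = np.asarray(color)
    if categorical is None:
        categorical = color.dtype.kind in ("U", "S", "O", "b")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if categorical:
        for value in np.unique(color):
            sel = color == value
            ax.scatter(emb[sel, 0], emb[sel, 1], s=4, alpha=0.6, label=str(value))
        ax.legend(title=label or None, frameon=False)
    else:
        sc = ax.scatter(emb[:, 0], emb[:, 1], s=4, alpha=0.6, c=color.astype(float),
                        cmap="viridis")
        ax.figure.colorbar(sc, ax=ax, label=label)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.set_xticks([])
    ax.set_yticks([])
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
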