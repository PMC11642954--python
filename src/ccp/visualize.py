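"""2-D visualization: CCP-assisted (or raw) UMAP and t-SNE, plus figure output.

"CCP-assisted" simply means the 2-D reducer consumes the super-gene matrix
instead of the full gene space; no intermediate PCA is inserted.  UMAP and
t-SNE internals are delegated to umap-learn and scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Embedding2D", "assist_umap", "assist_tsne", "plot_embedding"]

_SUPPORTED_FIGURE_FORMATS = (".png", ".svg", ".pdf")


@dataclass
class Embedding2D:
    """An M × 2 embedding with provenance (reducer, input kind, seed)."""

    coords: np.ndarray
    method: str
    input_kind: str = "other"
    seed: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding must have exactly 2 columns")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite coordinates")


def _as_array(data) -> tuple[np.ndarray, str]:
    # SuperGeneMatrix / ExpressionMatrix / ndarray all accepted
    kind = "other"
    if hasattr(data, "column_labels"):
        kind = "supergenes"
    elif hasattr(data, "gene_ids"):
        kind = "raw"
    values = data.values if hasattr(data, "values") else np.asarray(data)
    return np.asarray(values, dtype=np.float64), kind


def assist_umap(
    data, n_neighbors: int = 15, min_dist: float = 0.5, seed: int = 0
) -> Embedding2D:
    """UMAP to 2-D.  Deterministic for a fixed seed (single-threaded)."""
    import umap

    values, kind = _as_array(data)
    m = values.shape[0]
    if m < 3:
        raise ValueError("UMAP needs at least 3 cells")
    if n_neighbors >= m:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be below the cell count {m}; "
            "pass a smaller n_neighbors"
        )
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = reducer.fit_transform(values)
    return Embedding2D(coords, method="umap", input_kind=kind, seed=seed)


def assist_tsne(data, perplexity: float = 30.0, seed: int = 0) -> Embedding2D:
    """t-SNE to 2-D.  Requires perplexity < (M - 1) / 3."""
    from sklearn.manifold import TSNE

    values, kind = _as_array(data)
    m = values.shape[0]
    if m < 3:
        raise ValueError("t-SNE needs at least 3 cells")
    if perplexity >= (m - 1) / 3:
        raise ValueError(
            f"perplexity={perplexity} too large for {m} cells; "
            f"needs perplexity < {(m - 1) / 3:.1f}"
        )
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(values)
    return Embedding2D(coords, method="tsne", input_kind=kind, seed=seed)


def plot_embedding(e: Embedding2D, labels=None, out: str | Path = "embedding.png") -> Path:
    """Scatter-plot an embedding, one color per label class, with a legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    if out.suffix.lower() not in _SUPPORTED_FIGURE_FORMATS:
        raise ValueError(
            f"unsupported figure format {out.suffix!r}; "
            f"supported: {', '.join(_SUPPORTED_FIGURE_FORMATS)}"
        )
    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        ax.scatter(e.coords[:, 0], e.coords[:, 1], s=8, color="tab:blue")
    else:
        lab = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
        if lab.shape[0] != e.coords.shape[0]:
            raise ValueError(
                f"{lab.shape[0]} labels for {e.coords.shape[0]} embedded cells"
            )
        for value in np.unique(lab):
            mask = lab == value
            ax.scatter(
                e.coords[mask, 0], e.coords[mask, 1], s=8, label=str(value)
            )
        ax.legend(markerscale=2, fontsize=8, loc="best")
    ax.set_xlabel(f"{e.method.upper()} 1")
    ax.set_ylabel(f"{e.method.upper()} 2")
    ax.set_title(f"{e.method.upper()} ({e.input_kind})")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
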