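"""Composite 3-D t-SNE view: one Gini-based dimension plus two Fano-based ones.

A 2-D t-SNE of the Fano/PCA embedding separates common clusters but leaves
rare clusters overlapping; a 1-D t-SNE of the Gini-feature Jaccard distance
separates the rare clusters.  Stacking the two gives a three-dimensional
view in which all clusters separate.  The coordinates integrate two
different feature spaces, so distances have no single-projection meaning —
the plot is a visualization aid, not an embedding of one metric.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE


def _tsne(x, n_components, seed, perplexity, metric):
    return TSNE(
        n_components=n_components,
        metric=metric,
        perplexity=perplexity,
        init="random",
        random_state=seed,
    ).fit_transform(x)


def composite_tsne(
    gini_dist: np.ndarray,
    fano_embedding: np.ndarray,
    seed: int = 0,
    pca_gini_threshold: int = 5000,
    perplexity: float | None = None,
) -> np.ndarray:
    """cells x 3 coordinates: column 0 from the Gini distance, 1-2 from the
    Fano embedding.

    The Gini column is a 1-D t-SNE on the precomputed Jaccard distance; above
    ``pca_gini_threshold`` cells it is run on the first 50 principal
    components of the distance rows instead (t-SNE on a large precomputed
    matrix is prohibitively slow).  Deterministic given ``seed``.
    """
    gini_dist = np.asarray(gini_dist, dtype=float)
    fano_embedding = np.asarray(fano_embedding, dtype=float)
    n = gini_dist.shape[0]
    if gini_dist.shape != (n, n) or fano_embedding.shape[0] != n:
        raise ValueError(
            f"cell count mismatch: distance {gini_dist.shape}, "
            f"embedding {fano_embedding.shape}"
        )
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    if n > pca_gini_threshold:
        x = PCA(n_components=min(50, n - 1), random_state=int(seeds[0])).fit_transform(
            gini_dist
        )
        g = _tsne(x, 1, int(seeds[0]), perplexity, "euclidean")
    else:
        g = _tsne(gini_dist, 1, int(seeds[0]), perplexity, "precomputed")
    f = _tsne(fano_embedding, 2, int(seeds[1]), perplexity, "euclidean")
    return np.column_stack([g, f])


def write_coordinates(coords: np.ndarray, cell_ids, path) -> None:
    import pandas as pd

    pd.DataFrame(
        coords, columns=["gini1", "fano1", "fano2"], index=list(cell_ids)
    ).rename_axis("cell_id").to_csv(path, sep="\t")


def plot_composite(coords: np.ndarray, labels, path) -> None:
    """Static 3-D scatter of the composite coordinates, colored by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for lab in np.unique(labels):
        sel = labels == lab
        ax.scatter(
            coords[sel, 1], coords[sel, 2], coords[sel, 0], s=8, label=str(lab)
        )
    ax.set_xlabel("Fano tSNE 1")
    ax.set_ylabel("Fano tSNE 2")
    ax.set_zlabel("Gini tSNE")
    ax.legend(title="cluster", loc="upper left", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
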