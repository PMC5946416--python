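"""Common-cell clustering stage: Fano-factor features, PCA, k-means, gap statistic.

The Fano factor (variance over mean) of a gene's expression across cells is
large for genes that vary between abundant cell types, so the top-Fano genes
are an effective feature set for resolving common clusters.  Cells are
embedded with PCA on those genes and clustered with restarted k-means; the
number of clusters can be chosen with the gap statistic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .partition import Partition


def fano_factor(x) -> float:
    """Variance-over-mean of a count vector (sample variance, n-1 denominator).

    Genes with zero mean are assigned 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("fano_factor needs at least 2 observations")
    m = x.mean()
    if m == 0:
        return 0.0
    return float(x.var(ddof=1) / m)


def fano_factor_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-wise Fano factors of a genes x cells matrix."""
    counts = np.asarray(counts, dtype=float)
    means = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    out = np.zeros(counts.shape[0])
    nz = means > 0
    out[nz] = var[nz] / means[nz]
    return out


def select_top_fano(m, n_genes: int = 1000) -> set[str]:
    """Ids of the ``n_genes`` genes with the largest Fano factor.

    Ties at the cutoff are broken by lexicographic gene id so the selection is
    deterministic.  If fewer genes exist, all are returned with a warning.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    fano = pd.Series(fano_factor_matrix(m.counts), index=list(m.gene_ids))
    if n_genes >= fano.size:
        if n_genes > fano.size:
            warnings.warn(
                f"requested {n_genes} genes but only {fano.size} available; using all"
            )
        return set(fano.index)
    order = fano.sort_index().sort_values(ascending=False, kind="stable")
    return set(order.index[:n_genes])


def pca_reduce(m, n_components: int = 50) -> np.ndarray:
    """PCA embedding (cells x components) of the cells-by-genes matrix.

    Genes are mean-centered; the effective number of components is
    min(n_components, n_cells - 1, n_genes).  Each component's sign is fixed
    by forcing its largest-magnitude gene loading positive, so the embedding
    is deterministic.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    counts = m.counts if hasattr(m, "counts") else np.asarray(m)
    x = counts.T.astype(float)  # cells x genes
    n_cells, n_genes = x.shape
    eff = min(n_components, n_cells - 1, n_genes)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :eff], s[:eff], vt[:eff]
    flip = np.sign(vt[np.arange(eff), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    return u * s * flip


def _seed_stream(seed: int, n: int) -> np.ndarray:
    # Prefix-stable: the first m seeds are identical for any n >= m, which
    # makes the best-of-restarts objective non-increasing in n_restarts.
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _best_kmeans(x: np.ndarray, k: int, n_restarts: int, seed: int):
    """Best of ``n_restarts`` independent Lloyd runs; returns (labels, inertia)."""
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points {x.shape[0]}")
    if k == 1:
        mu = x.mean(axis=0)
        return np.zeros(x.shape[0], dtype=int), float(((x - mu) ** 2).sum())
    best = None
    for s in _seed_stream(seed, n_restarts):
        km = KMeans(
            n_clusters=k,
            n_init=1,
            init="k-means++",
            algorithm="lloyd",
            tol=1e-6,
            max_iter=300,
            random_state=int(s),
        ).fit(x)
        if best is None or km.inertia_ < best[1]:
            best = (km.labels_, float(km.inertia_))
    return best


def kmeans_cluster(e: np.ndarray, k: int, n_restarts: int = 20, seed: int = 0, cell_ids=()) -> Partition:
    """k-means on an embedding, keeping the restart with the lowest
    within-cluster sum of squares.  Labels are 1..k."""
    labels, _ = _best_kmeans(np.asarray(e, dtype=float), k, n_restarts, seed)
    return Partition.from_labels(labels, tuple(cell_ids))


def choose_k_gap(
    e: np.ndarray,
    k_max: int = 6,
    n_refs: int = 20,
    seed: int = 0,
    n_restarts: int = 5,
) -> int:
    """Choose k with the gap statistic (firstSEmax rule).

    For k = 1..k_max, Gap(k) = mean_b log W_b(k) - log W(k), where W is the
    pooled within-cluster dispersion (k-means objective) and the B reference
    datasets are uniform draws over the bounding box of the data in its
    principal-axes frame.  Returns the smallest k with
    Gap(k) >= Gap(k+1) - SE(k+1); if no k qualifies, k_max.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    x = np.asarray(e, dtype=float)
    rng = np.random.default_rng(seed)
    xc = x - x.mean(axis=0)
    # principal-axes rotation; W is rotation-invariant so refs are clustered as-is
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    xp = xc @ vt.T
    lo, hi = xp.min(axis=0), xp.max(axis=0)
    ks = np.arange(1, k_max + 1)
    km_seeds = _seed_stream(seed, k_max * (n_refs + 1)).reshape(k_max, n_refs + 1)
    log_w = np.empty(k_max)
    log_w_ref = np.empty((n_refs, k_max))
    refs = [rng.uniform(lo, hi, size=xp.shape) for _ in range(n_refs)]
    for i, k in enumerate(ks):
        log_w[i] = np.log(_best_kmeans(xp, k, n_restarts, int(km_seeds[i, 0]))[1])
        for b, ref in enumerate(refs):
            log_w_ref[b, i] = np.log(
                _best_kmeans(ref, k, n_restarts, int(km_seeds[i, b + 1]))[1]
            )
    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            return int(ks[i])
    return int(k_max)


def fano_stage(
    m,
    k: int | None = None,
    n_genes: int = 1000,
    n_components: int = 50,
    n_restarts: int = 20,
    gap_k_max: int = 6,
    gap_n_refs: int = 20,
    seed: int = 0,
) -> tuple[Partition, np.ndarray, int]:
    """Run the full common-cell stage: top-Fano genes -> PCA -> k-means.

    When ``k`` is None it is chosen with the gap statistic.  Returns the
    partition, the PCA embedding and the k used.
    """
    top = select_top_fano(m, n_genes)
    emb = pca_reduce(m.restrict_genes(top), n_components)
    if k is None:
        k = choose_k_gap(emb, k_max=gap_k_max, n_refs=gap_n_refs, seed=seed)
    part = kmeans_cluster(emb, k, n_restarts=n_restarts, seed=seed, cell_ids=m.cell_ids)
    return part, emb, int(k)
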