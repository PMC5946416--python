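"""Rare-cell clustering stage: Gini-index gene selection and density clustering.

The Gini index of a gene — twice the area between the Lorenz curve of its
expression across cells and the diagonal — is high for genes expressed in a
small subset of cells, which makes it an effective selector of rare-cell
markers.  Because raw Gini values trend strongly with a gene's expression
level, they are detrended against maximum expression with a two-pass LOESS
fit; genes whose detrended (normalized) Gini is significantly above zero are
the "high Gini" features.  Cells are then compared by the Jaccard distance of
their binarized profiles over those features and clustered with DBSCAN, which
can isolate arbitrarily small dense groups while leaving unassignable cells
as noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fano import fano_factor_matrix
from .partition import Partition


def gini_index(x) -> float:
    """Gini index of a non-negative vector, in [0, 1).

    Computed via the O(n log n) sorted form
    ``sum_i (2i - n - 1) x_(i) / (n^2 mean(x))``, which equals twice the area
    between the diagonal and the Lorenz curve, and also the mean-absolute-
    difference form ``sum_ij |x_i - x_j| / (2 n^2 mean(x))``.  Constant (and
    all-zero) vectors score 0; the index is invariant to positive scaling.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("gini_index needs a 1-D vector of length >= 2")
    if np.any(x < 0):
        raise ValueError("gini_index is undefined for negative entries")
    total = x.sum()
    if total == 0 or np.ptp(x) == 0:
        return 0.0
    n = x.size
    xs = np.sort(x)
    coef = 2.0 * np.arange(1, n + 1) - n - 1
    return float(coef @ xs / (n * total))


def gini_index_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-wise Gini indices of a genes x cells matrix (vectorized)."""
    counts = np.asarray(counts)
    n = counts.shape[1]
    if n < 2:
        raise ValueError("need at least 2 cells")
    xs = np.sort(counts, axis=1)
    coef = 2.0 * np.arange(1, n + 1) - n - 1
    totals = xs.sum(axis=1, dtype=float)
    num = xs @ coef
    out = np.zeros(counts.shape[0], dtype=float)
    nz = totals > 0
    out[nz] = num[nz] / (n * totals[nz])
    return out


def gene_scores(m) -> pd.DataFrame:
    """Per-gene score table: max expression, raw Gini and Fano factor.

    Returns a DataFrame indexed by gene id with columns ``max_expr``,
    ``gini_raw`` and ``fano``; ``gini_norm`` and ``p_value`` are added by
    :func:`normalize_gini`.
    """
    counts = m.counts
    return pd.DataFrame(
        {
            "max_expr": counts.max(axis=1),
            "gini_raw": gini_index_matrix(counts),
            "fano": fano_factor_matrix(counts),
        },
        index=pd.Index(list(m.gene_ids), name="gene_id"),
    )


def _lowess_eval(y, x, x_eval, span):
    # Fitted at the sample points, linearly interpolated to x_eval; values
    # outside the fitted range are clamped to the boundary fit.
    fitted = lowess(
        y,
        x,
        frac=span,
        it=3,
        delta=0.01 * (np.max(x) - np.min(x)),
        return_sorted=True,
    )
    return np.interp(x_eval, fitted[:, 0], fitted[:, 1])


def normalize_gini(
    scores: pd.DataFrame,
    span: float = 0.9,
    outlier_quantile: float = 0.9,
    robust: bool = False,
) -> pd.DataFrame:
    """Detrend raw Gini against maximum expression; attach one-sided p-values.

    Pass 1 fits a LOESS of ``gini_raw`` on ``log2(max_expr + 0.1)`` over all
    genes; pass 2 refits after excluding genes whose first-pass residual lies
    above ``outlier_quantile`` (so true high-Gini outliers do not drag the
    trend up).  ``gini_norm`` is the residual from the second fit.  The
    p-value is the upper-tail probability of ``gini_norm`` under a normal
    distribution whose location/scale are the sample mean/SD of all residuals
    (median/1.4826*MAD when ``robust=True``).
    """
    if (scores["max_expr"] > 0).sum() < 10:
        raise ValueError(
            "normalize_gini needs at least 10 genes with nonzero expression; "
            "provide a larger input"
        )
    x = np.log2(scores["max_expr"].to_numpy(dtype=float) + 0.1)
    y = scores["gini_raw"].to_numpy(dtype=float)
    resid1 = y - _lowess_eval(y, x, x, span)
    keep = resid1 <= np.quantile(resid1, outlier_quantile)
    gini_norm = y - _lowess_eval(y[keep], x[keep], x, span)
    if robust:
        loc = np.median(gini_norm)
        scale = 1.4826 * np.median(np.abs(gini_norm - loc))
    else:
        loc = gini_norm.mean()
        scale = gini_norm.std(ddof=1)
    if scale == 0:
        raise ValueError("degenerate normalized Gini distribution (zero spread)")
    out = scores.copy()
    out["gini_norm"] = gini_norm
    out["p_value"] = stats.norm.sf(gini_norm, loc=loc, scale=scale)
    return out


def select_high_gini(scores: pd.DataFrame, p_threshold: float = 1e-4) -> set[str]:
    """Genes with normalized-Gini p-value strictly below ``p_threshold``."""
    if "p_value" not in scores:
        raise ValueError("scores lack p-values; run normalize_gini first")
    sel = set(scores.index[scores["p_value"] < p_threshold])
    if not sel:
        raise ValueError(
            f"no gene passed p < {p_threshold}; relax the threshold — the rare-cell "
            "stage cannot proceed without Gini features"
        )
    return sel


def jaccard_distance(m) -> np.ndarray:
    """Pairwise Jaccard distance between cells on binarized profiles.

    Each cell's profile over the (high-Gini) genes is binarized at count > 0;
    d(i,j) = 1 - |A∩B| / |A∪B|.  Two cells expressing none of the genes are at
    distance 0 by convention.
    """
    counts = m.counts if hasattr(m, "counts") else np.asarray(m)
    if counts.shape[0] < 1 or counts.shape[1] < 2:
        raise ValueError("need at least 1 gene and 2 cells")
    b = (counts > 0).T.astype(np.float64)  # cells x genes
    inter = b @ b.T
    sizes = b.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def dbscan_cluster(d: np.ndarray, eps: float = 0.5, min_pts: int = 3, cell_ids=()) -> Partition:
    """DBSCAN on a precomputed distance matrix; unassigned cells become noise.

    ``min_pts`` counts the point itself, matching the classical definition.
    An all-noise result is legal and means "no dense structure at this eps".
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10) or np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    labels = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(d).labels_
    return Partition.from_labels(labels, tuple(cell_ids), noise=-1)


def gini_stage(
    m,
    p_threshold: float = 1e-4,
    eps: float = 0.5,
    min_pts: int = 3,
    span: float = 0.9,
    outlier_quantile: float = 0.9,
    robust: bool = False,
) -> tuple[Partition, pd.DataFrame, np.ndarray]:
    """Run the full rare-cell stage on a filtered count matrix.

    Returns the DBSCAN partition, the per-gene score table and the Jaccard
    distance matrix (reused by the composite t-SNE view).
    """
    scores = normalize_gini(
        gene_scores(m), span=span, outlier_quantile=outlier_quantile, robust=robust
    )
    high = select_high_gini(scores, p_threshold)
    d = jaccard_distance(m.restrict_genes(high))
    part = dbscan_cluster(d, eps=eps, min_pts=min_pts, cell_ids=m.cell_ids)
    return part, scores, d
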