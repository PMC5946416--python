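"""Cluster-aware weighted consensus of the rare-cell and common-cell partitions.

Each base partition P is encoded as a binary connectivity matrix M(P) with
M_ij = 1 when cells i and j share a cluster.  The consensus association

    Mbar_ij = w_ij^G M_ij(P^G) + w_ij^F M_ij(P^F),   w_ij^G + w_ij^F = 1,

averages the two, with pair weights derived from *cell-specific* weights:
the rare-cell (Gini) weight of a cell is a decreasing logistic function of
the proportion x_i of its cluster,

    w~_i^G(x_i) = 1 - 1 / (1 + exp(-(x_i - mu') / s')),

so cells in small clusters trust the rare-cell partition and cells in large
clusters trust the common-cell one; the common-cell (Fano) weight is a
constant f'.  Pair weights take the larger of the two Gini cell weights
(a pair containing one rare cell is treated as rare) and are normalized to
sum to one.  The user-facing parameters are mu (the cluster proportion at
which both methods are trusted equally), s = s' (how fast trust in the
rare-cell method decays) and f = f'/(1 + f') (the weight of the common-cell
partition against a fully-trusted rare call).

A hard clustering is read off Mbar by minimizing ||Mbar - U||^2 over
connectivity matrices U, which with an orthogonality relaxation reduces to
k-means on the rows of Mbar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .fano import _best_kmeans
from .partition import NOISE, Partition


@dataclass(frozen=True)
class WeightParams:
    """Logistic weighting parameters, stored in their internal (primed) form."""

    mu_prime: float
    s_prime: float
    f_prime: float

    def __post_init__(self):
        if self.s_prime <= 0:
            raise ValueError("s' must be positive")
        if self.f_prime <= 0:
            raise ValueError("f' must be positive")

    @property
    def f(self) -> float:
        return self.f_prime / (1.0 + self.f_prime)

    @property
    def s(self) -> float:
        return self.s_prime

    @property
    def mu(self) -> float:
        # f' = 1 - 1/(1 + exp(-(mu - mu')/s'))  <=>  mu = mu' - s' logit(f')
        return float(self.mu_prime - self.s_prime * logit(self.f_prime))


def derive_params(mu: float = 0.05, s: float = 0.00625, f: float = 0.025) -> WeightParams:
    """Invert the user-facing (mu, s, f) triple to internal (mu', s', f').

    f' = f/(1-f), s' = s and mu' = mu - s' * logit(1 - f').  The link between
    mu and mu' requires f' < 1, i.e. f < 1/2: f is the consensus weight the
    common-cell partition gets against a fully trusted rare call, and by
    construction the rare-cell method is the trusted one below mu.  The
    inversion round-trips with the forward relations to 1e-12.
    """
    if not 0.0 < f < 0.5:
        raise ValueError(
            f"f must lie in (0, 0.5), got {f}: f = f'/(1+f') with the internal "
            "f' in (0, 1)"
        )
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must be a proportion in (0, 1)")
    if s <= 0:
        raise ValueError("s must be positive")
    f_prime = f / (1.0 - f)
    mu_prime = mu - s * logit(1.0 - f_prime)
    return WeightParams(mu_prime=mu_prime, s_prime=s, f_prime=f_prime)


def gini_cell_weight(x_i, params: WeightParams):
    """Cell-specific rare-cell weight: a decreasing logistic in the cluster
    proportion ``x_i`` of the cell, equal to 0.5 at x_i = mu'."""
    x = np.asarray(x_i, dtype=float)
    if np.any((x <= 0) | (x > 1)):
        raise ValueError("cluster proportions must lie in (0, 1]")
    w = expit(-(x - params.mu_prime) / params.s_prime)
    return float(w) if np.isscalar(x_i) else w


def cell_weights(p: Partition, params: WeightParams) -> np.ndarray:
    """Per-cell rare-cell weights from a partition.

    Noise cells (no confident rare-cell assignment) get weight 0, i.e. full
    trust in the common-cell partition.
    """
    props = p.proportions
    w = np.zeros(p.n)
    for c, x in props.items():
        w[p.labels == c] = gini_cell_weight(x, params)
    return w


def pair_weights(w_tilde_g_i: float, w_tilde_g_j: float, f_prime: float) -> tuple[float, float]:
    """Normalized pair weights (w_ij^G, w_ij^F), summing to 1.

    The pair's rare-cell weight is the max of the two cell weights, so a pair
    with one rare member is still judged by the rare-cell partition.
    """
    w_g = max(w_tilde_g_i, w_tilde_g_j)
    denom = w_g + f_prime
    if denom == 0:
        raise ValueError("degenerate weights: both the Gini pair weight and f' are zero")
    return w_g / denom, f_prime / denom


def connectivity(p: Partition) -> np.ndarray:
    """Binary connectivity matrix of a partition: 1 iff two cells share a
    cluster.  Noise cells connect only to themselves; diagonal is 1."""
    lab = p.labels
    m = (lab[:, None] == lab[None, :]) & (lab[:, None] != NOISE)
    np.fill_diagonal(m, True)
    return m.astype(np.float64)


def consensus_matrix(
    m_g: np.ndarray,
    m_f: np.ndarray,
    w_tilde_g: np.ndarray,
    params: WeightParams,
) -> np.ndarray:
    """Weighted consensus association Mbar in [0, 1], symmetric, unit diagonal.

    Entrywise: Mbar_ij = w_ij^G M^G_ij + w_ij^F M^F_ij with the pair weights
    of :func:`pair_weights`, so every entry is a convex combination of the two
    connectivity values.
    """
    m_g = np.asarray(m_g, dtype=float)
    m_f = np.asarray(m_f, dtype=float)
    w = np.asarray(w_tilde_g, dtype=float)
    n = w.size
    if m_g.shape != (n, n) or m_f.shape != (n, n):
        raise ValueError(
            f"dimension mismatch: weights for {n} cells, connectivity "
            f"{m_g.shape} and {m_f.shape}"
        )
    pair_g = np.maximum.outer(w, w)
    w_g = pair_g / (pair_g + params.f_prime)
    mbar = w_g * m_g + (1.0 - w_g) * m_f
    np.fill_diagonal(mbar, 1.0)
    return mbar


def final_cluster(
    mbar: np.ndarray,
    k_final: int,
    n_restarts: int = 20,
    seed: int = 0,
    cell_ids=(),
) -> Partition:
    """Hard consensus clustering: k-means on the rows of Mbar.

    Minimizing ||Mbar - U||^2 over connectivity matrices U relaxes, under an
    orthogonality constraint, to k-means with each cell's association profile
    (its row of Mbar) as the feature vector.
    """
    mbar = np.asarray(mbar, dtype=float)
    if k_final < 1 or k_final > mbar.shape[0]:
        raise ValueError(f"k_final={k_final} out of range for n={mbar.shape[0]}")
    labels, _ = _best_kmeans(mbar, k_final, n_restarts, seed)
    return Partition.from_labels(labels, tuple(cell_ids))


def choose_k_final(p_g: Partition, p_f: Partition, params: WeightParams) -> int:
    """Default consensus cluster count: k_F plus the rare candidates.

    Every (non-noise) rare-cell cluster whose proportion is below mu — the
    regime where the rare-cell method is the trusted one — is expected to
    survive as its own consensus cluster on top of the k_F common clusters.
    Override via the ``k_final`` pipeline/CLI option when this heuristic does
    not fit.
    """
    rare = sum(1 for x in p_g.proportions.values() if x < params.mu)
    return p_f.k + rare
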