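"""Synthetic UMI counts with planted common and rare clusters.

Per-gene baseline means are drawn once from a two-component log-normal
mixture — a large "background" component of essentially silent genes and an
"expressed" component — emulating the background-noise structure of real UMI
data, where the majority of annotated genes are detected in almost no cell.
Counts are negative-binomial with a quadratic mean-variance relation
v = m + alpha m^2, sampled independently per cell.  Cluster structure is planted by selecting,
for each cluster, a disjoint set of 100 lowly expressed (mean below 10
counts) and 100 highly expressed (mean above 10) genes and randomly
permuting those genes' identities within the cluster's cells — so a subset
of low-expression genes acquires high expression (and vice versa) only in
that cluster, creating cluster-specific marker signatures while leaving
every marginal gene-level distribution untouched.

The default configuration plants two common clusters (2000 and 1000 cells)
and four rare ones (10, 6, 4, 3 cells) over 23,538 genes: 3,023 cells in
total.  The log-normal/dispersion defaults are a parametric stand-in chosen
to reproduce realistic UMI sparsity and leave comfortably more than the 600
required genes in the high-expression stratum; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .partition import Partition
from .preprocess import CountMatrix, save_counts


@dataclass(frozen=True)
class SimulationConfig:
    cluster_sizes: tuple[int, ...] = (2000, 1000, 10, 6, 4, 3)
    n_genes: int = 23538
    bg_fraction: float = 0.80  # fraction of genes in the silent background component
    bg_log_mean: float = -18.0  # background mean law, ln scale
    bg_log_sigma: float = 1.5
    expr_log_mean: float = 3.2  # expressed-gene mean law, ln scale
    expr_log_sigma: float = 0.8
    dispersion: float = 0.2  # alpha in v = m + alpha m^2
    n_low_sig: int = 100
    n_high_sig: int = 100
    low_mean_cutoff: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not self.cluster_sizes or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must all be >= 1")
        object.__setattr__(self, "cluster_sizes", tuple(int(s) for s in self.cluster_sizes))
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0.0 <= self.bg_fraction < 1.0:
            raise ValueError("bg_fraction must lie in [0, 1)")
        if self.n_low_sig < 0 or self.n_high_sig < 0:
            raise ValueError("signature gene counts must be >= 0")

    @property
    def n_cells(self) -> int:
        return sum(self.cluster_sizes)


def _sample_nb(rng, means, n_cells, dispersion, dtype=np.int32):
    """genes x n_cells NB draws with v = m + alpha m^2 (r = 1/alpha)."""
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p[:, None], size=(means.size, n_cells)).astype(dtype)


def _signature_permutation(rng, n: int) -> np.ndarray:
    # Re-draw until at least half of the signature genes actually move, so a
    # lucky near-identity shuffle cannot produce a trivial signature.
    while True:
        perm = rng.permutation(n)
        if np.sum(perm == np.arange(n)) <= n // 2:
            return perm


def simulate_counts(cfg: SimulationConfig, full_output: bool = False):
    """Simulate a counts matrix with planted clusters.

    Returns ``(CountMatrix, truth: Partition)``; with ``full_output=True``
    a third element maps each cluster label to its signature gene ids.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    is_bg = rng.random(cfg.n_genes) < cfg.bg_fraction
    means = np.where(
        is_bg,
        rng.lognormal(cfg.bg_log_mean, cfg.bg_log_sigma, cfg.n_genes),
        rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sigma, cfg.n_genes),
    )
    k = len(cfg.cluster_sizes)

    low_pool = np.flatnonzero(means < cfg.low_mean_cutoff)
    high_pool = np.flatnonzero(means > cfg.low_mean_cutoff)
    for name, pool, need in (
        ("lowly expressed (mean < cutoff)", low_pool, k * cfg.n_low_sig),
        ("highly expressed (mean > cutoff)", high_pool, k * cfg.n_high_sig),
    ):
        if pool.size < need:
            raise ValueError(
                f"insufficient genes in the {name} stratum: need {need}, have {pool.size}"
            )
    low_pool = rng.permutation(low_pool)
    high_pool = rng.permutation(high_pool)

    blocks, signatures = [], {}
    for c, size in enumerate(cfg.cluster_sizes):
        sel = np.concatenate(
            [
                low_pool[c * cfg.n_low_sig : (c + 1) * cfg.n_low_sig],
                high_pool[c * cfg.n_high_sig : (c + 1) * cfg.n_high_sig],
            ]
        )
        cluster_means = means.copy()
        if sel.size:
            cluster_means[sel] = means[sel[_signature_permutation(rng, sel.size)]]
        blocks.append(_sample_nb(rng, cluster_means, size, cfg.dispersion))
        signatures[c + 1] = sel

    counts = np.concatenate(blocks, axis=1)
    gene_ids = tuple(f"g{i:05d}" for i in range(cfg.n_genes))
    cell_ids = tuple(f"c{i:04d}" for i in range(cfg.n_cells))
    labels = np.repeat(np.arange(1, k + 1), cfg.cluster_sizes)
    cm = CountMatrix(counts, gene_ids, cell_ids)
    truth = Partition(labels, cell_ids)
    if full_output:
        sig_ids = {c: tuple(gene_ids[g] for g in sel) for c, sel in signatures.items()}
        return cm, truth, sig_ids
    return cm, truth


def write_simulation(out_dir, cm: CountMatrix, truth: Partition, cfg: SimulationConfig) -> None:
    """Write counts (.mtx + TSVs), truth labels and the config (YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_counts(cm, out / "counts", fmt="mtx_dir")
    truth.write_tsv(out / "true_labels.tsv")
    cfg_dict = asdict(cfg)
    cfg_dict["cluster_sizes"] = list(cfg_dict["cluster_sizes"])
    with open(out / "simulation_config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=False)
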