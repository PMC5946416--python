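"""End-to-end pipeline: preprocess -> rare stage -> common stage -> consensus.

All randomness (k-means restarts, gap-statistic references, t-SNE) is seeded
from one master seed, so two runs with the same configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import consensus as cons
from . import evaluate, fano, gini, viz
from .partition import Partition
from .preprocess import CountMatrix, filter_counts

log = logging.getLogger("ginifano")


@dataclass(frozen=True)
class PipelineConfig:
    # preprocessing
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 2000
    # rare-cell (Gini) stage
    gini_p: float = 1e-4
    eps: float = 0.5
    min_pts: int = 3
    loess_span: float = 0.9
    loess_outlier_quantile: float = 0.9
    robust_pvalues: bool = False
    # common-cell (Fano) stage
    n_fano: int = 1000
    n_pcs: int = 50
    k_fano: int | None = None  # None -> gap statistic
    gap_k_max: int = 6
    gap_n_refs: int = 20
    # consensus weighting
    mu: float = 0.05
    s: float = 0.00625
    f: float = 0.025
    k_final: int | None = None  # None -> choose_k_final rule
    # shared
    n_restarts: int = 20
    seed: int = 0


@dataclass
class PipelineResult:
    partition_gini: Partition
    partition_fano: Partition
    partition_final: Partition
    gene_scores: "object"
    fano_embedding: np.ndarray
    gini_distance: np.ndarray
    consensus: np.ndarray
    k_gini: int
    k_fano: int
    k_final: int
    report: dict = field(default_factory=dict)
    coords: np.ndarray | None = None


def run_pipeline(
    counts: CountMatrix,
    config: PipelineConfig = PipelineConfig(),
    ref_labels=None,
    out_dir=None,
    compute_tsne: bool = False,
) -> PipelineResult:
    """Run the full ensemble pipeline on a raw count matrix.

    When ``ref_labels`` is given, agreement metrics (ARI, NMI, per-type MCC)
    are added to the report; when ``out_dir`` is given, partitions, scores,
    the JSON report and (with ``compute_tsne``) composite coordinates are
    written there.
    """
    cfg = config
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2**31)

    filtered = filter_counts(counts, cfg.min_cells_per_gene, cfg.min_genes_per_cell)
    log.info(
        "preprocess: %d/%d genes, %d/%d cells kept",
        filtered.n_genes, counts.n_genes, filtered.n_cells, counts.n_cells,
    )
    timings["preprocess"] = time.perf_counter() - t0

    t = time.perf_counter()
    p_gini, scores, d_gini = gini.gini_stage(
        filtered,
        p_threshold=cfg.gini_p,
        eps=cfg.eps,
        min_pts=cfg.min_pts,
        span=cfg.loess_span,
        outlier_quantile=cfg.loess_outlier_quantile,
        robust=cfg.robust_pvalues,
    )
    log.info("gini stage: %d clusters, %d noise cells", p_gini.k, len(p_gini.noise_cells))
    timings["gini_stage"] = time.perf_counter() - t

    t = time.perf_counter()
    p_fano, emb, k_f = fano.fano_stage(
        filtered,
        k=cfg.k_fano,
        n_genes=cfg.n_fano,
        n_components=cfg.n_pcs,
        n_restarts=cfg.n_restarts,
        gap_k_max=cfg.gap_k_max,
        gap_n_refs=cfg.gap_n_refs,
        seed=int(seeds[0]),
    )
    log.info("fano stage: k = %d%s", k_f, "" if cfg.k_fano else " (gap statistic)")
    timings["fano_stage"] = time.perf_counter() - t

    t = time.perf_counter()
    params = cons.derive_params(mu=cfg.mu, s=cfg.s, f=cfg.f)
    w = cons.cell_weights(p_gini, params)
    mbar = cons.consensus_matrix(
        cons.connectivity(p_gini), cons.connectivity(p_fano), w, params
    )
    k_final = cfg.k_final if cfg.k_final is not None else cons.choose_k_final(
        p_gini, p_fano, params
    )
    p_final = cons.final_cluster(
        mbar, k_final, n_restarts=cfg.n_restarts, seed=int(seeds[1]),
        cell_ids=filtered.cell_ids,
    )
    log.info("consensus: k_final = %d", k_final)
    timings["consensus"] = time.perf_counter() - t

    report = {
        "config": asdict(cfg),
        "n_genes_raw": counts.n_genes,
        "n_cells_raw": counts.n_cells,
        "n_genes_filtered": filtered.n_genes,
        "n_cells_filtered": filtered.n_cells,
        "k_gini": p_gini.k,
        "k_fano": k_f,
        "k_final": k_final,
        "n_gini_noise": len(p_gini.noise_cells),
        "gini_cluster_sizes": p_gini.sizes,
        "fano_cluster_sizes": p_fano.sizes,
        "final_cluster_sizes": p_final.sizes,
        "weight_params": {
            "mu": params.mu, "s": params.s, "f": params.f,
            "mu_prime": params.mu_prime, "s_prime": params.s_prime,
            "f_prime": params.f_prime,
        },
        "seed": cfg.seed,
    }

    if ref_labels is not None:
        ref = _restrict_ref(ref_labels, filtered.cell_ids)
        report["metrics"] = {
            "ari": evaluate.ari(p_final.labels, ref),
            "nmi": evaluate.nmi(p_final.labels, ref),
            "mcc_per_type": {
                str(k): v for k, v in evaluate.mcc_per_type(p_final, ref).items()
            },
        }

    result = PipelineResult(
        partition_gini=p_gini,
        partition_fano=p_fano,
        partition_final=p_final,
        gene_scores=scores,
        fano_embedding=emb,
        gini_distance=d_gini,
        consensus=mbar,
        k_gini=p_gini.k,
        k_fano=k_f,
        k_final=k_final,
        report=report,
    )

    if compute_tsne:
        t = time.perf_counter()
        result.report["tsne"] = True
        coords = viz.composite_tsne(d_gini, emb, seed=int(seeds[2]))
        result.coords = coords
        timings["tsne"] = time.perf_counter() - t
    timings["total"] = time.perf_counter() - t0
    report["timings_sec"] = {k: round(v, 3) for k, v in timings.items()}

    if out_dir is not None:
        _write_outputs(Path(out_dir), result, filtered, compute_tsne)
    return result


def _restrict_ref(ref_labels, cell_ids):
    if isinstance(ref_labels, Partition):
        m = dict(zip(ref_labels.cell_ids, ref_labels.labels))
        return np.asarray([m[c] for c in cell_ids])
    if isinstance(ref_labels, dict):
        return np.asarray([ref_labels[c] for c in cell_ids])
    return np.asarray(ref_labels)


def _write_outputs(out, res: PipelineResult, filtered, compute_tsne):
    out.mkdir(parents=True, exist_ok=True)
    res.partition_gini.write_tsv(out / "partition_gini.tsv")
    res.partition_fano.write_tsv(out / "partition_fano.tsv")
    res.partition_final.write_tsv(out / "partition_final.tsv")
    res.gene_scores.to_csv(out / "gene_scores.tsv", sep="\t")
    np.savetxt(out / "fano_embedding.tsv", res.fano_embedding, delimiter="\t")
    with open(out / "report.json", "w") as fh:
        json.dump(res.report, fh, indent=2, default=str)
    if compute_tsne and hasattr(res, "coords"):
        viz.write_coordinates(res.coords, filtered.cell_ids, out / "tsne_coordinates.tsv")
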