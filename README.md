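# ginifano

Cluster-aware weighted ensemble clustering for single-cell RNA-seq: detect
**common and very rare cell types in the same partition**.

Standard scRNA-seq clustering pipelines select highly variable genes with
the Fano factor (variance/mean), reduce with PCA and cluster with k-means
or graph methods.  That recipe resolves abundant cell types but reliably
swallows rare populations of a handful of cells.  Conversely, rare-cell
detectors built on the Gini index — genes whose expression is concentrated
in very few cells — isolate tiny clusters but merge the abundant types.
`ginifano` runs both and reconciles them with a cluster-aware weighted
consensus, so each method is trusted exactly where it is strong.

## Model

Let P^G (Gini/DBSCAN) and P^F (Fano/PCA/k-means) be the two base
partitions, encoded as binary connectivity matrices M(P) with M_ij = 1 when
cells i and j share a cluster.  The consensus association is

    M̄_ij = w_ij^G · M_ij(P^G) + w_ij^F · M_ij(P^F),   w_ij^G + w_ij^F = 1,

where the pair weights derive from cell-specific weights: the Fano weight
is a constant f′, and the Gini weight of cell i is a decreasing logistic in
the proportion x_i of its Gini cluster,

    w̃_i^G(x_i) = 1 − 1 / (1 + exp(−(x_i − μ′)/s′)),

so membership in a tiny cluster is judged by the rare-cell method and
membership in a large one by the common-cell method.  A pair's Gini weight
is max(w̃_i^G, w̃_j^G), then the pair is normalized to sum to one.  The hard
consensus clustering solves min_U ‖M̄ − U‖² over connectivity matrices U,
which relaxes to k-means on the rows of M̄.  User-facing parameters:
μ (cluster proportion where both methods are trusted equally, default
0.05), s (transition width, default μ/8), f (weight of the common-cell
partition against a fully trusted rare call, default 0.025); see
`docs/methods.md` for the algebra and for guidance on f at large n.

The package also ships the negative-binomial simulator with planted common
and rare clusters used for validation, evaluation metrics (per-type MCC,
NMI, confusion maps), and a composite 3-D t-SNE view (two Fano dimensions
+ one Gini dimension) in which common and rare clusters separate
simultaneously.

## Worked example

Simulate 3,023 cells (common clusters of 2,000 and 1,000 cells; rare
clusters of 10, 6, 4 and 3 cells) over 23,538 genes, then run the full
pipeline with two common clusters:

```sh
ginifano simulate --out sim/
ginifano run --counts sim/counts --k-fano 2 --seed 0 \
             --ref-labels sim/true_labels.tsv --out run/
```

which prints

```
{"k_gini": 5, "k_fano": 2, "k_final": 6, "final_cluster_sizes": {"1": 2000, "2": 1000, "3": 10, "4": 6, "5": 4, "6": 3}}
```

Reading: the Gini stage found 5 clusters (the four rare ones plus one
merged common block), the Fano stage separated the two common clusters,
and the consensus recovered all six planted clusters at their exact sizes.
`run/report.json` additionally records ARI/NMI against the truth labels
(1.0 here), per-cluster sizes, the weight parameters and per-stage
timings; `run/partition_final.tsv` holds the labels.  The same pipeline is
available in Python via `ginifano.run_pipeline` — see `docs/methods.md`.

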