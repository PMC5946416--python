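"""Agreement between a predicted partition and reference cell labels.

Per-type detection is scored one-vs-rest with the Matthews correlation
coefficient (MCC, in [-1, 1]); overall agreement with normalized mutual
information (NMI, in [0, 1]); and a confusion map gives, for each reference
label, the proportion of its cells landing in each predicted cluster.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from .partition import Partition


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); 0 when any factor
    of the denominator vanishes (the standard convention).
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    if all(c == 0 for c in counts):
        raise ValueError("all four confusion counts are zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _align(pred: Partition, ref_labels) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ref_labels, Partition):
        ref_map = dict(zip(ref_labels.cell_ids, ref_labels.labels))
    elif isinstance(ref_labels, dict):
        ref_map = ref_labels
    else:
        ref = np.asarray(ref_labels)
        if ref.size != pred.n:
            raise ValueError("reference label vector length does not match prediction")
        return pred.labels, ref
    missing = [c for c in pred.cell_ids if c not in ref_map]
    if missing:
        raise ValueError(f"cells absent from the reference labels: {missing[:5]}")
    return pred.labels, np.asarray([ref_map[c] for c in pred.cell_ids])


def mcc_per_type(pred: Partition, ref_labels) -> dict:
    """One-vs-rest MCC per reference type.

    Each reference type's positive prediction set is the predicted cluster
    with the largest overlap (ties go to the larger cluster, then the smaller
    label); noise is never used as the positive set.
    """
    labels, ref = _align(pred, ref_labels)
    sizes = pred.sizes
    out = {}
    for t in pd.unique(ref):
        in_type = ref == t
        best = None
        for c in pred.cluster_ids:
            overlap = int(np.sum(in_type & (labels == c)))
            key = (overlap, sizes[c], -c)
            if best is None or key > best[0]:
                best = (key, c)
        if best is None or best[0][0] == 0:
            pos = np.zeros(pred.n, dtype=bool)
        else:
            pos = labels == best[1]
        tp = int(np.sum(pos & in_type))
        fp = int(np.sum(pos & ~in_type))
        fn = int(np.sum(~pos & in_type))
        tn = int(np.sum(~pos & ~in_type))
        out[t] = mcc(tp, tn, fp, fn)
    return out


def nmi(p1, p2, average: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions.

    Mutual information normalized by the arithmetic mean of the two label
    entropies by default (``average`` may also be ``"geometric"`` or
    ``"max"``).  1 for identical partitions up to relabeling; two single-
    cluster partitions score 1 by convention.
    """
    a = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if a.size != b.size:
        raise ValueError("partitions cover different numbers of cells")
    return float(normalized_mutual_info_score(a, b, average_method=average))


def confusion_map(pred: Partition, ref_labels) -> pd.DataFrame:
    """Rows = reference labels, columns = predicted clusters, rows sum to 1.

    Each entry is the proportion of the reference label's cells assigned to
    that predicted cluster (noise appears as column 0 when present).
    """
    labels, ref = _align(pred, ref_labels)
    tab = pd.crosstab(pd.Series(ref, name="reference"), pd.Series(labels, name="predicted"))
    return tab.div(tab.sum(axis=1), axis=0)


def ari(p1, p2) -> float:
    """Adjusted Rand index between two partitions (1 = identical up to relabeling)."""
    from sklearn.metrics import adjusted_rand_score

    a = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    return float(adjusted_rand_score(a, b))
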