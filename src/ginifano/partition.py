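"""Hard partitions of cells, with an explicit noise label.

A :class:`Partition` assigns every cell either to one of ``k`` clusters
(labels ``1..k``) or to noise (label ``0``, produced e.g. by DBSCAN for
low-density cells).  Cluster proportions are always taken relative to the
total number of cells, noise included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NOISE = 0


@dataclass(frozen=True)
class Partition:
    """Cluster label per cell; label 0 is reserved for noise."""

    labels: np.ndarray
    cell_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 encodes noise)")
        if self.cell_ids:
            ids = tuple(str(c) for c in self.cell_ids)
            if len(ids) != labels.size:
                raise ValueError(
                    f"{len(ids)} cell ids for {labels.size} labels"
                )
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate cell ids")
            object.__setattr__(self, "cell_ids", ids)
        else:
            object.__setattr__(
                self, "cell_ids", tuple(f"cell{i}" for i in range(labels.size))
            )

    @classmethod
    def from_labels(cls, labels, cell_ids=(), noise=None) -> "Partition":
        """Canonicalize arbitrary hashable labels to 1..k (first-seen order).

        ``noise`` marks the label value (e.g. -1 for scikit-learn DBSCAN)
        mapped to the noise label 0.
        """
        labels = list(labels)
        mapping: dict = {}
        out = np.empty(len(labels), dtype=np.int64)
        for i, lab in enumerate(labels):
            if noise is not None and lab == noise:
                out[i] = NOISE
                continue
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            out[i] = mapping[lab]
        return cls(out, tuple(cell_ids))

    @property
    def n(self) -> int:
        """Total number of cells, noise included."""
        return int(self.labels.size)

    @property
    def cluster_ids(self) -> tuple[int, ...]:
        return tuple(int(c) for c in np.unique(self.labels) if c != NOISE)

    @property
    def k(self) -> int:
        """Number of clusters (noise not counted)."""
        return len(self.cluster_ids)

    @property
    def sizes(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.cluster_ids}

    @property
    def proportions(self) -> dict[int, float]:
        """Cluster size over total cell count (noise cells stay in the denominator)."""
        n = self.n
        return {c: s / n for c, s in self.sizes.items()}

    @property
    def noise_cells(self) -> frozenset[str]:
        return frozenset(
            cid for cid, lab in zip(self.cell_ids, self.labels) if lab == NOISE
        )

    def members(self, cluster: int) -> tuple[str, ...]:
        idx = np.flatnonzero(self.labels == cluster)
        return tuple(self.cell_ids[i] for i in idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": list(self.cell_ids), "label": self.labels})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Partition":
        df = pd.read_csv(Path(path), sep="\t", dtype={"cell_id": str})
        return cls(df["label"].to_numpy(), tuple(df["cell_id"]))
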