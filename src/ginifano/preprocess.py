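"""Reading, validation and filtering of UMI count matrices.

Counts are held genes x cells as a dense integer array together with
gene and cell identifiers.  Two on-disk layouts are supported: a 10X-style
directory (``matrix.mtx`` plus ``genes.tsv``/``features.tsv`` and
``barcodes.tsv``) and a dense TSV/CSV with gene rows, cell columns and a
header row of cell ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class CountValidationError(ValueError):
    """Raised when a count matrix violates the integer/non-negative contract."""


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer UMI counts, genes x cells, with identifiers."""

    counts: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CountValidationError("counts must be a 2-D genes x cells array")
        if not np.issubdtype(counts.dtype, np.integer):
            frac = counts != np.floor(counts)
            if np.any(frac):
                g, c = np.argwhere(frac)[0]
                raise CountValidationError(
                    f"non-integer count {counts[g, c]!r} at gene row {g}, cell column {c}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            g, c = np.argwhere(counts < 0)[0]
            raise CountValidationError(
                f"negative count {counts[g, c]} at gene row {g}, cell column {c}"
            )
        gene_ids = tuple(str(g) for g in self.gene_ids)
        cell_ids = tuple(str(c) for c in self.cell_ids)
        if counts.shape != (len(gene_ids), len(cell_ids)):
            raise CountValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} gene ids x {len(cell_ids)} cell ids"
            )
        for name, ids in (("gene", gene_ids), ("cell", cell_ids)):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for i in ids:
                    if i in seen:
                        dup = i
                        break
                    seen.add(i)
                raise CountValidationError(f"duplicate {name} id: {dup!r}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "cell_ids", cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Sub-matrix by boolean masks or index arrays; values are untouched."""
        gi = np.arange(self.n_genes) if gene_mask is None else np.arange(self.n_genes)[gene_mask]
        ci = np.arange(self.n_cells) if cell_mask is None else np.arange(self.n_cells)[cell_mask]
        return CountMatrix(
            self.counts[np.ix_(gi, ci)],
            tuple(self.gene_ids[i] for i in gi),
            tuple(self.cell_ids[i] for i in ci),
        )

    def restrict_genes(self, gene_ids) -> "CountMatrix":
        wanted = set(gene_ids)
        mask = np.array([g in wanted for g in self.gene_ids])
        return self.subset(gene_mask=mask)


def _load_mtx_dir(path: Path) -> CountMatrix:
    mtx = path / "matrix.mtx"
    genes = next((path / n for n in ("genes.tsv", "features.tsv") if (path / n).exists()), None)
    barcodes = path / "barcodes.tsv"
    for f in (mtx, genes, barcodes):
        if f is None or not f.exists():
            missing = f if f is not None else path / "genes.tsv (or features.tsv)"
            raise FileNotFoundError(f"missing count matrix file: {missing}")
    mat = spio.mmread(mtx)
    if sparse.issparse(mat):
        mat = mat.toarray()
    gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].astype(str).tolist()
    cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    return CountMatrix(np.asarray(mat), tuple(gene_ids), tuple(cell_ids))


def _load_dense(path: Path) -> CountMatrix:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(df.to_numpy(), tuple(map(str, df.index)), tuple(map(str, df.columns)))


def load_counts(path, fmt: str = "auto") -> CountMatrix:
    """Load a genes x cells count matrix.

    Parameters
    ----------
    path
        Directory with ``matrix.mtx`` + TSV sidecars (``fmt="mtx_dir"``) or a
        dense TSV/CSV with gene rows and a cell-id header (``fmt="dense_tsv"``).
    fmt
        ``"mtx_dir"``, ``"dense_tsv"`` or ``"auto"`` (directory -> mtx_dir).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"counts input not found: {path}")
    if fmt == "auto":
        fmt = "mtx_dir" if path.is_dir() else "dense_tsv"
    if fmt == "mtx_dir":
        return _load_mtx_dir(path)
    if fmt == "dense_tsv":
        return _load_dense(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'mtx_dir' or 'dense_tsv'")


def save_counts(m: CountMatrix, path, fmt: str = "mtx_dir") -> None:
    """Write a CountMatrix back to disk in either supported layout."""
    path = Path(path)
    if fmt == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(m.counts))
        pd.Series(m.gene_ids).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    elif fmt == "dense_tsv":
        pd.DataFrame(m.counts, index=list(m.gene_ids), columns=list(m.cell_ids)).to_csv(
            path, sep="\t"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def filter_counts(
    m: CountMatrix,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 2000,
) -> CountMatrix:
    """Remove lowly detected genes, then lowly complex cells.

    A gene is "expressed" in a cell when its count is > 0.  Genes expressed in
    fewer than ``min_cells_per_gene`` cells are dropped first; cells expressing
    fewer than ``min_genes_per_cell`` of the remaining genes are dropped second.
    Exactly one gene pass then one cell pass is performed, so re-applying the
    filter after cells were removed may remove further genes.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("filter thresholds must be >= 0")
    expressed = m.counts > 0
    gene_mask = expressed.sum(axis=1) >= min_cells_per_gene
    expressed = expressed[gene_mask]
    cell_mask = expressed.sum(axis=0) >= min_genes_per_cell
    if not gene_mask.any() or not cell_mask.any():
        raise ValueError("empty matrix after filtering")
    return m.subset(gene_mask=gene_mask, cell_mask=cell_mask)


def median_library_scale(m: CountMatrix) -> np.ndarray:
    """Optional median-of-library-size scaling (off by default in the pipeline).

    Returns a float genes x cells matrix where each cell's counts are scaled by
    (median library size) / (cell library size).  Provided for exploratory use;
    the core pipeline consumes raw filtered counts.
    """
    lib = m.counts.sum(axis=0).astype(float)
    if np.any(lib == 0):
        warnings.warn("cells with zero library size left unscaled")
        lib[lib == 0] = 1.0
    return m.counts * (np.median(lib) / lib)[None, :]
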