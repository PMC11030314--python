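"""In-memory containers for the analysis: counts, normalized expression,
linear embeddings.

The containers are deliberately light (dataclasses over scipy.sparse /
pandas) rather than a full AnnData: the pipeline passes a handful of
well-defined objects between stages and every field is documented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["CountMatrix", "ExpressionMatrix", "Embedding", "MITO_PREFIX"]

#: mouse convention for mitochondrial gene symbols
MITO_PREFIX = "mt-"


def _as_csr(mat) -> sparse.csr_matrix:
    if sparse.issparse(mat):
        return mat.tocsr()
    return sparse.csr_matrix(np.asarray(mat))


@dataclass
class CountMatrix:
    """Raw integer counts, cells x genes, with per-cell metadata.

    cell_meta holds categorical labels (age, condition, genotype, pool)
    indexed like ``cell_ids``; gene_meta may carry a boolean ``mito`` flag
    (defaulted from the ``mt-`` prefix if absent).
    """

    counts: sparse.csr_matrix
    cell_ids: list
    gene_ids: list
    cell_meta: pd.DataFrame | None = None
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} matrix columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene identifiers")
        data = self.counts.data
        if data.size and (data.min() < 0 or np.any(data != np.round(data))):
            raise ValueError("counts must be nonnegative integers")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        else:
            self.cell_meta = self.cell_meta.copy()
            if len(self.cell_meta) != n:
                raise ValueError("cell_meta length does not match cell count")
            self.cell_meta.index = self.cell_ids
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.gene_ids)
        else:
            self.gene_meta = self.gene_meta.copy()
            if len(self.gene_meta) != g:
                raise ValueError("gene_meta length does not match gene count")
            self.gene_meta.index = self.gene_ids
        if "mito" not in self.gene_meta.columns:
            self.gene_meta["mito"] = [
                gid.lower().startswith(MITO_PREFIX) for gid in self.gene_ids
            ]

    # -- derived per-cell statistics -------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def mito_pct_per_cell(self) -> np.ndarray:
        """Percent of each cell's counts falling on mitochondrial genes."""
        mito = np.asarray(self.gene_meta["mito"].values, dtype=bool)
        total = self.counts_per_cell().astype(float)
        mito_counts = np.asarray(self.counts[:, mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total > 0, 100.0 * mito_counts / total, 0.0)
        return pct

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[keep],
            cell_ids=[self.cell_ids[i] for i in keep],
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.iloc[keep],
            gene_meta=self.gene_meta,
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class ExpressionMatrix:
    """Normalized expression values plus a record of how they were produced."""

    values: sparse.csr_matrix
    cell_ids: list
    gene_ids: list
    normalization: dict = field(default_factory=dict)
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = _as_csr(self.values).astype(float)
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("identifier lengths do not match matrix shape")
        if self.values.data.size and not np.all(np.isfinite(self.values.data)):
            raise ValueError("expression values must be finite")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        else:
            self.cell_meta = self.cell_meta.copy()
            self.cell_meta.index = self.cell_ids

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def gene_vector(self, gene: str) -> np.ndarray:
        return np.asarray(self.values[:, self.gene_index(gene)].todense()).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def cells_mask(self, cells) -> np.ndarray:
        """Boolean mask over rows for a list of cell ids (order ignored)."""
        wanted = set(map(str, cells))
        missing = wanted - set(self.cell_ids)
        if missing:
            raise KeyError(f"cells not present: {sorted(missing)[:5]}")
        return np.array([c in wanted for c in self.cell_ids])


@dataclass
class Embedding:
    """Linear (or other) low-dimensional coordinates for cells."""

    coords: np.ndarray
    cell_ids: list
    variance_explained: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (cells x components)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")
        self.cell_ids = list(map(str, self.cell_ids))
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell id count does not match coordinate rows")
        if self.variance_explained is not None:
            self.variance_explained = np.asarray(self.variance_explained, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]
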