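"""Reading and writing count matrices (10x-style MTX triplet or dense CSV).

MTX directories follow the 10x layout: ``matrix.mtx`` in MatrixMarket
coordinate integer format with 1-based indices and genes-as-rows,
``features.tsv`` and ``barcodes.tsv`` sidecars, and an optional
``cell_meta.tsv`` keyed by cell id.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix

__all__ = ["FormatError", "read_counts", "write_counts"]


class FormatError(ValueError):
    """Raised when an on-disk matrix violates its format contract."""


def _read_meta(path: str) -> pd.DataFrame | None:
    meta_path = os.path.join(path, "cell_meta.tsv")
    if os.path.exists(meta_path):
        return pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return None


def read_counts(path: str, format: str = "mtx_dir") -> CountMatrix:
    """Load a count matrix.

    format 'mtx_dir': *path* is a directory holding matrix.mtx (genes x
    cells, 1-based coordinate entries), features.tsv, barcodes.tsv.
    format 'csv': *path* is a CSV with cells as rows, a header row of gene
    ids, and the first column holding cell ids.
    """
    if format == "mtx_dir":
        mtx_path = os.path.join(path, "matrix.mtx")
        for required in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
            if not os.path.exists(os.path.join(path, required)):
                raise FileNotFoundError(os.path.join(path, required))
        try:
            mat = spio.mmread(mtx_path)
        except ValueError as exc:
            raise FormatError(f"{mtx_path}: {exc}") from exc
        genes = pd.read_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=None
        )[0].astype(str).tolist()
        cells = pd.read_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=None
        )[0].astype(str).tolist()
        mat = sparse.csr_matrix(mat)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"{mtx_path}: matrix is {mat.shape} but sidecars declare "
                f"{len(genes)} features x {len(cells)} barcodes"
            )
        counts = mat.T.tocsr()  # cells x genes
        meta = _read_meta(path)
        if meta is not None:
            try:
                meta = meta.loc[cells]
            except KeyError as exc:
                raise FormatError(f"cell_meta.tsv missing barcodes: {exc}") from exc
        return CountMatrix(counts=counts, cell_ids=cells, gene_ids=genes, cell_meta=meta)
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy()
        if values.size and np.any(values != np.round(values)):
            raise FormatError(f"{path}: non-integer entries in count CSV")
        return CountMatrix(
            counts=sparse.csr_matrix(values.astype(np.int64)),
            cell_ids=df.index.astype(str).tolist(),
            gene_ids=df.columns.astype(str).tolist(),
        )
    raise ValueError(f"unknown format {format!r}")


def write_counts(cm: CountMatrix, path: str, format: str = "mtx_dir") -> None:
    """Write a count matrix; round-trips bit-exactly through read_counts."""
    if format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        mat = sparse.coo_matrix(cm.counts.T)  # genes x cells, 10x orientation
        spio.mmwrite(
            os.path.join(path, "matrix.mtx"),
            mat,
            field="integer",
            symmetry="general",
        )
        with open(os.path.join(path, "features.tsv"), "w") as fh:
            fh.write("\n".join(cm.gene_ids) + "\n")
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(cm.cell_ids) + "\n")
        if cm.cell_meta is not None and cm.cell_meta.shape[1] > 0:
            cm.cell_meta.to_csv(os.path.join(path, "cell_meta.tsv"), sep="\t")
    elif format == "csv":
        pd.DataFrame(
            cm.dense(), index=cm.cell_ids, columns=cm.gene_ids
        ).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
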