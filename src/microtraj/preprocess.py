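"""QC filtering, normalization, feature selection and linear embedding.

The defaults mirror the standard droplet scRNA-seq workflow: strict QC
cutoffs on detected genes / total counts / mitochondrial percentage,
log normalization to 10,000 counts per cell with natural log and
pseudocount 1, variance-stabilizing (vst-style) highly-variable-gene
ranking, per-gene scaling with clipping, and PCA with a fixed sign
convention.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse
from sklearn.decomposition import PCA as _SKPCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix, Embedding, ExpressionMatrix

__all__ = [
    "qc_filter",
    "marker_gate",
    "lognormalize",
    "select_hvg",
    "scale_center",
    "pca",
]

log = logging.getLogger(__name__)

#: clip for scaled expression values, in standard deviations
SCALE_CLIP = 10.0


def qc_filter(
    cm: CountMatrix,
    min_genes: float = 1000,
    min_counts: float = 10000,
    max_mito_pct: float = 5.0,
) -> CountMatrix:
    """Retain cells with genes > min_genes, counts > min_counts and
    mitochondrial percentage < max_mito_pct (all strict comparisons).

    The gene set is unchanged.  If no cell passes, an empty matrix is
    returned with a warning rather than an exception.
    """
    genes = cm.genes_per_cell()
    counts = cm.counts_per_cell()
    mito = cm.mito_pct_per_cell()
    keep = (genes > min_genes) & (counts > min_counts) & (mito < max_mito_pct)
    n_removed = int(cm.n_cells - keep.sum())
    log.info("qc_filter removed %d of %d cells", n_removed, cm.n_cells)
    if not keep.any():
        log.warning("qc_filter: no cells passed thresholds (%s, %s, %s)",
                    min_genes, min_counts, max_mito_pct)
    return cm.subset_cells(keep)


def marker_gate(cm: CountMatrix, gates: list[tuple[str, str, float]]) -> CountMatrix:
    """Filter cells by a conjunction of raw-count predicates.

    Each gate is ``(gene, op, threshold)`` with op in {'>', '<'}.  An empty
    gate list is the identity.  A missing gene raises KeyError naming it.
    """
    keep = np.ones(cm.n_cells, dtype=bool)
    for gene, op, threshold in gates:
        j = cm.gene_index(gene)  # raises KeyError naming the gene
        col = np.asarray(cm.counts[:, j].todense()).ravel()
        if op == ">":
            keep &= col > threshold
        elif op == "<":
            keep &= col < threshold
        else:
            raise ValueError(f"gate operator must be '>' or '<', got {op!r}")
    return cm.subset_cells(keep)


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """value = ln(1 + count / cell_total * scale_factor).

    Cells with zero total counts stay all-zero.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = cm.counts_per_cell().astype(float)
    inv = np.zeros_like(totals)
    nz = totals > 0
    inv[nz] = scale_factor / totals[nz]
    scaled = sparse.diags(inv) @ cm.counts.astype(float)
    scaled = scaled.tocsr()
    scaled.data = np.log1p(scaled.data)
    return ExpressionMatrix(
        values=scaled,
        cell_ids=cm.cell_ids,
        gene_ids=cm.gene_ids,
        normalization={
            "scale_factor": scale_factor,
            "log_base": "e",
            "pseudocount": 1.0,
        },
        cell_meta=cm.cell_meta,
    )


def _vst_standardized_variance(counts: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Standardized variance per gene after a mean-variance trend fit.

    log10(variance) is regressed on log10(mean) with lowess (span 0.3) over
    genes with positive variance; counts are standardized by the trend's
    expected sd, clipped at sqrt(n_cells), and the variance of the clipped
    values is returned.  Constant genes get 0.
    """
    n = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    out = np.zeros(counts.shape[1])
    fit_mask = (var > 0) & (mean > 0)
    if fit_mask.sum() < 3:
        out[fit_mask] = var[fit_mask]
        return out
    lx = np.log10(mean[fit_mask])
    ly = np.log10(var[fit_mask])
    smoothed = lowess(ly, lx, frac=span, return_sorted=False)
    exp_sd = np.sqrt(10.0 ** smoothed)
    clip = np.sqrt(n)
    z = (counts[:, fit_mask] - mean[fit_mask]) / exp_sd
    np.clip(z, -clip, clip, out=z)
    out[fit_mask] = z.var(axis=0, ddof=1)
    return out


def select_hvg(cm: CountMatrix, n_top: int = 2500, span: float = 0.3) -> list[str]:
    """Rank genes by vst-style standardized variance; return the top n_top.

    Ties are broken by gene id for determinism.
    """
    if n_top > cm.n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {cm.n_genes}")
    counts = cm.dense().astype(float)
    sv = _vst_standardized_variance(counts, span=span)
    order = sorted(range(cm.n_genes), key=lambda j: (-sv[j], cm.gene_ids[j]))
    return [cm.gene_ids[j] for j in order[:n_top]]


def scale_center(
    em: ExpressionMatrix,
    genes: list[str] | None = None,
    clip: float = SCALE_CLIP,
) -> tuple[np.ndarray, list[str]]:
    """Per-gene center to mean 0 and scale to unit variance (ddof=1),
    clipping at +/-clip.  Zero-variance genes become all-zero columns.

    Returns (cells x genes array, gene order used).
    """
    if genes is None:
        genes = em.gene_ids
    idx = [em.gene_index(g) for g in genes]
    x = np.asarray(em.values[:, idx].todense(), dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    np.clip(out, -clip, clip, out=out)
    return out, list(genes)


def pca(scaled: np.ndarray, n_components: int = 25, cell_ids=None) -> Embedding:
    """PCA with components ordered by decreasing variance explained.

    The sign of each component is fixed by forcing its largest-magnitude
    loading positive, making the embedding deterministic.
    """
    x = np.asarray(scaled, dtype=float)
    max_rank = min(x.shape)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds max rank {max_rank}"
        )
    model = _SKPCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(x)
    flip = np.ones(n_components)
    for c in range(n_components):
        j = np.argmax(np.abs(model.components_[c]))
        if model.components_[c, j] < 0:
            flip[c] = -1.0
    coords = coords * flip
    if cell_ids is None:
        cell_ids = [str(i) for i in range(x.shape[0])]
    return Embedding(
        coords=coords,
        cell_ids=cell_ids,
        variance_explained=model.explained_variance_ratio_,
    )
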