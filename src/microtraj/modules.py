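"""Trajectory-dependent gene discovery and module grouping.

Genes varying focally over the cell graph are detected with Moran's I,

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,

tested one-sided for positive autocorrelation either by permutation of the
cell labels or analytically under the randomization assumption, with
Benjamini-Hochberg control across genes (the study-default significance
cutoff is q < 0.005).  Significant genes are smoothed along pseudotime
(binned means, computed per branch and concatenated when branch labels
exist), connected in a correlation kNN graph, and partitioned into
coregulated modules by Louvain community detection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps

from .containers import ExpressionMatrix
from .graph import CellGraph, louvain_partition
from .stats import bh_qvalues
from .trajectory import Trajectory

__all__ = ["AutocorrResult", "GeneModules", "morans_i", "morans_test",
           "discover_modules", "top_module_genes", "Q_CUTOFF"]

#: study-default significance cutoff for focal expression
Q_CUTOFF = 0.005


@dataclass
class AutocorrResult:
    """Per-gene Moran's I with p/q values.

    ``table`` is indexed by gene with columns I, expected_I, p, q,
    constant.  expected_I is exactly -1/(n-1).
    """

    table: pd.DataFrame
    n: int
    method: str

    def significant(self, q_cutoff: float = Q_CUTOFF) -> list[str]:
        t = self.table
        return t.index[(t["q"] < q_cutoff) & ~t["constant"]].tolist()

    def qvalues(self) -> pd.Series:
        return self.table["q"]


@dataclass
class GeneModules:
    """Partition of trajectory-significant genes into coregulated modules.

    Module ids are 1..M ordered by descending module size; per-module gene
    lists are sorted by ascending q-value (ties by gene id).
    """

    assignment: dict
    resolution: float
    seed: int
    qvalues: dict
    flags: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def genes_of(self, module_id: int) -> list[str]:
        genes = [g for g, m in self.assignment.items() if m == module_id]
        return sorted(genes, key=lambda g: (self.qvalues.get(g, math.nan)
                                            if not math.isnan(self.qvalues.get(g, math.nan))
                                            else math.inf, g))

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)


def morans_i(x: np.ndarray, g: CellGraph) -> float:
    """Moran's I of a per-cell vector on the cell graph.

    Raises on a constant vector (I is undefined there).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != g.n:
        raise ValueError("vector length does not match graph size")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    num = float(z @ (g.adjacency @ z))
    return (g.n / g.W) * num / ss


def _batch_morans(zc: np.ndarray, g: CellGraph) -> np.ndarray:
    """I for each column of a centered matrix (columns with ss=0 -> nan)."""
    ss = np.einsum("ij,ij->j", zc, zc)
    num = np.einsum("ij,ij->j", zc, g.adjacency @ zc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ss > 0, (g.n / g.W) * num / ss, np.nan)


def _analytic_p(zc: np.ndarray, i_obs: np.ndarray, g: CellGraph) -> np.ndarray:
    """One-sided normal p under the randomization assumption."""
    n = g.n
    a = g.adjacency
    s0 = float(a.sum())
    s1 = float(2.0 * (a.multiply(a)).sum())          # (1/2) sum (w_ij + w_ji)^2
    row = np.asarray(a.sum(axis=1)).ravel()
    s2 = float(np.sum((2.0 * row) ** 2))
    e_i = -1.0 / (n - 1)
    ss = np.einsum("ij,ij->j", zc, zc)
    m4 = np.einsum("ij,ij->j", zc * zc, zc * zc)
    with np.errstate(invalid="ignore", divide="ignore"):
        b2 = n * m4 / ss**2
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    var = num / den - e_i**2
    var = np.maximum(var, 1e-300)
    z = (i_obs - e_i) / np.sqrt(var)
    return sps.norm.sf(z)


def morans_test(
    em: ExpressionMatrix,
    g: CellGraph,
    genes: list[str] | None = None,
    method: str = "permutation",
    n_perm: int = 999,
    seed: int = 0,
) -> AutocorrResult:
    """Test genes for positive graph autocorrelation.

    method 'permutation': p = (1 + #{permuted I >= observed I}) / (1 + n_perm),
    one-sided.  method 'analytic': normal approximation under the
    randomization-assumption variance.  method 'exhaustive': enumerate all
    n! cell permutations (n <= 8 only).  Constant genes get p = 1 and are
    flagged.  q-values are Benjamini-Hochberg across the tested genes.
    """
    if genes is None:
        genes = em.gene_ids
    if len(genes) == 0:
        raise ValueError("empty gene list")
    if em.n_cells != g.n:
        raise ValueError("expression matrix and graph disagree on cell count")
    idx = [em.gene_index(gx) for gx in genes]
    x = np.asarray(em.values[:, idx].todense(), dtype=float)
    zc = x - x.mean(axis=0)
    i_obs = _batch_morans(zc, g)
    constant = np.isnan(i_obs)

    if method == "permutation":
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(genes))
        for _ in range(n_perm):
            perm = rng.permutation(g.n)
            i_perm = _batch_morans(zc[perm], g)
            exceed += (i_perm >= i_obs - 1e-12)  # ties count as exceedances
        p = (1.0 + exceed) / (1.0 + n_perm)
    elif method == "analytic":
        p = _analytic_p(zc, i_obs, g)
    elif method == "exhaustive":
        if g.n > 8:
            raise ValueError("exhaustive enumeration only for n <= 8")
        total = math.factorial(g.n)
        exceed = np.zeros(len(genes))
        for perm in itertools.permutations(range(g.n)):
            i_perm = _batch_morans(zc[list(perm)], g)
            exceed += (i_perm >= i_obs - 1e-12)
        # the identity permutation is part of the reference set
        p = exceed / total
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.where(constant, 1.0, p)
    q = bh_qvalues(p)
    table = pd.DataFrame(
        {
            "I": i_obs,
            "expected_I": -1.0 / (g.n - 1),
            "p": p,
            "q": q,
            "constant": constant,
        },
        index=list(genes),
    )
    return AutocorrResult(table=table, n=g.n, method=method)


def _binned_profile(values: np.ndarray, t: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bin means of *values* ordered by pseudotime."""
    order = np.argsort(t, kind="mergesort")
    chunks = np.array_split(order, n_bins)
    return np.array([values[c].mean(axis=0) for c in chunks if c.size > 0])


def _gene_profiles(
    em: ExpressionMatrix,
    traj: Trajectory,
    genes: list[str],
    n_bins: int,
) -> np.ndarray:
    """Smoothed per-gene profiles: binned pseudotime means, per branch path.

    With branch labels, each non-trunk branch defines a path trunk+branch
    and the binned means over paths are concatenated, so branch-specific
    programs stay distinguishable.  Returns genes x bins array.
    """
    idx = [em.gene_index(gx) for gx in genes]
    x = np.asarray(em.values[:, idx].todense(), dtype=float)
    t = traj.pseudotime
    if traj.branch_labels is None:
        prof = _binned_profile(x, t, n_bins)
        return prof.T
    branches = sorted({b for b in traj.branch_labels if b != "trunk"})
    if not branches:
        return _binned_profile(x, t, n_bins).T
    parts = []
    trunk = traj.branch_labels == "trunk"
    for b in branches:
        mask = trunk | (traj.branch_labels == b)
        parts.append(_binned_profile(x[mask], t[mask], n_bins))
    return np.vstack(parts).T


def discover_modules(
    em: ExpressionMatrix,
    traj: Trajectory,
    sig_genes,
    resolution: float = 1.0,
    k_gene: int = 10,
    seed: int = 0,
    n_bins: int = 20,
) -> GeneModules:
    """Group trajectory-significant genes into coregulated modules.

    *sig_genes* is a list of gene ids, or a mapping / Series gene -> q-value
    (q-values order the per-module representatives).  Pipeline: smooth along
    pseudotime -> pairwise Pearson correlation of profiles -> k-nearest-
    neighbor gene graph (union-symmetrized, binary) -> Louvain at the given
    resolution.  Module ids are renumbered 1..M by descending size.
    """
    if isinstance(sig_genes, pd.Series):
        qmap = sig_genes.to_dict()
        genes = list(sig_genes.index)
    elif isinstance(sig_genes, dict):
        qmap = dict(sig_genes)
        genes = list(sig_genes)
    else:
        genes = list(sig_genes)
        qmap = {gx: math.nan for gx in genes}
    if len(genes) < 2:
        raise ValueError("need at least 2 significant genes")

    profiles = _gene_profiles(em, traj, genes, n_bins)
    sd = profiles.std(axis=1)
    flags = {}
    keep = sd > 0
    if not keep.all():
        flags["constant_profiles_dropped"] = [g for g, k in zip(genes, keep) if not k]
        genes = [g for g, k in zip(genes, keep) if k]
        profiles = profiles[keep]
        if len(genes) < 2:
            raise ValueError("fewer than 2 genes with varying profiles")
    corr = np.corrcoef(profiles)
    np.fill_diagonal(corr, -np.inf)

    n_g = len(genes)
    k_eff = min(k_gene, n_g - 1)
    rows, cols = [], []
    for j in range(n_g):
        nbrs = np.argsort(-corr[j], kind="mergesort")[:k_eff]
        rows.extend([j] * k_eff)
        cols.extend(nbrs.tolist())
    a = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_g, n_g))
    a = a.maximum(a.T).tocsr()
    a.setdiag(0)
    a.eliminate_zeros()
    gene_graph = CellGraph(adjacency=a, cell_ids=genes,
                           construction={"k": k_eff, "metric": "pearson",
                                         "space": "profile"})
    part = louvain_partition(gene_graph, resolution=resolution, seed=seed)

    sizes = np.bincount(part.labels)
    order = np.argsort(-sizes, kind="mergesort")
    rank = np.empty(sizes.size, dtype=int)
    rank[order] = np.arange(sizes.size)
    assignment = {g: int(rank[part.labels[j]]) + 1 for j, g in enumerate(genes)}
    if len(set(assignment.values())) == 1:
        flags["single_module"] = True
    return GeneModules(
        assignment=assignment,
        resolution=resolution,
        seed=seed,
        qvalues={g: qmap.get(g, math.nan) for g in genes},
        flags=flags,
    )


def top_module_genes(gm: GeneModules, k: int = 10) -> dict[int, list[str]]:
    """Per module, the k genes with smallest q-value (ties by gene id)."""
    return {m: gm.genes_of(m)[:k] for m in gm.module_ids}
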