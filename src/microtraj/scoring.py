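"""Projection of contrasts onto gene modules and related summary statistics.

A module is collapsed onto a contrast by computing, per gene, the log2
fold change of group means of normalized expression (with a pseudocount),
then testing the module's mean log2FC against 0 with a one-sample t-test
in log2 space (null hypothesis of no change).  Dotplot statistics (percent
of cells expressing and average normalized expression) and the
quartile-binned co-expression analysis (anchor-gene quartiles, per-gene
z-scored quartile means, Friedman omnibus + Dunn's pairwise comparisons)
are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix
from .stats import dunn_posthoc

__all__ = [
    "ModuleShift",
    "DotplotStats",
    "QuartileResult",
    "module_log2fc",
    "module_shift_test",
    "dotplot_stats",
    "quartile_bins",
    "quartile_coexpression",
]

#: default pseudocount for log2 fold changes of normalized means
DEFAULT_EPSILON = 0.01


@dataclass
class ModuleShift:
    """Mean log2 fold change of one module plus a one-sample t-test vs 0."""

    module_id: object
    log2fc: pd.Series
    mean_log2fc: float
    t_statistic: float
    p_value: float
    n_genes: int
    epsilon: float
    degenerate: bool = False
    n_dropped: int = 0


@dataclass
class DotplotStats:
    """Per (gene, group) percent-expressing and mean normalized expression."""

    table: pd.DataFrame  # MultiIndex (gene, group): pct_expressing, avg_expression


@dataclass
class QuartileResult:
    anchor_gene: str
    quartile: pd.Series                  # per cell: Q1..Q4
    tested_genes: list
    zscores: pd.DataFrame                # genes x quartiles, z-scored means
    friedman_statistic: float
    friedman_p: float
    dunn: dict
    excluded: dict = field(default_factory=dict)  # gene -> pct expressing


def module_log2fc(
    em: ExpressionMatrix,
    genes: list[str],
    group_a_cells,
    group_b_cells,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[pd.Series, int]:
    """Per-gene log2((mean_a + eps) / (mean_b + eps)) of normalized values.

    Genes whose mean is 0 in both groups are dropped; the count of dropped
    genes is returned alongside.
    """
    mask_a = em.cells_mask(group_a_cells)
    mask_b = em.cells_mask(group_b_cells)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both contrast groups must be nonempty")
    idx = [em.gene_index(gx) for gx in genes]
    x = np.asarray(em.values[:, idx].todense(), dtype=float)
    mean_a = x[mask_a].mean(axis=0)
    mean_b = x[mask_b].mean(axis=0)
    both_zero = (mean_a == 0) & (mean_b == 0)
    lfc = np.log2((mean_a + epsilon) / (mean_b + epsilon))
    out = pd.Series(lfc[~both_zero], index=[g for g, z in zip(genes, both_zero) if not z])
    if out.empty:
        raise ValueError("every gene had zero mean in both groups")
    return out, int(both_zero.sum())


def module_shift_test(
    log2fcs: pd.Series | np.ndarray,
    module_id=None,
    epsilon: float = DEFAULT_EPSILON,
) -> ModuleShift:
    """One-sample t-test of per-gene log2 fold changes against 0.

    t = mean / (sd / sqrt(n)), two-sided p from the t distribution with
    n - 1 degrees of freedom.  A zero-variance vector yields a flagged
    degenerate result (t = 0, p = 1 when the mean is 0; p undefined -> NaN
    otherwise).
    """
    values = pd.Series(log2fcs).astype(float)
    finite = values[np.isfinite(values)]
    n_dropped = len(values) - len(finite)
    if len(finite) < 2:
        raise ValueError("need >= 2 finite log2 fold changes")
    sd = finite.std(ddof=1)
    mean = finite.mean()
    if sd == 0:
        return ModuleShift(
            module_id=module_id, log2fc=finite, mean_log2fc=float(mean),
            t_statistic=0.0 if mean == 0 else np.nan,
            p_value=1.0 if mean == 0 else np.nan,
            n_genes=len(finite), epsilon=epsilon,
            degenerate=True, n_dropped=n_dropped,
        )
    res = sps.ttest_1samp(finite, popmean=0.0)
    return ModuleShift(
        module_id=module_id,
        log2fc=finite,
        mean_log2fc=float(mean),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_genes=len(finite),
        epsilon=epsilon,
        n_dropped=n_dropped,
    )


def dotplot_stats(
    em: ExpressionMatrix,
    genes: list[str],
    groups: dict[str, list],
) -> DotplotStats:
    """Percent of cells expressing (> 0) and mean normalized expression.

    *groups* maps group label -> cell ids; groups must be nonempty.
    """
    rows = []
    for label, cells in groups.items():
        mask = em.cells_mask(cells)
        if not mask.any():
            raise ValueError(f"group {label!r} is empty")
        idx = [em.gene_index(gx) for gx in genes]
        x = np.asarray(em.values[:, idx].todense(), dtype=float)[mask]
        pct = 100.0 * (x > 0).mean(axis=0)
        avg = x.mean(axis=0)
        for gx, p, a in zip(genes, pct, avg):
            rows.append((gx, label, float(p), float(a)))
    table = pd.DataFrame(
        rows, columns=["gene", "group", "pct_expressing", "avg_expression"]
    ).set_index(["gene", "group"])
    return DotplotStats(table=table)


def quartile_bins(em: ExpressionMatrix, anchor_gene: str) -> pd.Series:
    """Assign each cell to an anchor-expression quartile Q1(lowest)..Q4.

    Cells are ranked by anchor expression with ties broken by cell id and
    split into four near-equal bins (sizes differ by at most 1).
    """
    if em.n_cells < 4:
        raise ValueError("need at least 4 cells for quartile binning")
    x = em.gene_vector(anchor_gene)
    order = sorted(range(em.n_cells), key=lambda i: (x[i], em.cell_ids[i]))
    labels = np.empty(em.n_cells, dtype=object)
    chunks = np.array_split(np.asarray(order), 4)
    for qi, chunk in enumerate(chunks):
        labels[chunk] = f"Q{qi + 1}"
    return pd.Series(labels, index=em.cell_ids, name=f"{anchor_gene}_quartile")


def quartile_coexpression(
    em: ExpressionMatrix,
    anchor_gene: str,
    target_genes: list[str],
    pct_min: float = 25.0,
) -> QuartileResult:
    """Quartile-binned co-expression ('autocrine') analysis.

    Target genes expressed in more than pct_min percent of cells are kept;
    per gene, the four quartile means of normalized expression are z-scored
    across quartiles; a Friedman test (genes as blocks, quartiles as
    treatments) gives the omnibus p, and Dunn's pairwise comparisons
    against Q1 (Holm-corrected) follow.
    """
    quart = quartile_bins(em, anchor_gene)
    idx = [em.gene_index(gx) for gx in target_genes]
    x = np.asarray(em.values[:, idx].todense(), dtype=float)
    pct = 100.0 * (x > 0).mean(axis=0)
    keep = pct > pct_min
    excluded = {g: float(p) for g, p, k in zip(target_genes, pct, keep) if not k}
    tested = [g for g, k in zip(target_genes, keep) if k]
    if not tested:
        raise ValueError(
            f"no target gene expressed in > {pct_min}% of cells; "
            f"per-gene percents: {excluded}"
        )
    qlabels = ["Q1", "Q2", "Q3", "Q4"]
    qmask = {q: (quart.values == q) for q in qlabels}
    means = np.array([
        [x[qmask[q]][:, j].mean() for q in qlabels]
        for j, (g, k) in enumerate(zip(target_genes, keep)) if k
    ])
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / sd, 0.0)
    zdf = pd.DataFrame(z, index=tested, columns=qlabels)
    if len(tested) >= 2:
        stat, p = sps.friedmanchisquare(*[z[:, j] for j in range(4)])
        dunn = dunn_posthoc(z, reference=0, correction="holm")
    else:
        # a single gene cannot support the genes-as-blocks omnibus test
        stat, p = float("nan"), float("nan")
        dunn = {}
    return QuartileResult(
        anchor_gene=anchor_gene,
        quartile=quart,
        tested_genes=tested,
        zscores=zdf,
        friedman_statistic=float(stat),
        friedman_p=float(p),
        dunn=dunn,
        excluded=excluded,
    )
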