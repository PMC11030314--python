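"""Rank-sum differential expression and chi-square overlap of gene sets.

DE between two cell groups uses the two-sided Mann-Whitney U (Wilcoxon
rank-sum) test per gene — exact enumeration for small tie-free groups,
normal approximation with tie correction otherwise — with BH control
across tested genes.  The significance of the overlap between two DE gene
sets over a common universe is assessed with a Pearson chi-square test on
the 2x2 membership table (no continuity correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix
from .scoring import DEFAULT_EPSILON
from .stats import bh_qvalues

__all__ = ["DEResult", "OverlapResult", "rank_sum_de", "overlap_chisq",
           "concordant_intersection"]


@dataclass
class DEResult:
    """Per-gene rank-sum DE table: log2FC, p, q, pct per group."""

    table: pd.DataFrame
    group_sizes: tuple
    filters: dict

    def significant(self, q_cutoff: float = 0.05) -> list[str]:
        return self.table.index[self.table["q"] < q_cutoff].tolist()


@dataclass
class OverlapResult:
    universe_size: int
    n_a: int
    n_b: int
    n_overlap: int
    table: np.ndarray
    chi2: float
    p_value: float
    degenerate: bool = False


def _ranksum_p(a: np.ndarray, b: np.ndarray, use_continuity: bool = False) -> float:
    """Two-sided Mann-Whitney p; exact when both groups <= 8 and tie-free."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    if len(a) <= 8 and len(b) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method,
        use_continuity=use_continuity,
    )
    return float(res.pvalue)


def rank_sum_de(
    em: ExpressionMatrix,
    group_a,
    group_b,
    min_pct: float = 10.0,
    min_abs_log2fc: float = 0.0,
    epsilon: float = DEFAULT_EPSILON,
    use_continuity: bool = False,
) -> DEResult:
    """Wilcoxon rank-sum DE of normalized expression between two groups.

    Genes are prefiltered to those expressed in at least min_pct percent of
    cells in either group and with |log2FC| >= min_abs_log2fc.  Constant
    genes get p = 1.  BH q-values are computed across tested genes.
    """
    mask_a = em.cells_mask(group_a)
    mask_b = em.cells_mask(group_b)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("both groups need at least 3 cells")
    x = em.dense()
    xa, xb = x[mask_a], x[mask_b]
    pct_a = 100.0 * (xa > 0).mean(axis=0)
    pct_b = 100.0 * (xb > 0).mean(axis=0)
    lfc = np.log2((xa.mean(axis=0) + epsilon) / (xb.mean(axis=0) + epsilon))
    tested = ((np.maximum(pct_a, pct_b) >= min_pct)
              & (np.abs(lfc) >= min_abs_log2fc))
    genes = [g for g, t in zip(em.gene_ids, tested) if t]
    if not genes:
        raise ValueError("no gene passes the DE prefilters")
    cols = np.flatnonzero(tested)
    p = np.array([
        _ranksum_p(xa[:, j], xb[:, j], use_continuity=use_continuity)
        for j in cols
    ])
    q = bh_qvalues(p)
    table = pd.DataFrame(
        {
            "log2fc": lfc[cols],
            "p": p,
            "q": q,
            "pct_a": pct_a[cols],
            "pct_b": pct_b[cols],
        },
        index=genes,
    )
    return DEResult(
        table=table,
        group_sizes=(int(mask_a.sum()), int(mask_b.sum())),
        filters={"min_pct": min_pct, "min_abs_log2fc": min_abs_log2fc,
                 "use_continuity": use_continuity, "epsilon": epsilon},
    )


def overlap_chisq(set_a, set_b, universe) -> OverlapResult:
    """Pearson chi-square (1 df, no continuity correction) for the overlap
    of two gene sets within a universe.

    Degenerate margins (a set empty or equal to the universe) are flagged
    and yield chi2 = 0, p = 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    n_ab = len(a & b)
    table = np.array([
        [n_ab, len(a) - n_ab],
        [len(b) - n_ab, n - len(a) - len(b) + n_ab],
    ], dtype=float)
    degenerate = (len(a) in (0, n)) or (len(b) in (0, n))
    if degenerate:
        return OverlapResult(
            universe_size=n, n_a=len(a), n_b=len(b), n_overlap=n_ab,
            table=table, chi2=0.0, p_value=1.0, degenerate=True,
        )
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return OverlapResult(
        universe_size=n, n_a=len(a), n_b=len(b), n_overlap=n_ab,
        table=table, chi2=float(chi2), p_value=float(p),
    )


def concordant_intersection(de_a: DEResult, de_b: DEResult,
                            q_cutoff: float = 0.05) -> set:
    """Significant genes shared by two DE results whose log2FC signs agree."""
    shared = set(de_a.significant(q_cutoff)) & set(de_b.significant(q_cutoff))
    return {
        g for g in shared
        if np.sign(de_a.table.loc[g, "log2fc"]) == np.sign(de_b.table.loc[g, "log2fc"])
    }
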