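"""Shared statistical primitives: FDR control and rank-based post-hoc tests.

These are used across the discovery (Moran's I screening), differential
expression, and quartile co-expression modules so that every q-value in the
package comes from a single Benjamini–Hochberg implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["bh_qvalues", "holm_adjust", "dunn_posthoc"]


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values).

    q for the i-th order statistic is ``min_{j >= i} p_(j) * m / j``, capped
    at 1.  NaN p-values propagate as NaN and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down family-wise error adjustment."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    stepped = p[order] * (m - np.arange(m))
    stepped = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    return out


def dunn_posthoc(
    block_matrix: np.ndarray,
    reference: int = 0,
    correction: str = "holm",
) -> dict:
    """Dunn's multiple comparisons after a Friedman test.

    Parameters
    ----------
    block_matrix:
        blocks x treatments array (e.g. genes x quartiles).  Each row is
        ranked internally, as in the Friedman framework.
    reference:
        column index every other treatment is compared against.
    correction:
        'holm' (default) or 'none'.

    Returns a dict with the per-comparison z statistics and adjusted
    two-sided p-values, keyed by treatment column index.

    The z statistic for treatments a, b over n blocks and k treatments is
    ``(Rbar_a - Rbar_b) / sqrt(k (k + 1) / (6 n))`` where Rbar are mean
    within-block ranks.
    """
    x = np.asarray(block_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("block_matrix must be 2-D with >=2 blocks and >=2 treatments")
    n, k = x.shape
    ranks = sps.rankdata(x, axis=1)
    rbar = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    others = [j for j in range(k) if j != reference]
    z = np.array([(rbar[j] - rbar[reference]) / se for j in others])
    p = 2.0 * sps.norm.sf(np.abs(z))
    if correction == "holm":
        p_adj = holm_adjust(p)
    elif correction == "none":
        p_adj = p
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return {
        "reference": reference,
        "comparisons": others,
        "z": z,
        "p_raw": p,
        "p_adjusted": p_adj,
        "mean_ranks": rbar,
    }
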