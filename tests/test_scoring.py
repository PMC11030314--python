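"""Module projection scoring, dotplot statistics, quartile co-expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy import stats as sps

import microtraj as mt
from microtraj.containers import ExpressionMatrix


def em_from(x, cell_ids=None):
    x = np.asarray(x, float)
    return ExpressionMatrix(
        values=sparse.csr_matrix(x),
        cell_ids=cell_ids or [f"c{i}" for i in range(x.shape[0])],
        gene_ids=[f"g{j}" for j in range(x.shape[1])],
    )


# ---------------------------------------------------------------------------
# log2 fold change
# ---------------------------------------------------------------------------

def test_identical_groups_give_zero_log2fc():
    rng = np.random.default_rng(0)
    x = np.vstack([rng.gamma(2, 1, size=(5, 4))] * 2)
    em = em_from(x)
    lfc, dropped = mt.module_log2fc(
        em, ["g0", "g1"], [f"c{i}" for i in range(5)],
        [f"c{i}" for i in range(5, 10)],
    )
    assert np.allclose(lfc, 0.0)
    assert dropped == 0


def test_doubled_mean_approaches_log2fc_one_as_epsilon_vanishes():
    x = np.zeros((4, 1))
    x[:2, 0] = 4.0
    x[2:, 0] = 2.0
    em = em_from(x)
    lfc, _ = mt.module_log2fc(em, ["g0"], ["c0", "c1"], ["c2", "c3"],
                              epsilon=1e-12)
    assert lfc.iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_log2fc_matches_direct_formula():
    rng = np.random.default_rng(1)
    x = rng.gamma(2, 1, size=(20, 6))
    em = em_from(x)
    a = [f"c{i}" for i in range(10)]
    b = [f"c{i}" for i in range(10, 20)]
    eps = 0.01
    lfc, _ = mt.module_log2fc(em, [f"g{j}" for j in range(6)], a, b, epsilon=eps)
    expected = np.log2((x[:10].mean(0) + eps) / (x[10:].mean(0) + eps))
    assert np.allclose(lfc.values, expected)


def test_log2fc_antisymmetry_under_group_swap():
    rng = np.random.default_rng(2)
    x = rng.gamma(2, 1, size=(16, 5))
    em = em_from(x)
    a = [f"c{i}" for i in range(8)]
    b = [f"c{i}" for i in range(8, 16)]
    genes = [f"g{j}" for j in range(5)]
    fwd, _ = mt.module_log2fc(em, genes, a, b)
    rev, _ = mt.module_log2fc(em, genes, b, a)
    assert np.allclose(fwd.values, -rev.values)


def test_genes_zero_in_both_groups_are_dropped_and_counted():
    x = np.ones((6, 3))
    x[:, 2] = 0.0
    em = em_from(x)
    lfc, dropped = mt.module_log2fc(
        em, ["g0", "g1", "g2"],
        ["c0", "c1", "c2"], ["c3", "c4", "c5"],
    )
    assert dropped == 1
    assert "g2" not in lfc.index


# ---------------------------------------------------------------------------
# one-sample t-test in log2 space
# ---------------------------------------------------------------------------

def test_all_zero_vector_is_degenerate_null():
    shift = mt.module_shift_test(np.zeros(5))
    assert shift.t_statistic == 0.0
    assert shift.p_value == 1.0
    assert shift.degenerate


def test_worked_example_matches_textbook_t():
    # values (0.5, 1.0, 1.5, 2.0): mean 1.25, sd sqrt(5/12), n=4
    values = np.array([0.5, 1.0, 1.5, 2.0])
    shift = mt.module_shift_test(values)
    sd = values.std(ddof=1)
    expected_t = values.mean() / (sd / 2.0)
    expected_p = 2 * sps.t.sf(expected_t, df=3)
    assert shift.t_statistic == pytest.approx(expected_t)
    assert shift.t_statistic == pytest.approx(3.873, abs=1e-3)
    assert shift.p_value == pytest.approx(expected_p)
    assert shift.p_value == pytest.approx(0.0305, abs=1e-3)


def test_t_invariant_under_positive_scaling():
    rng = np.random.default_rng(3)
    v = rng.normal(0.3, 1.0, 20)
    a = mt.module_shift_test(v)
    b = mt.module_shift_test(v * 37.5)
    assert a.t_statistic == pytest.approx(b.t_statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_power_for_planted_shift():
    """delta = 0.5 with gene sd 0.2 over 30 genes: reject H0 in >=95% of runs."""
    rng = np.random.default_rng(4)
    rejections = sum(
        mt.module_shift_test(rng.normal(0.5, 0.2, 30)).p_value < 0.05
        for _ in range(200)
    )
    assert rejections >= 190


def test_too_few_values_raise():
    with pytest.raises(ValueError):
        mt.module_shift_test(np.array([0.2]))


# ---------------------------------------------------------------------------
# dotplot statistics
# ---------------------------------------------------------------------------

def test_silent_gene_has_zero_pct_and_mean():
    x = np.ones((8, 2))
    x[:, 1] = 0.0
    em = em_from(x)
    stats = mt.dotplot_stats(em, ["g0", "g1"],
                             {"grp": [f"c{i}" for i in range(8)]})
    row = stats.table.loc[("g1", "grp")]
    assert row["pct_expressing"] == 0.0
    assert row["avg_expression"] == 0.0


def test_ubiquitous_gene_has_pct_100():
    rng = np.random.default_rng(5)
    x = rng.uniform(0.5, 2.0, size=(10, 1))
    em = em_from(x)
    stats = mt.dotplot_stats(em, ["g0"], {"all": [f"c{i}" for i in range(10)]})
    assert stats.table.loc[("g0", "all"), "pct_expressing"] == 100.0


def test_dotplot_matches_per_group_loop():
    rng = np.random.default_rng(6)
    x = rng.gamma(1, 1, size=(30, 4))
    x[x < 0.7] = 0
    em = em_from(x)
    groups = {"a": [f"c{i}" for i in range(15)],
              "b": [f"c{i}" for i in range(15, 30)]}
    stats = mt.dotplot_stats(em, [f"g{j}" for j in range(4)], groups)
    for label, cells in groups.items():
        idx = [int(c[1:]) for c in cells]
        for j in range(4):
            col = x[idx, j]
            row = stats.table.loc[(f"g{j}", label)]
            assert row["pct_expressing"] == pytest.approx(100 * (col > 0).mean())
            assert row["avg_expression"] == pytest.approx(col.mean())


def test_dotplot_pct_invariant_to_scale_factor(aging_sim):
    cm, _ = aging_sim
    sub = cm.subset_cells(np.arange(40))
    groups = {"all": sub.cell_ids}
    genes = sub.gene_ids[:5]
    p1 = mt.dotplot_stats(mt.lognormalize(sub, 1e4), genes, groups)
    p2 = mt.dotplot_stats(mt.lognormalize(sub, 1e2), genes, groups)
    assert np.allclose(p1.table["pct_expressing"], p2.table["pct_expressing"])


def test_empty_group_is_named_in_error():
    em = em_from(np.ones((4, 2)))
    with pytest.raises(KeyError):
        mt.dotplot_stats(em, ["g0"], {"ghost": ["nope"]})


# ---------------------------------------------------------------------------
# quartile binning and co-expression
# ---------------------------------------------------------------------------

def test_eight_distinct_cells_split_into_sorted_pairs():
    x = np.arange(8, dtype=float)[:, None]
    em = em_from(x)
    q = mt.quartile_bins(em, "g0")
    assert list(q) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


def test_tied_anchor_values_still_near_equal_bins():
    em = em_from(np.ones((10, 1)))
    q = mt.quartile_bins(em, "g0")
    sizes = q.value_counts()
    assert sizes.max() - sizes.min() <= 1


def test_quartile_boundaries_match_sort_and_slice():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(37, 1))
    em = em_from(x)
    q = mt.quartile_bins(em, "g0")
    order = sorted(range(37), key=lambda i: (x[i, 0], f"c{i}"))
    chunks = np.array_split(np.asarray(order), 4)
    for qi, chunk in enumerate(chunks):
        for i in chunk:
            assert q.iloc[i] == f"Q{qi + 1}"


def _autocrine_matrix(coupled=True, seed=8, n=400):
    """Anchor gene plus targets that do or do not track it."""
    rng = np.random.default_rng(seed)
    anchor = rng.gamma(2, 1, n)
    targets = []
    for _ in range(6):
        if coupled:
            targets.append(anchor * rng.uniform(0.5, 1.5) +
                           rng.normal(0, 0.3, n))
        else:
            targets.append(rng.gamma(2, 1, n))
    x = np.column_stack([anchor] + targets).clip(0)
    return em_from(x)


def test_coupled_targets_rise_across_quartiles():
    em = _autocrine_matrix(coupled=True)
    res = mt.quartile_coexpression(em, "g0", [f"g{j}" for j in range(1, 7)])
    assert res.zscores["Q4"].mean() > res.zscores["Q1"].mean()
    assert res.friedman_p < 0.05


def test_independent_targets_give_uniform_friedman_p():
    pvals = []
    for seed in range(60):
        em = _autocrine_matrix(coupled=False, seed=100 + seed, n=120)
        res = mt.quartile_coexpression(em, "g0",
                                       [f"g{j}" for j in range(1, 7)])
        pvals.append(res.friedman_p)
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_sparsely_expressed_gene_excluded_by_pct_filter():
    rng = np.random.default_rng(9)
    n = 100
    anchor = rng.gamma(2, 1, n)
    rare = np.zeros(n)
    rare[:20] = 1.0          # expressed in exactly 20% of cells
    common = rng.gamma(2, 1, n)
    common2 = rng.gamma(2, 1, n)
    em = em_from(np.column_stack([anchor, rare, common, common2]))
    res = mt.quartile_coexpression(em, "g0", ["g1", "g2", "g3"], pct_min=25)
    assert "g1" not in res.tested_genes
    assert res.excluded["g1"] == pytest.approx(20.0)
    assert set(res.tested_genes) == {"g2", "g3"}
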