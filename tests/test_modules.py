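"""Moran's I autocorrelation screening and gene-module discovery."""

import itertools
import math

import numpy as np
import pytest
from scipy import sparse
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

import microtraj as mt
from microtraj.containers import Embedding, ExpressionMatrix
from microtraj.trajectory import Trajectory

from conftest import random_cell_graph


def brute_force_moran(x, adj):
    """Direct O(n^2) double-sum evaluation of Moran's I."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    w_total = adj.sum()
    num = sum(adj[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / w_total) * num / (z @ z)


def graph_of(adj):
    return mt.CellGraph(adjacency=sparse.csr_matrix(np.asarray(adj, float)),
                        cell_ids=[str(i) for i in range(len(adj))])


def expression_of(x):
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1:
        x = x.T
    return ExpressionMatrix(
        values=sparse.csr_matrix(x),
        cell_ids=[str(i) for i in range(x.shape[0])],
        gene_ids=[f"g{j}" for j in range(x.shape[1])],
    )


# ---------------------------------------------------------------------------
# Moran's I statistic
# ---------------------------------------------------------------------------

def test_block_indicator_on_within_block_graph_gives_one():
    a = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        for i in block:
            for j in block:
                if i != j:
                    a[i, j] = 1
    x = np.array([1, 1, 1, 0, 0, 0], float)
    assert mt.morans_i(x, graph_of(a)) == pytest.approx(1.0)


def test_alternating_chain_is_negative():
    n = 8
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    x = np.array([0, 1] * (n // 2), float)
    assert mt.morans_i(x, graph_of(a)) < 0


def test_constant_vector_raises():
    g = graph_of(np.array([[0, 1], [1, 0]], float))
    with pytest.raises(ValueError):
        mt.morans_i(np.ones(2), g)


def test_moran_equals_brute_force_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(4, 13))
        g = random_cell_graph(rng, n)
        x = rng.normal(size=n)
        direct = brute_force_moran(x, g.adjacency.toarray())
        assert mt.morans_i(x, g) == pytest.approx(direct, abs=1e-12)


def test_moran_invariant_under_joint_permutation():
    rng = np.random.default_rng(1)
    g = random_cell_graph(rng, 10)
    x = rng.normal(size=10)
    perm = rng.permutation(10)
    a = g.adjacency.toarray()
    g_perm = graph_of(a[np.ix_(perm, perm)])
    assert mt.morans_i(x[perm], g_perm) == pytest.approx(mt.morans_i(x, g))


# ---------------------------------------------------------------------------
# significance testing
# ---------------------------------------------------------------------------

def test_exhaustive_p_matches_enumeration_oracle():
    rng = np.random.default_rng(2)
    g = random_cell_graph(rng, 6)
    x = rng.normal(size=6)
    res = mt.morans_test(expression_of(x), g, method="exhaustive")
    adj = g.adjacency.toarray()
    i_obs = brute_force_moran(x, adj)
    count = sum(
        brute_force_moran(x[list(p)], adj) >= i_obs - 1e-12
        for p in itertools.permutations(range(6))
    )
    expected = count / math.factorial(6)
    assert res.table["p"].iloc[0] == pytest.approx(expected, abs=1e-9)


def test_expected_i_is_exact():
    rng = np.random.default_rng(3)
    g = random_cell_graph(rng, 9)
    res = mt.morans_test(expression_of(rng.normal(size=(9, 3))), g,
                         method="analytic")
    assert np.allclose(res.table["expected_I"], -1.0 / 8)


def test_null_permutation_pvalues_uniform():
    rng = np.random.default_rng(3)
    emb = Embedding(coords=rng.normal(size=(200, 4)),
                    cell_ids=[str(i) for i in range(200)])
    g = mt.knn_graph(emb, 8)
    x = rng.normal(size=(200, 200))
    em = expression_of(x)
    res = mt.morans_test(em, g, method="permutation", n_perm=200, seed=3)
    ks = sps.kstest(res.table["p"], "uniform")
    assert ks.pvalue > 0.01


def test_constant_gene_flagged_with_p_one():
    rng = np.random.default_rng(4)
    g = random_cell_graph(rng, 12)
    x = rng.normal(size=(12, 2))
    x[:, 1] = 3.0
    res = mt.morans_test(expression_of(x), g, method="analytic")
    assert bool(res.table["constant"].iloc[1])
    assert res.table["p"].iloc[1] == 1.0


def test_planted_gene_significant_background_not(aging_chain):
    res = aging_chain["autocorr"]
    truth = aging_chain["truth"]
    q = res.table["q"]
    planted = [g for g in q.index if truth.module_membership[g] != "background"]
    background = [g for g in q.index if truth.module_membership[g] == "background"]
    # every planted module gene passes the q < 0.005 screen
    assert (q.loc[planted] < 0.005).all()
    # background genes overwhelmingly do not
    assert (q.loc[background] > 0.005).mean() > 0.95


def test_qvalues_monotone_in_p(aging_chain):
    t = aging_chain["autocorr"].table.sort_values("p")
    assert np.all(np.diff(t["q"].values) >= -1e-15)


# ---------------------------------------------------------------------------
# module discovery
# ---------------------------------------------------------------------------

def _toy_traj(n):
    t = np.linspace(0, 1, n)
    return Trajectory(
        curve=np.column_stack([t, np.zeros(n)]),
        pseudotime=t,
        cell_ids=[str(i) for i in range(n)],
    )


def test_anticorrelated_gene_groups_split_perfectly():
    rng = np.random.default_rng(5)
    n = 200
    t = np.linspace(0, 1, n)
    up = np.outer(t, np.ones(6)) + rng.normal(0, 0.01, (n, 6))
    down = np.outer(1 - t, np.ones(6)) + rng.normal(0, 0.01, (n, 6))
    em = expression_of(np.column_stack([up, down]))
    gm = mt.discover_modules(em, _toy_traj(n),
                             [f"g{j}" for j in range(12)], k_gene=4)
    labels = [gm.assignment[f"g{j}"] for j in range(12)]
    truth = [0] * 6 + [1] * 6
    assert adjusted_rand_score(truth, labels) == 1.0


def test_vanishing_resolution_yields_single_module():
    rng = np.random.default_rng(6)
    n = 100
    x = rng.normal(size=(n, 10)) + np.linspace(0, 1, n)[:, None]
    em = expression_of(x)
    gm = mt.discover_modules(em, _toy_traj(n),
                             [f"g{j}" for j in range(10)], resolution=1e-6)
    assert gm.n_modules == 1
    assert gm.flags.get("single_module")


def test_default_simulation_module_recovery(aging_chain):
    gm = aging_chain["modules"]
    truth = aging_chain["truth"]
    pred = [gm.assignment[g] for g in gm.assignment]
    true = [truth.module_membership[g] for g in gm.assignment]
    assert adjusted_rand_score(true, pred) >= 0.8


def test_recovery_declines_gracefully_with_dispersion():
    """Module recovery (ARI) must not improve as NB noise grows."""
    from microtraj.simulate import SimConfig

    aris = []
    for disp in (10.0, 1.0, 0.25):   # variance = mu + mu^2/disp: rising noise
        seed_aris = []
        for seed in (0, 1):
            cfg = SimConfig(seed=seed, nb_dispersion=disp, n_cells_per_age=250)
            cm, truth = mt.simulate_aging_dataset(cfg)
            em = mt.lognormalize(cm)
            hvg = mt.select_hvg(cm, 110)
            scaled, _ = mt.scale_center(em, hvg)
            emb = mt.pca(scaled, 6, cell_ids=cm.cell_ids)
            age = cm.cell_meta["age"].astype(int).values
            traj = mt.fit_principal_curve(emb, anchor=age)
            planted = [g for g in cm.gene_ids if g.startswith("mod")]
            gm = mt.discover_modules(em, traj, planted)
            pred = [gm.assignment[g] for g in planted]
            true = [truth.module_membership[g] for g in planted]
            seed_aris.append(adjusted_rand_score(true, pred))
        aris.append(np.mean(seed_aris))
    assert aris[0] >= aris[1] - 0.1
    assert aris[1] >= aris[2] - 0.1
    assert aris[0] >= 0.8


# ---------------------------------------------------------------------------
# top genes
# ---------------------------------------------------------------------------

def test_small_module_returns_all_genes():
    gm = mt.GeneModules(
        assignment={"a": 1, "b": 1, "c": 1},
        resolution=1.0, seed=0,
        qvalues={"a": 0.01, "b": 0.001, "c": 0.005},
    )
    assert mt.top_module_genes(gm, k=10) == {1: ["b", "c", "a"]}


def test_equal_qvalues_tie_break_alphabetically():
    gm = mt.GeneModules(
        assignment={"z": 1, "a": 1, "m": 1},
        resolution=1.0, seed=0,
        qvalues={"z": 0.5, "a": 0.5, "m": 0.5},
    )
    assert mt.top_module_genes(gm, k=2) == {1: ["a", "m"]}


def test_top_genes_match_brute_force_sort():
    rng = np.random.default_rng(7)
    genes = [f"g{j}" for j in range(30)]
    q = {g: float(rng.random()) for g in genes}
    assignment = {g: int(rng.integers(1, 4)) for g in genes}
    gm = mt.GeneModules(assignment=assignment, resolution=1.0, seed=0, qvalues=q)
    top = mt.top_module_genes(gm, k=5)
    for m, lst in top.items():
        members = [g for g in genes if assignment[g] == m]
        expected = sorted(members, key=lambda g: (q[g], g))[:5]
        assert lst == expected
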