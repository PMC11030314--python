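import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import microtraj as mt
from microtraj.simulate import SimConfig


@pytest.fixture(scope="session")
def aging_sim():
    """Default synthetic aging dataset plus ground truth (seed 0)."""
    cm, truth = mt.simulate_aging_dataset(SimConfig(seed=0))
    return cm, truth


@pytest.fixture(scope="session")
def aging_chain(aging_sim):
    """Full analysis chain on the default simulation, computed once.

    Returns a dict with the intermediate objects every downstream test
    needs: normalized expression, embedding, cell graph, oriented and
    branch-split trajectory, autocorrelation table, gene modules.
    """
    cm, truth = aging_sim
    em = mt.lognormalize(cm)
    hvg = mt.select_hvg(cm, 110)
    scaled, order = mt.scale_center(em, hvg)
    emb = mt.pca(scaled, 6, cell_ids=cm.cell_ids)
    age = pd.to_numeric(cm.cell_meta["age"]).values
    traj = mt.fit_principal_curve(emb, anchor=age)
    roots = [c for c, a in zip(cm.cell_ids, age) if a == 6]
    traj = mt.orient_by_root(traj, roots)
    traj = mt.split_terminal_branches(traj, emb, t_split=0.6, k_branches=2, seed=0)
    graph = mt.knn_graph(emb, 15)
    autocorr = mt.morans_test(em, graph, method="analytic")
    sig = autocorr.significant()
    gm = mt.discover_modules(em, traj, autocorr.table.loc[sig, "q"], seed=0)
    return {
        "cm": cm,
        "truth": aging_sim[1],
        "em": em,
        "hvg": hvg,
        "emb": emb,
        "graph": graph,
        "traj": traj,
        "autocorr": autocorr,
        "modules": gm,
    }


@pytest.fixture()
def small_expression():
    """Tiny dense expression matrix with known values for formula tests."""
    rng = np.random.default_rng(42)
    x = rng.gamma(2.0, 1.0, size=(30, 8))
    x[x < 0.5] = 0.0
    return mt.ExpressionMatrix(
        values=sparse.csr_matrix(x),
        cell_ids=[f"c{i}" for i in range(30)],
        gene_ids=[f"g{j}" for j in range(8)],
    )


def random_cell_graph(rng, n, p=0.4):
    """Random symmetric binary graph with no self-loops, >=1 edge."""
    while True:
        a = rng.random((n, n)) < p
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() > 0:
            break
    return mt.CellGraph(adjacency=sparse.csr_matrix(a.astype(float)),
                        cell_ids=[str(i) for i in range(n)])
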