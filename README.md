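# microtraj

Trajectory analysis of microglial aging from single-cell RNA-seq, as a
tested, reusable pipeline — plus the formula-defined microscopy
quantification that accompanies such studies.

## The problem

Microglia, the brain's resident macrophages, do not jump from a
homeostatic to an inflamed state during aging: in the hippocampus they
pass through intermediate states — a transient stress response (marked by
*Tgfb1*), a surge of ribosomal/translational capacity — before terminal
inflammatory activation, with a semi-distinct myeloid-activation branch
proceeding independently. Resolving that progression from cross-sectional
single-cell snapshots (mice sampled at 6, 12, 18 and 24 months) requires:

1. **Pseudotime inference** — ordering cells along a latent aging
   trajectory from expression similarity, anchored at the youngest cells;
2. **Graph autocorrelation screening** — finding genes expressed focally
   along the trajectory with Moran's I on a cell–cell kNN graph,

   `I = (n/W) · Σᵢⱼ wᵢⱼ (xᵢ−x̄)(xⱼ−x̄) / Σᵢ (xᵢ−x̄)²`,

   keeping genes at Benjamini–Hochberg q < 0.005;
3. **Module discovery** — grouping the significant genes into coregulated
   modules by Louvain community detection on a correlation graph of their
   pseudotime profiles;
4. **Metagene projection** — scoring external contrasts (heterochronic
   parabiosis, disease models, *Tgfb1* knockouts, in-vitro treatments)
   against each module via the per-gene log2 fold change of group means
   and a one-sample t-test against 0 in log2 space.

Every step is implemented here over ordinary containers
(scipy.sparse + pandas), with the supporting statistics (Wilcoxon
rank-sum DE, χ² gene-set overlap, quartile-binned co-expression with
Friedman/Dunn tests, dotplot summaries) and the image operators used for
the histology (CD68-puncta activation scoring with the 100-px particle
floor, mean channel intensity in cell ROIs, puncta-normalized RNAscope
counts, the 0.312 µm/px scale).

Because the real datasets are external, the package ships a
**synthetic-data generator** that plants the assumed statistical
structure — four age groups coupled to a latent pseudotime, a declining
homeostatic module, a transient stress bump, late translation/inflammation
ramps, an independent myeloid branch, negative-binomial counts with
variable library sizes — together with the ground truth, so the whole
pipeline is testable end to end by recovery.

## Worked example

```python
import microtraj as mt
from microtraj.simulate import SimConfig
from scipy.stats import spearmanr

cm, truth = mt.simulate_aging_dataset(SimConfig(seed=1))

em = mt.lognormalize(cm)                      # ln(1 + c/total * 1e4)
hvg = mt.select_hvg(cm, 110)                  # vst-style ranking
scaled, _ = mt.scale_center(em, hvg)
emb = mt.pca(scaled, 6, cell_ids=cm.cell_ids)

age = cm.cell_meta["age"].astype(int).values
traj = mt.fit_principal_curve(emb, anchor=age)
traj = mt.orient_by_root(traj, [c for c, a in zip(cm.cell_ids, age) if a == 6])
traj = mt.split_terminal_branches(traj, emb, t_split=0.6, k_branches=2, seed=0)

graph = mt.knn_graph(emb, 15)
res = mt.morans_test(em, graph, method="analytic")
sig = res.significant(0.005)
gm = mt.discover_modules(em, traj, res.table.loc[sig, "q"], seed=0)
```

Output of the full script (`spearmanr` against the generator's truth):

```
simulated 2000 cells x 1110 genes (100 module genes)
pseudotime vs latent age signal: Spearman rho = 0.982
trajectory-dependent genes at q < 0.005: 111
coregulated modules: 5 (ARI vs planted truth = 0.86)
  module 1: mod1_g001, mod1_g002, mod1_g003
  module 2: bg_g748, mod5_g001, mod5_g004
  module 3: mod2_g001, mod2_g002, mod2_g003
  module 4: mod3_g001, mod3_g002, mod3_g003
  module 5: mod4_g001, mod4_g002, mod4_g003
```

The pseudotime tracks the latent aging signal (ρ = 0.98); the screen
recovers all 100 planted module genes (plus a handful of background genes
that pick up real autocorrelation through library-size composition); the
five discovered communities correspond one-to-one to the five planted
modules (discovered ids are ordered by size, so e.g. discovered module 4
is the planted translation module).

The same chain runs from one YAML config:

```bash
microtraj run --config run.yaml        # simulate → qc → cluster → trajectory → modules → project
```

writing per-stage TSV artifacts and a JSON manifest under the configured
output directory.

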