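"""End-to-end pipeline orchestration from a single configuration.

A run proceeds simulate -> qc -> cluster -> trajectory -> modules ->
project, each stage writing its artifacts under ``<outdir>/<stage>/`` and
contributing to a JSON manifest (parameter echo, per-stage seeds, row
counts).  One global seed fans out to per-stage seeds by stable hashing of
stage names, so stages are independently reproducible and never share a
random stream.

Analysis-parameter defaults are the study values (QC genes > 1000,
counts > 10000, mito < 5%; cluster resolution 0.4; Moran q < 0.005); runs
on the bundled synthetic data override the QC thresholds to that
generator's count scale via ``synthetic_run_config``.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import preprocess, trajectory as traj_mod
from .containers import CountMatrix
from .graph import knn_graph, louvain_partition
from .io import write_counts
from .modules import Q_CUTOFF, discover_modules, morans_test, top_module_genes
from .scoring import module_log2fc, module_shift_test
from .simulate import SimConfig, simulate_aging_dataset, simulate_condition_shift

__all__ = ["RunConfig", "validate_config", "run_pipeline",
           "synthetic_run_config", "stage_seed"]

STAGES = ("simulate", "qc", "cluster", "trajectory", "modules", "project")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    outdir: str = "run_out"
    seed: int = 0
    stages: tuple = STAGES
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: {
        "min_genes": 1000, "min_counts": 10000, "max_mito_pct": 5.0,
    })
    cluster: dict = field(default_factory=lambda: {
        "scale_factor": 1e4, "n_hvg": 2500, "n_pcs": 25, "k": 15,
        "resolution": 0.4,
    })
    trajectory: dict = field(default_factory=lambda: {
        "n_segments": 50, "max_iter": 100, "tol": 1e-4,
        "t_split": 0.6, "k_branches": 2, "root_age": None,
    })
    modules: dict = field(default_factory=lambda: {
        "method": "analytic", "n_perm": 999, "q_cutoff": Q_CUTOFF,
        "resolution": 1.0, "k_gene": 10, "n_bins": 20, "top_k": 10,
    })
    project: dict = field(default_factory=lambda: {
        "delta": 0.3, "epsilon": 0.01,
    })

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        errors = validate_config(raw)
        if errors:
            raise ValueError("invalid config:\n" + "\n".join(errors))
        cfg = cls()
        for key, value in raw.items():
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, tuple(value) if key == "stages" else value)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def validate_config(raw: dict) -> list[str]:
    """Report unknown keys and out-of-range values; empty list = valid."""
    errors = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key: {key}")
    if "stages" in raw:
        for s in raw["stages"]:
            if s not in STAGES:
                errors.append(f"unknown stage: {s}")
    qc = raw.get("qc", {})
    for key in ("min_genes", "min_counts"):
        if key in qc and qc[key] < 0:
            errors.append(f"qc.{key} must be nonnegative")
    cluster = raw.get("cluster", {})
    for key in ("n_hvg", "n_pcs", "k"):
        if key in cluster and cluster[key] <= 0:
            errors.append(f"cluster.{key} must be positive")
    modules = raw.get("modules", {})
    if "q_cutoff" in modules and not (0 < modules["q_cutoff"] <= 1):
        errors.append("modules.q_cutoff must be in (0, 1]")
    project = raw.get("project", {})
    if "delta" in project and abs(project["delta"]) > 1:
        errors.append("project.delta must satisfy |delta| <= 1")
    if "input_path" in raw.get("simulate", {}):
        path = raw["simulate"]["input_path"]
        if not os.path.exists(path):
            errors.append(f"simulate.input_path does not exist: {path}")
    return errors


def synthetic_run_config(outdir: str, seed: int = 0, **overrides) -> RunConfig:
    """RunConfig scaled to the synthetic generator's count depth.

    The generator emits a few hundred counts per cell over ~200 genes, so
    the droplet-scale QC floors are replaced by permissive synthetic-scale
    ones; everything else keeps the analysis defaults.
    """
    cfg = RunConfig(outdir=outdir, seed=seed)
    cfg.qc.update({"min_genes": 20, "min_counts": 50, "max_mito_pct": 100.0})
    cfg.cluster.update({"n_hvg": 110, "n_pcs": 6})
    for key, value in overrides.items():
        current = getattr(cfg, key)
        if isinstance(current, dict):
            current.update(value)
        else:
            setattr(cfg, key, value)
    return cfg


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the manifest.

    A stage failure halts the run with the failing stage named; artifacts
    of completed stages are retained on disk.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": [],
        "parameters": cfg.to_dict(),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in cfg.stages},
    }
    state: dict = {}
    for stage in cfg.stages:
        stage_dir = os.path.join(cfg.outdir, stage)
        os.makedirs(stage_dir, exist_ok=True)
        try:
            info = _STAGE_FUNCS[stage](cfg, state, stage_dir)
        except Exception as exc:  # halt with the failing stage named
            manifest["failed_stage"] = stage
            _write_manifest(cfg, manifest)
            raise StageFailure(stage, exc) from exc
        manifest["stages"].append({"name": stage, **info})
    _write_manifest(cfg, manifest)
    return manifest


def _write_manifest(cfg: RunConfig, manifest: dict) -> None:
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, state: dict, outdir: str) -> dict:
    params = dict(cfg.simulate)
    params.setdefault("seed", stage_seed(cfg.seed, "simulate"))
    sim_cfg = SimConfig(**params)
    cm, truth = simulate_aging_dataset(sim_cfg)
    state["counts"] = cm
    state["truth"] = truth
    state["sim_config"] = sim_cfg
    write_counts(cm, os.path.join(outdir, "counts"))
    truth.cells_frame(cm.cell_ids).to_csv(os.path.join(outdir, "truth_cells.tsv"), sep="\t")
    pd.Series(truth.module_membership, name="module").to_csv(
        os.path.join(outdir, "truth_genes.tsv"), sep="\t"
    )
    with open(os.path.join(outdir, "sim_config.yaml"), "w") as fh:
        yaml.safe_dump(sim_cfg.to_dict(), fh)
    return {"n_cells": cm.n_cells, "n_genes": cm.n_genes}


def _stage_qc(cfg: RunConfig, state: dict, outdir: str) -> dict:
    cm: CountMatrix = state["counts"]
    filtered = preprocess.qc_filter(cm, **cfg.qc)
    state["counts"] = filtered
    if "truth" in state:
        keep = [c in set(filtered.cell_ids) for c in cm.cell_ids]
        tr = state["truth"]
        import numpy as _np
        mask = _np.asarray(keep)
        tr = dataclasses.replace(
            tr, pseudotime=tr.pseudotime[mask], age=tr.age[mask],
            branch=tr.branch[mask],
        )
        state["truth"] = tr
    write_counts(filtered, os.path.join(outdir, "counts"))
    return {"n_cells": filtered.n_cells, "n_removed": cm.n_cells - filtered.n_cells}


def _stage_cluster(cfg: RunConfig, state: dict, outdir: str) -> dict:
    cm: CountMatrix = state["counts"]
    p = cfg.cluster
    em = preprocess.lognormalize(cm, scale_factor=p["scale_factor"])
    hvg = preprocess.select_hvg(cm, n_top=min(p["n_hvg"], cm.n_genes))
    scaled, order = preprocess.scale_center(em, hvg)
    emb = preprocess.pca(scaled, n_components=min(p["n_pcs"], len(order), cm.n_cells),
                         cell_ids=cm.cell_ids)
    graph = knn_graph(emb, k=p["k"])
    part = louvain_partition(graph, resolution=p["resolution"],
                             seed=stage_seed(cfg.seed, "cluster"))
    state.update({"expression": em, "embedding": emb, "graph": graph,
                  "partition": part, "hvg": hvg})
    pd.DataFrame({"cell_id": cm.cell_ids, "community": part.labels}).to_csv(
        os.path.join(outdir, "partition.tsv"), sep="\t", index=False
    )
    np.savetxt(os.path.join(outdir, "graph_edges.tsv"), graph.edge_list(),
               fmt="%d\t%d\t%g", header="i\tj\tw", comments="")
    return {"n_communities": part.n_communities,
            "modularity": part.modularity}


def _stage_trajectory(cfg: RunConfig, state: dict, outdir: str) -> dict:
    p = cfg.trajectory
    emb = state["embedding"]
    cm: CountMatrix = state["counts"]
    anchor = None
    if "age" in cm.cell_meta.columns:
        anchor = pd.to_numeric(cm.cell_meta["age"]).values
    traj = traj_mod.fit_principal_curve(
        emb, n_segments=p["n_segments"], max_iter=p["max_iter"], tol=p["tol"],
        seed=stage_seed(cfg.seed, "trajectory"), anchor=anchor,
    )
    root_age = p.get("root_age")
    if root_age is None and "age" in cm.cell_meta.columns:
        root_age = pd.to_numeric(cm.cell_meta["age"]).min()
    if root_age is not None:
        roots = [c for c, a in zip(cm.cell_ids, pd.to_numeric(cm.cell_meta["age"]))
                 if a == root_age]
        traj = traj_mod.orient_by_root(traj, roots)
    traj = traj_mod.split_terminal_branches(
        traj, emb, t_split=p["t_split"], k_branches=p["k_branches"],
        seed=stage_seed(cfg.seed, "trajectory"),
    )
    state["trajectory"] = traj
    pd.DataFrame({
        "cell_id": traj.cell_ids,
        "pseudotime": traj.pseudotime,
        "branch": traj.branch_labels,
    }).to_csv(os.path.join(outdir, "pseudotime.tsv"), sep="\t", index=False)
    np.savetxt(os.path.join(outdir, "curve.csv"), traj.curve, delimiter=",")
    return {"converged": traj.converged, "n_iter": traj.n_iter,
            "branch_sizes": traj.branch_info.get("sizes", {})}


def _stage_modules(cfg: RunConfig, state: dict, outdir: str) -> dict:
    p = cfg.modules
    em = state["expression"]
    graph = state["graph"]
    traj = state["trajectory"]
    res = morans_test(em, graph, method=p["method"], n_perm=p["n_perm"],
                      seed=stage_seed(cfg.seed, "modules"))
    res.table.to_csv(os.path.join(outdir, "autocorrelation.tsv"), sep="\t")
    sig = res.significant(p["q_cutoff"])
    gm = discover_modules(
        em, traj, res.table.loc[sig, "q"], resolution=p["resolution"],
        k_gene=p["k_gene"], seed=stage_seed(cfg.seed, "modules"),
        n_bins=p["n_bins"],
    )
    state["autocorr"] = res
    state["modules"] = gm
    pd.Series(gm.assignment, name="module").to_csv(
        os.path.join(outdir, "module_assignment.tsv"), sep="\t"
    )
    top = top_module_genes(gm, k=p["top_k"])
    for m, genes in top.items():
        with open(os.path.join(outdir, f"module_{m}_top_genes.txt"), "w") as fh:
            fh.write("\n".join(genes) + "\n")
    return {"n_significant": len(sig), "n_modules": gm.n_modules}


def _stage_project(cfg: RunConfig, state: dict, outdir: str) -> dict:
    p = cfg.project
    truth = state.get("truth")
    sim_cfg: SimConfig = state.get("sim_config")
    if truth is None or sim_cfg is None:
        raise RuntimeError("project stage requires a simulated base dataset")
    gm = state["modules"]
    treated_cm, _ = simulate_condition_shift(truth, sim_cfg, delta=p["delta"])
    base_cm: CountMatrix = state["counts"]
    from scipy import sparse as _sp
    combined = CountMatrix(
        counts=_sp.vstack([base_cm.counts, treated_cm.counts]).tocsr(),
        cell_ids=base_cm.cell_ids + treated_cm.cell_ids,
        gene_ids=base_cm.gene_ids,
        cell_meta=pd.concat([base_cm.cell_meta, treated_cm.cell_meta]),
    )
    em = preprocess.lognormalize(combined,
                                 scale_factor=cfg.cluster["scale_factor"])
    rows = []
    for m in gm.module_ids:
        genes = gm.genes_of(m)
        lfc, dropped = module_log2fc(
            em, genes, treated_cm.cell_ids, base_cm.cell_ids,
            epsilon=p["epsilon"],
        )
        shift = module_shift_test(lfc, module_id=m, epsilon=p["epsilon"])
        rows.append({
            "module": m, "mean_log2fc": shift.mean_log2fc,
            "t": shift.t_statistic, "p": shift.p_value,
            "n_genes": shift.n_genes, "n_dropped": dropped,
        })
    table = pd.DataFrame(rows).set_index("module")
    table.to_csv(os.path.join(outdir, "module_shifts.tsv"), sep="\t")
    state["module_shifts"] = table
    return {"n_modules": len(rows), "delta": p["delta"]}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "trajectory": _stage_trajectory,
    "modules": _stage_modules,
    "project": _stage_project,
}
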