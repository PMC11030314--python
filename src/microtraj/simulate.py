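"""Synthetic data with planted structure for the aging-trajectory analysis.

The generator emulates a cross-sectional single-cell study of hippocampal
microglia sampled at four ages (6, 12, 18, 24 months).  Each cell carries a
latent aging pseudotime t in [0, 1]; age groups map to overlapping Gaussian
windows on t so that ages mix along the trajectory.  Five gene modules are
planted on top of a flat background:

1. homeostatic      — linear decline, a * (1 - t)
2. stress response  — transient Gaussian bump centered mid-trajectory
3. translation      — late logistic ramp on the inflammatory branch
4. inflammation     — later, steeper logistic ramp on the inflammatory branch
5. myeloid          — constant elevation restricted to the myeloid branch

Cells past a pseudotime threshold split into an inflammatory branch (which
expresses the translation and inflammation ramps) or an independent myeloid
branch.  Counts are negative-binomial around library-size-scaled means with
log-normal library sizes.  Every dataset is paired with a SimTruth object
recording the latent variables, so recovery tests can score the pipeline
against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "ImageFixture",
    "GenerationError",
    "MODULE_NAMES",
    "simulate_aging_dataset",
    "simulate_condition_shift",
    "simulate_image_fixture",
]

MODULE_NAMES = ("module1", "module2", "module3", "module4", "module5")


class GenerationError(RuntimeError):
    """Raised when a fixture specification cannot be rendered."""


def _default_age_coupling() -> dict:
    # Overlapping windows so that adjacent ages mix along t, while the
    # means increase monotonically with age.
    return {6: (0.15, 0.13), 12: (0.40, 0.13), 18: (0.62, 0.13), 24: (0.80, 0.13)}


def _default_profile_params() -> dict:
    return {
        "decline_slope": 5.0,       # module 1: 1 + a*(1-t)
        "bump_center": 0.45,        # module 2: 1 + h*exp(-(t-c)^2 / 2w^2)
        "bump_width": 0.12,
        "bump_height": 3.0,
        "translation_midpoint": 0.55,   # module 3 logistic ramp
        "translation_steepness": 8.0,
        "translation_height": 4.0,
        "inflammation_midpoint": 0.75,  # module 4 logistic ramp
        "inflammation_steepness": 12.0,
        "inflammation_height": 5.0,
        "myeloid_height": 1.8,          # module 5 branch elevation
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic aging dataset.

    Defaults give ~2,000 cells (500 per age), 20 genes per module over a
    1,000-gene background with log-normal per-gene baselines, moderate
    negative-binomial noise (dispersion 10) and +/-35% log-normal
    library-size variation — strong enough planted structure that recovery
    is expected, weak enough that it is not forced.  The wide background
    anchors the mean-variance trend that feature selection fits, as in
    real transcriptomes where trajectory genes are a small minority.
    """

    n_cells_per_age: int = 500
    ages: tuple = (6, 12, 18, 24)
    n_genes_per_module: tuple = (20, 20, 20, 20, 20)
    n_background_genes: int = 1000
    n_mito_genes: int = 10
    pseudotime_age_coupling: dict = field(default_factory=_default_age_coupling)
    profile_params: dict = field(default_factory=_default_profile_params)
    branch_threshold: float = 0.55
    branch_prob: float = 0.2
    nb_dispersion: float = 10.0
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.3
    base_expression: float = 4.0
    gene_baseline_logsd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_age <= 0:
            raise ValueError("n_cells_per_age must be positive")
        if len(self.n_genes_per_module) != 5:
            raise ValueError("n_genes_per_module must have 5 entries")
        if any(n <= 0 for n in self.n_genes_per_module):
            raise ValueError("n_genes_per_module entries must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be nonnegative")
        if self.n_mito_genes < 0:
            raise ValueError("n_mito_genes must be nonnegative")
        missing = [a for a in self.ages if a not in self.pseudotime_age_coupling]
        if missing:
            raise ValueError(f"pseudotime_age_coupling missing ages {missing}")
        means = [self.pseudotime_age_coupling[a][0] for a in self.ages]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("pseudotime_age_coupling means must be non-decreasing with age")
        if any(self.pseudotime_age_coupling[a][1] <= 0 for a in self.ages):
            raise ValueError("pseudotime_age_coupling sds must be positive")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")
        if not (0.0 < self.branch_threshold < 1.0):
            raise ValueError("branch_threshold must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.libsize_logsd < 0:
            raise ValueError("libsize_logsd must be nonnegative")
        if self.base_expression <= 0:
            raise ValueError("base_expression must be positive")
        if self.gene_baseline_logsd < 0:
            raise ValueError("gene_baseline_logsd must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated matrix."""

    pseudotime: np.ndarray                 # per cell, in [0, 1]
    age: np.ndarray                        # per cell, months
    branch: np.ndarray                     # per cell: trunk | inflammatory | myeloid
    module_membership: dict                # gene id -> module name or 'background'
    delta: float = 0.0                     # applied condition shift

    def __post_init__(self):
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        self.age = np.asarray(self.age)
        self.branch = np.asarray(self.branch, dtype=object)
        n = self.pseudotime.size
        if self.age.size != n or self.branch.size != n:
            raise ValueError("truth arrays must have equal length")

    @property
    def n_cells(self) -> int:
        return self.pseudotime.size

    def cells_frame(self, cell_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pseudotime": self.pseudotime,
                "age": self.age,
                "branch": self.branch,
            },
            index=list(cell_ids),
        )

    def module_of(self, gene: str) -> str:
        return self.module_membership[gene]


# ---------------------------------------------------------------------------
# temporal mean profiles
# ---------------------------------------------------------------------------

def _profile_matrix(
    t: np.ndarray,
    branch: np.ndarray,
    modules: np.ndarray,
    params: dict,
) -> np.ndarray:
    """Relative expected expression (multiplier on base) per cell x gene.

    *modules* maps each gene to 0..4 (planted) or -1 (background / mito).
    """
    n = t.size
    g = modules.size
    non_myeloid = (branch != "myeloid").astype(float)
    myeloid = 1.0 - non_myeloid

    profiles = np.empty((5, n))
    profiles[0] = 1.0 + params["decline_slope"] * (1.0 - t)
    c, w, h = params["bump_center"], params["bump_width"], params["bump_height"]
    profiles[1] = 1.0 + h * np.exp(-((t - c) ** 2) / (2.0 * w * w))
    m, s, h3 = (
        params["translation_midpoint"],
        params["translation_steepness"],
        params["translation_height"],
    )
    profiles[2] = 1.0 + h3 * non_myeloid / (1.0 + np.exp(-s * (t - m)))
    m4, s4, h4 = (
        params["inflammation_midpoint"],
        params["inflammation_steepness"],
        params["inflammation_height"],
    )
    profiles[3] = 1.0 + h4 * non_myeloid / (1.0 + np.exp(-s4 * (t - m4)))
    profiles[4] = 1.0 + params["myeloid_height"] * myeloid

    out = np.ones((n, g))
    for j in range(g):
        if modules[j] >= 0:
            out[:, j] = profiles[modules[j]]
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean mu and variance mu + mu^2/dispersion.

    dispersion = inf gives the Poisson limit.
    """
    if math.isinf(dispersion):
        return rng.poisson(mu)
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    return rng.poisson(lam)


def _gene_ids(config: SimConfig) -> tuple[list[str], np.ndarray, dict]:
    gene_ids: list[str] = []
    modules: list[int] = []
    membership: dict = {}
    for m, n_m in enumerate(config.n_genes_per_module):
        for j in range(n_m):
            gid = f"mod{m + 1}_g{j + 1:03d}"
            gene_ids.append(gid)
            modules.append(m)
            membership[gid] = MODULE_NAMES[m]
    for j in range(config.n_background_genes):
        gid = f"bg_g{j + 1:03d}"
        gene_ids.append(gid)
        modules.append(-1)
        membership[gid] = "background"
    for j in range(config.n_mito_genes):
        gid = f"mt-sim{j + 1}"
        gene_ids.append(gid)
        modules.append(-1)
        membership[gid] = "background"
    return gene_ids, np.asarray(modules), membership


def _draw_latents(config: SimConfig, rng: np.random.Generator):
    ages = np.repeat(config.ages, config.n_cells_per_age)
    t = np.empty(ages.size)
    for a in config.ages:
        mask = ages == a
        mu, sd = config.pseudotime_age_coupling[a]
        t[mask] = rng.normal(mu, sd, size=mask.sum())
    np.clip(t, 0.0, 1.0, out=t)
    branch = np.where(t < config.branch_threshold, "trunk", "inflammatory").astype(object)
    late = t >= config.branch_threshold
    myeloid_draw = rng.random(ages.size) < config.branch_prob
    branch[late & myeloid_draw] = "myeloid"
    return t, ages, branch


def _gene_baselines(config: SimConfig, modules: np.ndarray) -> np.ndarray:
    """Per-gene baseline mean counts: log-normal spread around
    base_expression, drawn from a dedicated stream so the same config
    yields identical baselines in base and contrast datasets.

    Module and background genes draw from the same distribution, so the
    mean-variance trend is anchored by background genes across the whole
    expression range.
    """
    rng = np.random.default_rng([config.seed, 7919])
    spread = rng.normal(0.0, config.gene_baseline_logsd, size=modules.size)
    return config.base_expression * np.exp(spread)


def _emit_counts(
    config: SimConfig,
    rng: np.random.Generator,
    t: np.ndarray,
    branch: np.ndarray,
    modules: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    libsize = np.exp(rng.normal(config.libsize_logmean, config.libsize_logsd, size=t.size))
    rel = _profile_matrix(t, branch, modules, config.profile_params)
    baseline = _gene_baselines(config, modules)
    mu = libsize[:, None] * baseline[None, :] * rel
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    return counts, mu


def expected_means(config: SimConfig, truth: SimTruth) -> np.ndarray:
    """Generative mean counts (at unit library size) per cell x gene."""
    _, modules, _ = _gene_ids(config)
    rel = _profile_matrix(truth.pseudotime, truth.branch, modules, config.profile_params)
    return _gene_baselines(config, modules)[None, :] * rel


def simulate_aging_dataset(config: SimConfig | None = None) -> tuple[CountMatrix, SimTruth]:
    """Generate the cross-sectional aging dataset plus ground truth.

    Deterministic given ``config.seed``.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    t, ages, branch = _draw_latents(config, rng)
    gene_ids, modules, membership = _gene_ids(config)
    counts, _ = _emit_counts(config, rng, t, branch, modules)
    cell_ids = [f"cell{i:05d}_{a}mo" for i, a in enumerate(ages)]
    cm = CountMatrix(
        counts=sparse.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_meta=pd.DataFrame({"age": ages, "condition": "aging"}, index=cell_ids),
    )
    truth = SimTruth(pseudotime=t, age=ages, branch=branch, module_membership=membership)
    return cm, truth


def simulate_condition_shift(
    base_truth: SimTruth,
    config: SimConfig,
    delta: float,
) -> tuple[CountMatrix, SimTruth]:
    """Emit a 'treated' dataset whose cells sit at pseudotime t + delta.

    The same generative model is sampled at the shifted (clamped) latent
    positions; branches are re-assigned at the new positions.  Deterministic
    given ``config.seed`` (a fixed stream offset separates it from the base
    dataset's draws).
    """
    config.validate()
    if abs(delta) > 1.0:
        raise ValueError("delta must satisfy |delta| <= 1")
    rng = np.random.default_rng([config.seed, 104729])  # distinct stream
    t = np.clip(base_truth.pseudotime + delta, 0.0, 1.0)
    branch = np.where(t < config.branch_threshold, "trunk", "inflammatory").astype(object)
    late = t >= config.branch_threshold
    myeloid_draw = rng.random(t.size) < config.branch_prob
    branch[late & myeloid_draw] = "myeloid"
    gene_ids, modules, membership = _gene_ids(config)
    counts, _ = _emit_counts(config, rng, t, branch, modules)
    cell_ids = [f"trt{i:05d}_{a}mo" for i, a in enumerate(base_truth.age)]
    cm = CountMatrix(
        counts=sparse.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_meta=pd.DataFrame(
            {"age": base_truth.age, "condition": "treated"}, index=cell_ids
        ),
    )
    truth = SimTruth(
        pseudotime=t,
        age=base_truth.age,
        branch=branch,
        module_membership=membership,
        delta=delta,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# image fixtures
# ---------------------------------------------------------------------------

@dataclass
class ImageFixture:
    """Synthetic microscopy fixture: label mask + puncta channel + truth."""

    label_mask: np.ndarray
    puncta_image: np.ndarray
    truth: dict                      # cell id -> list of (area_px, intensity)
    resolution_um_per_px: float

    def __post_init__(self):
        if self.label_mask.shape != self.puncta_image.shape:
            raise ValueError("mask and puncta image shapes differ")


_TILE = 44          # px per cell tile
_RADIUS = 18        # cell disk radius within the tile


def _blob_pixels(center: tuple[int, int], area: int) -> np.ndarray:
    """Row-major pixel block of exactly *area* pixels around *center*."""
    side = int(math.ceil(math.sqrt(area)))
    r0 = center[0] - side // 2
    c0 = center[1] - side // 2
    rows, cols = np.meshgrid(np.arange(r0, r0 + side), np.arange(c0, c0 + side),
                             indexing="ij")
    flat = np.stack([rows.ravel(), cols.ravel()], axis=1)
    return flat[:area]


def simulate_image_fixture(
    n_cells: int,
    puncta_spec: list[tuple[int, int, float]],
    resolution_um_per_px: float = 0.312,
    seed: int = 0,
) -> ImageFixture:
    """Render non-overlapping cell disks on a grid and place puncta.

    puncta_spec entries are ``(cell_id, area_px, intensity)`` with cell ids
    in 1..n_cells.  Each punctum is rendered as a compact pixel block fully
    inside its cell; violating the cell footprint raises GenerationError.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if resolution_um_per_px <= 0:
        raise ValueError("resolution_um_per_px must be positive")
    # layout and puncta placement are deterministic; *seed* is accepted for
    # interface stability should jittered placement be added
    n_cols = int(math.ceil(math.sqrt(n_cells)))
    n_rows = int(math.ceil(n_cells / n_cols))
    shape = (n_rows * _TILE, n_cols * _TILE)
    mask = np.zeros(shape, dtype=np.int32)
    centers = {}
    for k in range(n_cells):
        r = (k // n_cols) * _TILE + _TILE // 2
        c = (k % n_cols) * _TILE + _TILE // 2
        # carve the local tile only, not a full-image grid per cell
        r_lo, r_hi = r - _RADIUS - 1, r + _RADIUS + 2
        c_lo, c_hi = c - _RADIUS - 1, c + _RADIUS + 2
        sub_r, sub_c = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi),
                                   indexing="ij")
        disk = (sub_r - r) ** 2 + (sub_c - c) ** 2 <= _RADIUS ** 2
        mask[r_lo:r_hi, c_lo:c_hi][disk] = k + 1
        centers[k + 1] = (r, c)

    puncta = np.zeros(shape, dtype=np.uint16)
    truth: dict = {k + 1: [] for k in range(n_cells)}
    per_cell_count: dict = {k + 1: 0 for k in range(n_cells)}
    # deterministic anchor offsets so multiple puncta in one cell never overlap
    offsets = [(0, 0), (-12, -12), (-12, 12), (12, -12), (12, 12)]
    for cell_id, area, intensity in puncta_spec:
        if cell_id not in centers:
            raise GenerationError(f"cell id {cell_id} outside 1..{n_cells}")
        if area < 1:
            raise GenerationError(f"punctum area {area} < 1 px")
        slot = per_cell_count[cell_id]
        if slot >= len(offsets):
            raise GenerationError(f"too many puncta for cell {cell_id}")
        r, c = centers[cell_id]
        anchor = (r + offsets[slot][0], c + offsets[slot][1])
        pix = _blob_pixels(anchor, int(area))
        out_of_bounds = ((pix[:, 0] < 0) | (pix[:, 0] >= shape[0])
                         | (pix[:, 1] < 0) | (pix[:, 1] >= shape[1]))
        if out_of_bounds.any():
            raise GenerationError(
                f"punctum of {area} px does not fit inside cell {cell_id}"
            )
        inside = mask[pix[:, 0], pix[:, 1]] == cell_id
        if not inside.all():
            raise GenerationError(
                f"punctum of {area} px does not fit inside cell {cell_id}"
            )
        if np.any(puncta[pix[:, 0], pix[:, 1]] > 0):
            raise GenerationError(f"puncta overlap in cell {cell_id}")
        puncta[pix[:, 0], pix[:, 1]] = int(round(intensity))
        truth[cell_id].append((int(area), float(intensity)))
        per_cell_count[cell_id] += 1
    return ImageFixture(
        label_mask=mask,
        puncta_image=puncta,
        truth=truth,
        resolution_um_per_px=resolution_um_per_px,
    )
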