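"""Formula-defined microscopy quantification for microglia activation.

Operators mirror the standard FIJI workflow: maximum-intensity projection
of z-stacks, thresholding of a puncta channel, 8-connected component
labeling intersected with per-cell ROI masks, a minimum particle-size rule
(default 100 px at 0.312 um/px, i.e. the printed 31.2 um equivalence) to
call a cell activated, mean channel intensity within each ROI, and
puncta-intensity-normalized counts for single-molecule RNA in situ data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "QuantConfig",
    "max_intensity_projection",
    "percent_activated",
    "mean_intensity_in_mask",
    "rnascope_normalized_count",
    "px_area_to_um",
]


@dataclass
class QuantConfig:
    """Quantification parameters.

    min_particle_px: puncta components at least this large (in pixels,
    within a cell) mark the cell as activated.  resolution_um_per_px is the
    imaging scale.  intensity_threshold is the 8-bit-style cutoff applied
    to the puncta channel before component labeling.
    """

    min_particle_px: int = 100
    resolution_um_per_px: float = 0.312
    intensity_threshold: float = 0.0

    def __post_init__(self):
        if self.min_particle_px <= 0:
            raise ValueError("min_particle_px must be positive")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be nonnegative")


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over the leading (z) axis."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a z-stack with shape (z, rows, cols)")
    return stack.max(axis=0)


def _check_mask(label_mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(label_mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("label mask contains no cells")
    if not np.array_equal(labels, np.arange(1, labels.size + 1)):
        raise ValueError("mask labels must be contiguous 1..K")
    return mask


def percent_activated(
    label_mask: np.ndarray,
    puncta_image: np.ndarray,
    cfg: QuantConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Percent of cells containing a large-enough punctum.

    The puncta channel is thresholded, 8-connected components are labeled,
    and each component is intersected with every cell's mask: the area of a
    component *within* a cell counts toward that cell (components straddling
    cells are split).  A cell is activated iff any within-cell component
    area reaches cfg.min_particle_px.  Returns (100 * activated / total,
    per-cell table).
    """
    cfg = cfg or QuantConfig()
    mask = _check_mask(label_mask)
    img = np.asarray(puncta_image)
    if img.shape != mask.shape:
        raise ValueError("puncta image and mask shapes differ")
    binary = img > cfg.intensity_threshold
    comps = measure.label(binary, connectivity=2)  # 8-connectivity
    n_cells = int(mask.max())
    activated = np.zeros(n_cells, dtype=bool)
    largest = np.zeros(n_cells, dtype=int)
    if comps.max() > 0:
        # joint histogram of (component, cell) pairs gives within-cell areas
        pair = comps.astype(np.int64) * (n_cells + 1) + mask.astype(np.int64)
        sel = (comps > 0) & (mask > 0)
        codes, areas = np.unique(pair[sel], return_counts=True)
        cells = codes % (n_cells + 1)
        for cell, area in zip(cells, areas):
            ci = int(cell) - 1
            largest[ci] = max(largest[ci], int(area))
        activated = largest >= cfg.min_particle_px
    table = pd.DataFrame(
        {
            "cell": np.arange(1, n_cells + 1),
            "largest_within_cell_punctum_px": largest,
            "activated": activated,
        }
    ).set_index("cell")
    return 100.0 * activated.sum() / n_cells, table


def mean_intensity_in_mask(
    label_mask: np.ndarray,
    intensity_image: np.ndarray,
) -> pd.Series:
    """Arithmetic mean intensity over each cell's pixels.

    Labels with no pixels are excluded (they cannot occur in a contiguous
    mask, but empty labels in arbitrary input are skipped rather than NaN).
    """
    mask = _check_mask(label_mask)
    img = np.asarray(intensity_image, dtype=float)
    if img.shape != mask.shape:
        raise ValueError("intensity image and mask shapes differ")
    n_cells = int(mask.max())
    flat_mask = mask.ravel()
    flat_img = img.ravel()
    sums = np.bincount(flat_mask, weights=flat_img, minlength=n_cells + 1)
    areas = np.bincount(flat_mask, minlength=n_cells + 1)
    means = {}
    for k in range(1, n_cells + 1):
        if areas[k] > 0:
            means[k] = sums[k] / areas[k]
    return pd.Series(means, name="mean_intensity")


def rnascope_normalized_count(
    label_mask: np.ndarray,
    puncta_image: np.ndarray,
    reference_puncta: list[float],
    cells_to_measure: list[int] | None = None,
) -> pd.Series:
    """Per-cell puncta-intensity-normalized transcript count.

    Total puncta-channel intensity within each cell divided by the mean
    intensity of the reference puncta (the per-section single-punctum
    calibration).
    """
    if len(reference_puncta) < 1:
        raise ValueError("need at least one reference punctum")
    ref = float(np.mean(reference_puncta))
    if ref == 0:
        raise ValueError("mean reference punctum intensity is zero")
    mask = _check_mask(label_mask)
    img = np.asarray(puncta_image, dtype=float)
    if img.shape != mask.shape:
        raise ValueError("puncta image and mask shapes differ")
    n_cells = int(mask.max())
    sums = np.bincount(mask.ravel(), weights=img.ravel(), minlength=n_cells + 1)
    cells = cells_to_measure or list(range(1, n_cells + 1))
    bad = [c for c in cells if not (1 <= c <= n_cells)]
    if bad:
        raise ValueError(f"cells outside mask labels: {bad}")
    return pd.Series({c: sums[c] / ref for c in cells}, name="normalized_count")


def px_area_to_um(area_px: float, resolution_um_per_px: float = 0.312) -> float:
    """Linear pixel-to-micron conversion: area_px * resolution.

    Note the printed equivalence this mirrors (100 px <-> 31.2 um at
    0.312 um/px) applies a linear length factor to a pixel count; the
    operator reproduces that convention as stated rather than a squared
    area conversion.
    """
    if resolution_um_per_px <= 0:
        raise ValueError("resolution_um_per_px must be positive")
    if area_px < 0:
        raise ValueError("area_px must be nonnegative")
    return float(area_px) * float(resolution_um_per_px)
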