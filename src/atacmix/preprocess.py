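"""Peak and cell filtering for model-ready binary accessibility matrices.

The pipeline applied to a raw count matrix is, in order:

1. :func:`filter_peaks` — keep peaks observed with at least
   ``min_reads_per_peak_cell`` reads in at least ``min_cells`` cells;
2. :func:`filter_cells` — keep cells whose total read count is at least
   ``n_filtered_peaks / cell_count_divisor`` (divisor 50 by default);
3. :func:`drop_rare_ubiquitous` — optional, for very large peak sets: remove
   peaks with reads > 2 in fewer than X% of cells (rare) and peaks with reads
   >= 1 in at least (100 - X)% of cells (ubiquitous);
4. :func:`binarize_input` — mask values greater than 1 to 1, giving the
   {0,1} matrix consumed by the Bernoulli likelihood.

Raw counts should be kept alongside the binarized matrix: the post-model
imputation-binarization thresholds are defined on raw means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .matrix_io import PeakByCellMatrix

__all__ = [
    "FilterConfig",
    "PRESETS",
    "filter_peaks",
    "filter_cells",
    "drop_rare_ubiquitous",
    "binarize_input",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for peak/cell filtering.

    ``rare_ubiquitous_x`` of ``None`` disables step 3;
    ``cell_count_divisor`` of ``math.inf`` disables the cell filter.
    """

    min_cells: int = 10
    min_reads_per_peak_cell: int = 2
    rare_ubiquitous_x: float | None = None
    cell_count_divisor: float = 50.0

    def __post_init__(self) -> None:
        if self.min_cells < 0:
            raise ValueError("min_cells must be >= 0")
        if self.min_reads_per_peak_cell < 0:
            raise ValueError("min_reads_per_peak_cell must be >= 0")
        if self.rare_ubiquitous_x is not None and not (
            0 < self.rare_ubiquitous_x < 50
        ):
            raise ValueError("rare_ubiquitous_x must lie in (0, 50)")
        if self.cell_count_divisor <= 0:
            raise ValueError("cell_count_divisor must be positive")


#: Per-dataset thresholds as published for the validation mixtures.
PRESETS: dict[str, FilterConfig] = {
    "insilico": FilterConfig(min_cells=10, min_reads_per_peak_cell=2,
                             rare_ubiquitous_x=5.0),
    "gm12878_hek293t": FilterConfig(min_cells=10, min_reads_per_peak_cell=2),
    "gm12878_hl60": FilterConfig(min_cells=10, min_reads_per_peak_cell=2),
    "leukemia": FilterConfig(min_cells=5, min_reads_per_peak_cell=2),
    "forebrain": FilterConfig(min_cells=50, min_reads_per_peak_cell=2),
    "breast_tumor": FilterConfig(min_cells=5, min_reads_per_peak_cell=1),
    "splenocyte": FilterConfig(min_cells=0, min_reads_per_peak_cell=0),
}


def _dense_bool_counts(values, threshold: int) -> np.ndarray:
    """Per-peak number of cells with count >= threshold."""
    if threshold <= 0:
        return np.full(values.shape[0], values.shape[1])
    if sp.issparse(values):
        return np.asarray((values >= threshold).sum(axis=1)).ravel()
    return (np.asarray(values) >= threshold).sum(axis=1)


def filter_peaks(m: PeakByCellMatrix, cfg: FilterConfig) -> PeakByCellMatrix:
    """Keep peaks with >= ``min_reads_per_peak_cell`` reads in >= ``min_cells`` cells."""
    n_qualifying = _dense_bool_counts(m.values, cfg.min_reads_per_peak_cell)
    keep = np.flatnonzero(n_qualifying >= cfg.min_cells)
    if keep.size == 0:
        raise ValueError(
            "peak filter removed all peaks "
            f"(min_cells={cfg.min_cells}, min_reads={cfg.min_reads_per_peak_cell})"
        )
    log.info("filter_peaks: %d -> %d peaks", m.n_peaks, keep.size)
    return m.subset_peaks(keep)


def filter_cells(m: PeakByCellMatrix, cfg: FilterConfig) -> PeakByCellMatrix:
    """Keep cells with total read count >= n_peaks / ``cell_count_divisor``.

    Call after :func:`filter_peaks`: the threshold is defined on the number
    of *filtered* peaks.
    """
    if math.isinf(cfg.cell_count_divisor):
        return m
    threshold = m.n_peaks / cfg.cell_count_divisor
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    keep = np.flatnonzero(totals >= threshold)
    if keep.size == 0:
        raise ValueError(
            f"cell filter removed all cells (threshold {threshold:.1f} reads)"
        )
    log.info("filter_cells: %d -> %d cells (threshold %.1f reads)",
             m.n_cells, keep.size, threshold)
    return m.subset_cells(keep)


def drop_rare_ubiquitous(m: PeakByCellMatrix, x: float) -> PeakByCellMatrix:
    """Remove rare and ubiquitous peaks.

    Rare: reads > 2 in fewer than ``x``% of cells. Ubiquitous: reads >= 1 in
    at least ``100 - x``% of cells. Both predicates are evaluated on the same
    input peak set.
    """
    if not (0 < x < 50):
        raise ValueError("x must lie in (0, 50)")
    n_cells = m.n_cells
    n_gt2 = _dense_bool_counts(m.values, 3)  # integer counts: >2 <=> >=3
    n_ge1 = _dense_bool_counts(m.values, 1)
    rare = n_gt2 < (x / 100.0) * n_cells
    ubiquitous = n_ge1 >= ((100.0 - x) / 100.0) * n_cells
    keep = np.flatnonzero(~(rare | ubiquitous))
    if keep.size == 0:
        raise ValueError("rare/ubiquitous filter removed all peaks")
    log.info("drop_rare_ubiquitous(x=%.1f): %d -> %d peaks",
             x, m.n_peaks, keep.size)
    return m.subset_peaks(keep)


def binarize_input(m: PeakByCellMatrix) -> PeakByCellMatrix:
    """Mask values greater than 1 to 1 (and keep zeros), giving a {0,1} matrix."""
    v = m.values
    if sp.issparse(v):
        out = v.copy()
        out.data = np.minimum(out.data, 1)
    else:
        out = np.minimum(np.asarray(v), 1)
    return m.with_values(out)


def preprocess(
    m: PeakByCellMatrix,
    cfg: FilterConfig = FilterConfig(),
    *,
    binarize: bool = True,
) -> tuple[PeakByCellMatrix, dict]:
    """Full filter pipeline: peaks -> cells -> rare/ubiquitous -> binarize.

    Returns the processed matrix together with a summary report of
    before/after dimensions per stage.
    """
    report: dict = {"input": {"n_peaks": m.n_peaks, "n_cells": m.n_cells}}
    out = filter_peaks(m, cfg)
    report["after_peak_filter"] = {"n_peaks": out.n_peaks, "n_cells": out.n_cells}
    out = filter_cells(out, cfg)
    report["after_cell_filter"] = {"n_peaks": out.n_peaks, "n_cells": out.n_cells}
    if cfg.rare_ubiquitous_x is not None:
        out = drop_rare_ubiquitous(out, cfg.rare_ubiquitous_x)
        report["after_rare_ubiquitous"] = {
            "n_peaks": out.n_peaks, "n_cells": out.n_cells,
        }
    if binarize:
        out = binarize_input(out)
    report["output"] = {"n_peaks": out.n_peaks, "n_cells": out.n_cells}
    return out, report
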