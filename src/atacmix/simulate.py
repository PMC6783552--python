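"""Block-structured scATAC-seq simulation with dropout and noise corruption.

The reference dataset mimics a mixture of cell types with disjoint sets of
type-specific open peaks: by default 300 cells in 3 equal clusters over 1000
peaks, each cluster owning a block of 100 specific peaks. Within a cluster's
cells its specific peaks carry a count of 1 or 2 at ratio 1:4 (P(1)=0.2,
P(2)=0.8); every other entry is 0 — the reference has no missing values.

Corruption reproduces the two-step protocol used to benchmark imputation:

1. dropout — every nonzero entry is independently zeroed with probability
   ``dropout_rate`` (benchmarks sweep 0.1 to 0.8);
2. noise — every entry is independently overwritten with 1 or 2 (ratio 1:4)
   with probability ``noise_prob`` (0.1 by default).

Boolean masks record exactly which entries each step touched, so recovery
can be scored against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import Peak, PeakByCellMatrix

__all__ = ["SimConfig", "SimTruthBundle", "generate_reference", "corrupt",
           "corrupt_real", "simulate"]

#: P(value == 1) and P(value == 2) for specific peaks and injected noise
_P_ONE, _P_TWO = 0.2, 0.8


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the published benchmark protocol."""

    n_cells: int = 300
    n_peaks: int = 1000
    n_clusters: int = 3
    specific_peaks_per_cluster: int = 100
    value_one_prob: float = _P_ONE
    dropout_rate: float = 0.0
    noise_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters * self.specific_peaks_per_cluster > self.n_peaks:
            raise ValueError("cluster-specific peak blocks exceed n_peaks")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not (0 <= self.noise_prob < 1):
            raise ValueError("noise_prob must lie in [0, 1)")
        if not (0 < self.value_one_prob < 1):
            raise ValueError("value_one_prob must lie in (0, 1)")


@dataclass
class SimTruthBundle:
    """Ground truth and corrupted observation for one simulated dataset."""

    reference: PeakByCellMatrix
    corrupted: PeakByCellMatrix
    labels: np.ndarray  # true cluster id per cell
    dropout_mask: np.ndarray  # True where the dropout step zeroed an entry
    noise_mask: np.ndarray  # True where the noise step overwrote an entry


def _cluster_assignment(n_cells: int, n_clusters: int) -> np.ndarray:
    """Even split; remainder cells assigned round-robin."""
    labels = np.arange(n_cells) % n_clusters
    return np.sort(labels)


def _draw_values(rng: np.random.Generator, size, value_one_prob: float) -> np.ndarray:
    return np.where(rng.random(size) < value_one_prob, 1, 2).astype(np.int64)


def generate_reference(cfg: SimConfig = SimConfig()) -> SimTruthBundle:
    """Generate the ground-truth matrix and true labels (no corruption).

    The returned bundle's ``corrupted`` field equals the reference and both
    masks are all-False; apply :func:`corrupt` for the benchmark protocol.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = _cluster_assignment(cfg.n_cells, cfg.n_clusters)
    values = np.zeros((cfg.n_peaks, cfg.n_cells), dtype=np.int64)
    for c in range(cfg.n_clusters):
        peak_lo = c * cfg.specific_peaks_per_cluster
        peak_hi = peak_lo + cfg.specific_peaks_per_cluster
        cells = np.flatnonzero(labels == c)
        block = _draw_values(
            rng, (cfg.specific_peaks_per_cluster, cells.size), cfg.value_one_prob
        )
        values[peak_lo:peak_hi, cells] = block

    peaks = [Peak("chrSim", 1000 * i, 1000 * i + 500) for i in range(cfg.n_peaks)]
    cells = [f"cell_{i:04d}" for i in range(cfg.n_cells)]
    ref = PeakByCellMatrix(
        values, peaks, cells, labels=[f"cluster_{c}" for c in labels]
    )
    empty = np.zeros(values.shape, dtype=bool)
    return SimTruthBundle(ref, ref, labels, empty, empty.copy())


def corrupt(
    m: PeakByCellMatrix,
    dropout_rate: float,
    noise_prob: float,
    seed: int,
    *,
    labels: np.ndarray | None = None,
    value_one_prob: float = _P_ONE,
) -> SimTruthBundle:
    """Apply dropout then noise injection; return matrix plus masks.

    Dropout zeroes nonzero entries with probability ``dropout_rate``; noise
    then overwrites arbitrary entries (including freshly zeroed ones) with
    1 or 2 at ratio 1:4 with probability ``noise_prob``.
    """
    if not (0 <= dropout_rate < 1):
        raise ValueError("dropout_rate must lie in [0, 1)")
    if not (0 <= noise_prob < 1):
        raise ValueError("noise_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ref = m.dense()
    out = ref.copy()

    dropout_mask = (rng.random(out.shape) < dropout_rate) & (out != 0)
    out[dropout_mask] = 0

    noise_mask = rng.random(out.shape) < noise_prob
    out[noise_mask] = _draw_values(rng, int(noise_mask.sum()), value_one_prob)

    if labels is None:
        labels = np.zeros(m.n_cells, dtype=np.int64)
    return SimTruthBundle(m, m.with_values(out), np.asarray(labels),
                          dropout_mask, noise_mask)


def corrupt_real(
    m: PeakByCellMatrix, rate: float, seed: int
) -> tuple[PeakByCellMatrix, np.ndarray]:
    """Dropout-only corruption of an arbitrary matrix, for robustness curves.

    Returns the corrupted matrix and the boolean mask of zeroed entries
    (a subset of the originally nonzero entries).
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = m.dense().copy()
    mask = (rng.random(out.shape) < rate) & (out != 0)
    out[mask] = 0
    return m.with_values(out), mask


def simulate(cfg: SimConfig = SimConfig()) -> SimTruthBundle:
    """Generate a reference and corrupt it per ``cfg`` in one call."""
    bundle = generate_reference(cfg)
    if cfg.dropout_rate == 0 and cfg.noise_prob == 0:
        return bundle
    corr = corrupt(
        bundle.reference,
        cfg.dropout_rate,
        cfg.noise_prob,
        # decorrelate from the value draw while staying reproducible
        seed=cfg.seed + 1_000_003,
        labels=bundle.labels,
        value_one_prob=cfg.value_one_prob,
    )
    return corr
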