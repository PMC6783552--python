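import numpy as np
import pytest

from atacmix import cluster as cl
from atacmix import gmvae
from atacmix import preprocess as pp
from atacmix.matrix_io import Peak, PeakByCellMatrix
from atacmix.simulate import SimConfig, simulate


def random_matrix(rng, n_peaks=20, n_cells=8, max_count=4, labels=False):
    values = rng.integers(0, max_count + 1, size=(n_peaks, n_cells))
    peaks = [Peak(f"chr{1 + i % 3}", 100 * i, 100 * i + 50) for i in range(n_peaks)]
    cells = [f"c{i}" for i in range(n_cells)]
    lab = [f"t{i % 2}" for i in range(n_cells)] if labels else None
    return PeakByCellMatrix(values, peaks, cells, labels=lab)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    return random_matrix(rng)


#: training config used for every end-to-end fit in the suite: the quick-mode
#: encoder with a modest epoch budget, sized for the 300x1000 benchmark matrix
QUICK_FIT = dict(k=3, quick=True, max_epochs=100, patience=15)


class _ModelCache:
    """Train-once cache for the corrupted-simulation models shared by the
    clustering-recovery and imputation-recovery tests."""

    def __init__(self):
        self._store = {}

    def get(self, dropout: float, seed: int):
        key = (dropout, seed)
        if key not in self._store:
            bundle = simulate(SimConfig(dropout_rate=dropout, noise_prob=0.1,
                                        seed=seed))
            binarized = pp.binarize_input(bundle.corrupted)
            model = gmvae.fit(binarized, gmvae.TrainConfig(seed=seed, **QUICK_FIT))
            self._store[key] = (bundle, binarized, model)
        return self._store[key]


@pytest.fixture(scope="session")
def trained_models():
    return _ModelCache()


def mean_cell_correlation(matrix: np.ndarray, reference: np.ndarray) -> float:
    """Mean per-cell Pearson correlation between two peak-by-cell matrices."""
    out = []
    for j in range(matrix.shape[1]):
        u = matrix[:, j] - matrix[:, j].mean()
        v = reference[:, j] - reference[:, j].mean()
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom > 0:
            out.append(float(u @ v / denom))
    return float(np.mean(out))
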