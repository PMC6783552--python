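"""Clustering on latent features, cluster-number estimation and metrics.

K-means (k-means++ init, fixed seed 18 by default for reproducibility) is
applied to the extracted latent features. Agreement with reference labels is
scored three ways:

* ARI — the chance-adjusted Rand index from the contingency table;
* NMI — mutual information normalized by the geometric mean of the Shannon
  entropies of the two labelings;
* micro-F1 — predicted clusters are matched to reference classes by
  maximum-overlap (Hungarian) assignment, then precision/recall/F1 are
  micro-averaged over cells.

The number of clusters can be estimated from the spectrum of X^T X: the
count of eigenvalues exceeding a threshold built from the Tracy-Widom
distribution of the largest eigenvalue of a Wishart matrix,

    mean = (sqrt(n-1) + sqrt(p))^2
    s.d. = (sqrt(n-1) + sqrt(p)) * (1/sqrt(n-1) + 1/p)^(1/3)

with n peaks and p cells, threshold = mean + t * s.d. The published s.d.
writes 1/p in the second factor where the classical expression has
1/sqrt(p); both are available (``sd_form="published"`` is the default,
``"corrected"`` gives the classical form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .matrix_io import PeakByCellMatrix

__all__ = [
    "ClusterAssignment",
    "MetricReport",
    "kmeans_cluster",
    "ari",
    "nmi",
    "f1_micro",
    "evaluate",
    "estimate_k",
    "tracy_widom_threshold",
]

#: fixed K-means seed used throughout for reproducibility
DEFAULT_KMEANS_SEED = 18

#: upper ~0.001 Tracy-Widom quantile, the customary significance multiplier
DEFAULT_TW_MULTIPLIER = 3.2724


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size and self.labels.max() >= self.k:
            raise ValueError("cluster id out of range")


@dataclass(frozen=True)
class MetricReport:
    ari: float
    nmi: float
    f1: float

    def as_dict(self) -> dict:
        return {"ari": self.ari, "nmi": self.nmi, "f1": self.f1}


def kmeans_cluster(
    features: np.ndarray, k: int, seed: int = DEFAULT_KMEANS_SEED
) -> ClusterAssignment:
    """K-means with k-means++ init on the latent features."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < k:
        raise ValueError(f"cannot form {k} clusters from {features.shape[0]} cells")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return ClusterAssignment(km.fit_predict(features), k)


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"labelings differ in length ({a.size} vs {b.size})")
    return a, b


def ari(a, b) -> float:
    """Adjusted Rand index: 0 expected for random labelings, 1 for identical."""
    a, b = _check_pair(a, b)
    return float(adjusted_rand_score(a, b))


def nmi(a, b) -> float:
    """Mutual information over the geometric mean of the two entropies."""
    a, b = _check_pair(a, b)
    if len(set(a)) < 2 or len(set(b)) < 2:
        raise ValueError("NMI is undefined (0/0) for a zero-entropy labeling")
    return float(normalized_mutual_info_score(a, b, average_method="geometric"))


def match_clusters(pred, truth) -> dict:
    """Hungarian maximum-overlap mapping from predicted cluster id to class."""
    pred, truth = _check_pair(pred, truth)
    cont = contingency_matrix(pred, truth)
    rows, cols = linear_sum_assignment(-cont)
    pred_ids = np.unique(pred)
    truth_ids = np.unique(truth)
    return {pred_ids[r]: truth_ids[c] for r, c in zip(rows, cols)}


def f1_micro(pred, truth) -> float:
    """Micro-averaged F1 after Hungarian matching of clusters to classes.

    With a one-to-one matching, micro precision and recall both equal the
    fraction of cells whose matched cluster label agrees with the reference;
    predicted clusters left unmatched (when there are more clusters than
    classes) count all their cells as errors.
    """
    pred, truth = _check_pair(pred, truth)
    mapping = match_clusters(pred, truth)
    mapped = np.array([mapping.get(p, None) for p in pred], dtype=object)
    correct = sum(m == t for m, t in zip(mapped, truth))
    return float(correct / pred.size)


def evaluate(pred, truth) -> MetricReport:
    """All three agreement scores for a predicted clustering vs reference."""
    labels = pred.labels if isinstance(pred, ClusterAssignment) else pred
    return MetricReport(ari(labels, truth), nmi(labels, truth),
                        f1_micro(labels, truth))


# ---------------------------------------------------------------------------
# cluster-number estimation
# ---------------------------------------------------------------------------


def tracy_widom_threshold(
    n_peaks: int, n_cells: int, t: float = DEFAULT_TW_MULTIPLIER,
    sd_form: str = "published",
) -> float:
    """Significance threshold mean + t * s.d. for eigenvalues of X^T X."""
    n, p = n_peaks, n_cells
    if n < 2 or p < 2:
        raise ValueError("need at least 2 peaks and 2 cells")
    a = np.sqrt(n - 1) + np.sqrt(p)
    mean = a**2
    if sd_form == "published":
        sd = a * (1 / np.sqrt(n - 1) + 1 / p) ** (1 / 3)
    elif sd_form == "corrected":
        sd = a * (1 / np.sqrt(n - 1) + 1 / np.sqrt(p)) ** (1 / 3)
    else:
        raise ValueError("sd_form must be 'published' or 'corrected'")
    return float(mean + t * sd)


def estimate_k(
    m: PeakByCellMatrix | np.ndarray,
    t: float = DEFAULT_TW_MULTIPLIER,
    *,
    sd_form: str = "published",
    center: bool = False,
) -> int:
    """Number of significant eigenvalues of X^T X (cells x cells).

    Operates on the binarized matrix as-is by default; ``center=True``
    subtracts per-peak means first.
    """
    X = m.dense().astype(float) if isinstance(m, PeakByCellMatrix) else \
        np.asarray(m, dtype=float)
    if sp.issparse(X):
        X = X.toarray()
    n_peaks, n_cells = X.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    gram = X.T @ X
    eigvals = np.linalg.eigvalsh(gram)
    thr = tracy_widom_threshold(n_peaks, n_cells, t, sd_form)
    return int(np.sum(eigvals > thr))
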