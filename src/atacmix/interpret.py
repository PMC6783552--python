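"""Downstream computations on imputed matrices and trained decoders.

* :func:`binarize_imputed` — turn decoder probabilities into binary calls
  using per-peak and per-cell means of the *raw* matrix as thresholds;
* :func:`metacell` / :func:`metacell_correlation` — cluster-mean profiles
  and each cell's Pearson correlation with its own cluster's meta-cell, the
  denoising benchmark;
* :func:`confusion_score` — how well imputation preserves inter/intra
  cluster structure: the imputed-vs-raw meta-cell cross-correlation matrix
  with each diagonal entry r replaced by 1 - r, averaged over the upper
  triangle (diagonal included); 0 means perfect preservation;
* :func:`specificity_score` — entropy-based cluster specificity of a peak:
  1 - sqrt(JensenDiv(p, q)) with base-2 entropies, where p is the peak's
  normalized signal mass per cluster and q the one-hot ideal pattern;
* :func:`feature_peaks` — peaks whose decoder weight for a latent feature
  deviates from that feature's weight mean by more than ``cutoff_sd``
  standard deviations (2.5 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .matrix_io import PeakByCellMatrix

__all__ = [
    "binarize_imputed",
    "metacell",
    "metacell_correlation",
    "confusion_score",
    "specificity_score",
    "top_specific_peaks",
    "FeaturePeakAssociation",
    "feature_peaks",
    "feature_subset_embedding",
]

log = logging.getLogger(__name__)


def _as_array(m) -> np.ndarray:
    if isinstance(m, PeakByCellMatrix):
        return m.dense().astype(float)
    return np.asarray(m, dtype=float)


def binarize_imputed(imputed, raw) -> np.ndarray:
    """Binary calls: 1 iff imputed(i,j) exceeds raw peak-i mean and raw cell-j mean."""
    imp = _as_array(imputed)
    rawv = _as_array(raw)
    if imp.shape != rawv.shape:
        raise ValueError(f"shape mismatch: imputed {imp.shape} vs raw {rawv.shape}")
    peak_means = rawv.mean(axis=1, keepdims=True)  # mean(raw_{i,:})
    cell_means = rawv.mean(axis=0, keepdims=True)  # mean(raw_{:,j})
    return ((imp > peak_means) & (imp > cell_means)).astype(np.int64)


def _label_groups(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    return labels, uniq


def metacell(m, labels) -> np.ndarray:
    """Per-cluster mean profile over peaks; rows follow first appearance order."""
    X = _as_array(m)
    labels, uniq = _label_groups(labels)
    if len(labels) != X.shape[1]:
        raise ValueError("labels must cover every cell")
    out = np.empty((len(uniq), X.shape[0]))
    for i, c in enumerate(uniq):
        members = labels == c
        if not members.any():
            raise ValueError(f"empty cluster {c!r}")
        out[i] = X[:, members].mean(axis=1)
    return out


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = np.linalg.norm(u) * np.linalg.norm(v)
    if denom == 0:
        return np.nan
    return float(u @ v / denom)


def metacell_correlation(
    single_cells, meta: np.ndarray, labels, *, method: str = "pearson"
) -> np.ndarray:
    """Correlation of each cell's peak vector with its own cluster's meta-cell.

    Cells with a zero-variance profile get NaN with a warning; summaries
    should exclude them. Spearman is offered as an option but is often
    ill-defined on sparse near-binary vectors (massive ties).
    """
    X = _as_array(single_cells)
    labels, uniq = _label_groups(labels)
    index = {c: i for i, c in enumerate(uniq)}
    out = np.empty(X.shape[1])
    n_undef = 0
    for j in range(X.shape[1]):
        mrow = meta[index[labels[j]]]
        if method == "pearson":
            r = _pearson(X[:, j], mrow)
        elif method == "spearman":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = spearmanr(X[:, j], mrow).statistic
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        if not np.isfinite(r):
            n_undef += 1
            r = np.nan
        out[j] = r
    if n_undef:
        log.warning("correlation undefined for %d zero-variance cells", n_undef)
    return out


def confusion_score(imputed_meta: np.ndarray, raw_meta: np.ndarray) -> float:
    """Structure-preservation score of imputation; 0 is perfect.

    Builds the K x K cross-correlation matrix C with C[i, j] the Pearson
    correlation of imputed meta-cell i with raw meta-cell j, replaces each
    diagonal entry r by 1 - r, and averages the upper triangle including
    the transformed diagonal. C is not symmetric in general, so the matrix
    is symmetrized first (each unordered cluster pair contributes the mean
    of its two cross-correlations); this leaves symmetric inputs untouched
    and makes the score independent of how clusters are ordered.
    """
    A = np.asarray(imputed_meta, dtype=float)
    B = np.asarray(raw_meta, dtype=float)
    if A.shape != B.shape:
        raise ValueError("meta-cell matrices must share cluster set and order")
    k = A.shape[0]
    C = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            C[i, j] = _pearson(A[i], B[j])
    C[np.diag_indices(k)] = 1.0 - np.diag(C)
    S = 0.5 * (C + C.T)
    iu = np.triu_indices(k)
    return float(S[iu].mean())


# ---------------------------------------------------------------------------
# cluster specificity
# ---------------------------------------------------------------------------


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _jensen_div(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    return _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))


def specificity_score(
    m, labels, *, per_cell: bool = False
) -> pd.DataFrame:
    """Entropy-based cluster specificity of every peak.

    For each peak, p is its observed signal normalized to a probability
    distribution and, for each cluster c, q is the ideal pattern that puts
    all mass uniformly on cluster c. The score is 1 - sqrt(JensenDiv(p, q))
    with base-2 entropies, so both divergence and score live in [0, 1]. By
    default p and q are distributions over *clusters* (the peak's signal
    mass aggregated per cluster); ``per_cell=True`` compares distributions
    over individual cells instead.

    Returns a DataFrame with one row per peak: per-cluster scores, the final
    score (max over clusters) and the argmax cluster. All-zero peaks get NaN
    scores and are flagged in the ``defined`` column.
    """
    X = _as_array(m)
    labels, uniq = _label_groups(labels)
    if len(labels) != X.shape[1]:
        raise ValueError("labels must cover every cell")
    n_peaks = X.shape[0]
    scores = np.full((n_peaks, len(uniq)), np.nan)
    totals = X.sum(axis=1)
    defined = totals > 0
    if not defined.all():
        log.warning("specificity undefined for %d all-zero peaks",
                    int((~defined).sum()))

    if per_cell:
        n_cells = X.shape[1]
        for ci, c in enumerate(uniq):
            members = labels == c
            q = members.astype(float) / members.sum()
            for i in np.flatnonzero(defined):
                p = X[i] / totals[i]
                scores[i, ci] = 1.0 - np.sqrt(max(_jensen_div(p, q), 0.0))
    else:
        mass = np.stack([X[:, labels == c].sum(axis=1) for c in uniq], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = mass / totals[:, None]
        for ci in range(len(uniq)):
            q = np.zeros(len(uniq))
            q[ci] = 1.0
            for i in np.flatnonzero(defined):
                scores[i, ci] = 1.0 - np.sqrt(max(_jensen_div(P[i], q), 0.0))

    df = pd.DataFrame(scores, columns=[f"score_{c}" for c in uniq])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["score"] = np.nanmax(scores, axis=1)
        best = np.where(defined, np.nanargmax(np.nan_to_num(scores, nan=-1),
                                              axis=1), -1)
    df["best_cluster"] = [uniq[b] if b >= 0 else None for b in best]
    df["defined"] = defined
    if isinstance(m, PeakByCellMatrix):
        df.index = m.peak_ids()
    return df


def top_specific_peaks(scores: pd.DataFrame, n: int = 200) -> pd.DataFrame:
    """The n peaks with the highest specificity score (defined peaks only)."""
    return scores[scores["defined"]].nlargest(n, "score")


# ---------------------------------------------------------------------------
# feature-peak associations from the single-layer decoder
# ---------------------------------------------------------------------------


@dataclass
class FeaturePeakAssociation:
    feature: int
    peaks: np.ndarray  # indices of associated peaks
    weights: np.ndarray  # their decoder weights
    cutoff_sd: float


def feature_peaks(
    decoder_weights: np.ndarray, cutoff_sd: float = 2.5, *, two_sided: bool = True
) -> list[FeaturePeakAssociation]:
    """Peaks most strongly wired to each latent feature.

    ``decoder_weights`` is the (d, n_peaks) weight matrix of the single-layer
    decoder. Each feature's weight vector is summarized by its mean and
    standard deviation (Gaussian approximation); peaks beyond ``cutoff_sd``
    standard deviations from the mean are the feature's associated peaks
    (both tails by default, upper tail only with ``two_sided=False``).
    """
    W = np.asarray(decoder_weights, dtype=float)
    out: list[FeaturePeakAssociation] = []
    for f in range(W.shape[0]):
        w = W[f]
        sd = w.std()
        if sd == 0:
            log.warning("feature %d has constant weights; no associations", f)
            idx = np.array([], dtype=int)
        else:
            dev = (w - w.mean()) / sd
            idx = np.flatnonzero(np.abs(dev) > cutoff_sd if two_sided
                                 else dev > cutoff_sd)
        out.append(FeaturePeakAssociation(f, idx, w[idx], cutoff_sd))
    return out


def feature_subset_embedding(features: np.ndarray, keep) -> np.ndarray:
    """Column subset of the latent feature matrix (batch-effect workflow).

    After identifying which features track a nuisance factor such as plate,
    re-embedding on the complementary subset isolates biological variation.
    """
    features = np.asarray(features)
    keep = np.asarray(sorted(set(int(i) for i in np.atleast_1d(keep))))
    if keep.size == 0:
        raise ValueError("keep must be non-empty")
    if keep.min() < 0 or keep.max() >= features.shape[1]:
        raise ValueError("feature index out of range")
    return features[:, keep]
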