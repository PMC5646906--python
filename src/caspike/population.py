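"""Population pipeline: stimulus PCA, k-means grouping, per-cluster mean
rates, histogram distance, and estimator comparison statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .point_process import IntensityGrid

logger = logging.getLogger(__name__)


def pca_weights(X, n_components: int = 3, center: bool = False) -> np.ndarray:
    """Principal-component weights of stimulus time courses.

    Rows of X are per-cell stimulus traces; the weights are the rows of
    X V = U S from the singular value decomposition X = U S V'.  By default
    the matrix is not mean-centred, matching the plain-SVD construction;
    pass ``center=True`` for conventional PCA.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix (cells x time)")
    if not np.any(X):
        raise ValueError("stimulus matrix is identically zero")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    return U[:, :n_components] * S[:n_components]


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray
    error: float     # within-cluster sum of squared distances E
    k: int


def kmeans_cluster(weights, k: int, seed: int | None = None, n_restarts: int = 10) -> ClusterResult:
    """Best-of-restarts k-means partition minimising the within-cluster
    sum of squared distances; empty clusters are re-seeded by the solver."""
    W = np.asarray(weights, dtype=float)
    if k > len(W):
        raise ValueError("k exceeds the number of points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(W)
    labels = km.labels_.astype(int)
    E = float(np.sum((W - km.cluster_centers_[labels]) ** 2))
    return ClusterResult(labels=labels, centroids=km.cluster_centers_, error=E, k=k)


def silhouette_k(weights, k_range=range(2, 7), seed: int | None = None) -> int:
    """Default heuristic for k: silhouette maximum over a small range."""
    from sklearn.metrics import silhouette_score

    W = np.asarray(weights, dtype=float)
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= len(W):
            break
        res = kmeans_cluster(W, k, seed=seed)
        s = silhouette_score(W, res.labels)
        logger.info("silhouette(k=%d) = %.3f", k, s)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("too few points for any k in range")
    return best_k


def cluster_mean_rate(posteriors, labels) -> dict[int, IntensityGrid]:
    """Pointwise mean MAP intensity of the members of each cluster."""
    labels = np.asarray(labels)
    if len(posteriors) != len(labels):
        raise ValueError("one label per posterior required")
    out: dict[int, IntensityGrid] = {}
    for lab in np.unique(labels):
        members = [p.x_star for p, l in zip(posteriors, labels) if l == lab]
        if not members:
            logger.warning("cluster %s empty; skipped", lab)
            continue
        delta = members[0].delta
        if any(m.n != members[0].n or abs(m.delta - delta) > 1e-12 for m in members):
            raise ValueError("posteriors must share a common grid")
        out[int(lab)] = IntensityGrid(np.mean([m.values for m in members], axis=0), delta)
    return out


def histogram_distance(R, S) -> float:
    """Overlap distance H(R, S) = sum_i min(R_i, S_i) / max(sum R, sum S).

    Symmetric, bounded in [0, 1]; equals 1 exactly when the histograms
    coincide.
    """
    R = np.asarray(R, dtype=float)
    S = np.asarray(S, dtype=float)
    if R.shape != S.shape:
        raise ValueError("histograms must share the same binning")
    if np.any(R < 0) or np.any(S < 0):
        raise ValueError("histogram counts must be non-negative")
    denom = max(R.sum(), S.sum())
    if denom == 0:
        raise ValueError("both histograms are empty")
    return float(np.minimum(R, S).sum() / denom)


def compare_estimators(l2_samples_a, l2_samples_b):
    """Two-sided Mann-Whitney rank-sum comparison of two error samples.

    Returns (statistic, p_value); the conventional significance threshold
    is p < 0.05.  Fully tied samples yield p = 1 under the tie-corrected
    normal approximation.
    """
    a = np.asarray(l2_samples_a, dtype=float)
    b = np.asarray(l2_samples_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        # degenerate all-tied case: no evidence of separation by convention
        return float(len(a) * len(b) / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
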