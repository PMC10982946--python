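"""Unsupervised outlier detectors with a uniform score contract.

Every scorer takes a samples x features array and returns one raw outlier
score per sample, with HIGHER meaning MORE outlying.  Proximity detectors
(LOF, KNN, AvgKNN, CBLOF, OCSVM, ABOD), distribution detectors (ECOD) and
ensemble detectors (IForest, FeatureBagging over LOF, locally selective
combination of a LOF/KNN pool) are provided.

scikit-learn supplies the core estimators (LocalOutlierFactor,
NearestNeighbors, KMeans, OneClassSVM, IsolationForest); the angle-based,
ECDF-based, cluster-based-score and selective-combination logic is
implemented here.

A :class:`DistanceCache` can be shared across detectors scoring the same
data so pairwise distance matrices are computed once per metric.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import skew
from sklearn.cluster import KMeans
from sklearn.ensemble import IsolationForest
from sklearn.neighbors import LocalOutlierFactor
from sklearn.svm import OneClassSVM

__all__ = [
    "DistanceCache",
    "score_lof",
    "score_knn",
    "score_avg_knn",
    "score_cblof",
    "score_ocsvm",
    "score_abod",
    "score_ecod",
    "score_iforest",
    "score_feature_bagging",
    "score_lscp",
    "flags_from_scores",
]


class DistanceCache:
    """Memoized pairwise distance matrices for one dataset."""

    def __init__(self, X: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self._dist: dict[str, np.ndarray] = {}

    def distances(self, metric: str) -> np.ndarray:
        if metric not in self._dist:
            metric_name = "cityblock" if metric == "manhattan" else metric
            self._dist[metric] = squareform(pdist(self.X, metric=metric_name))
        return self._dist[metric]


def _neighbor_distances(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest-neighbour distances and indices (self excluded)."""
    n = D.shape[0]
    if k >= n:
        raise ValueError(f"n_neighbors={k} needs more than {k} samples, have {n}")
    Dx = D.copy()
    np.fill_diagonal(Dx, np.inf)
    idx = np.argsort(Dx, axis=1, kind="stable")[:, :k]
    dist = np.take_along_axis(Dx, idx, axis=1)
    return dist, idx


# ---------------------------------------------------------------- proximity

def score_knn(X, n_neighbors: int = 5, metric: str = "euclidean",
              cache: DistanceCache | None = None) -> np.ndarray:
    """Distance to the k-th nearest neighbour (largest-distance variant)."""
    D = (cache or DistanceCache(X)).distances(metric)
    dist, _ = _neighbor_distances(D, n_neighbors)
    return dist[:, -1]


def score_avg_knn(X, n_neighbors: int = 5, metric: str = "euclidean",
                  cache: DistanceCache | None = None) -> np.ndarray:
    """Mean distance to the k nearest neighbours."""
    D = (cache or DistanceCache(X)).distances(metric)
    dist, _ = _neighbor_distances(D, n_neighbors)
    return dist.mean(axis=1)


def score_lof(X, n_neighbors: int = 20, metric: str = "euclidean",
              cache: DistanceCache | None = None) -> np.ndarray:
    """Local outlier factor; score = LOF value (≈1 for inliers, >1 outlying)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = min(n_neighbors, n - 1)
    if cache is not None:
        D = cache.distances(metric)
        lof = LocalOutlierFactor(n_neighbors=k, metric="precomputed")
        lof.fit(D)
    else:
        lof = LocalOutlierFactor(n_neighbors=k, metric=metric)
        lof.fit(X)
    return -lof.negative_outlier_factor_


def score_cblof(X, n_clusters: int = 8, seed: int = 0, alpha: float = 0.9,
                beta: float = 5.0, **_) -> np.ndarray:
    """Cluster-based local outlier factor.

    K-means partitions the data; clusters are split into "large" and
    "small" by the (alpha, beta) rule, and each sample is scored by its
    distance to the nearest large-cluster centroid (its own centroid for
    members of large clusters).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = min(n_clusters, n)
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    labels = km.fit_predict(X)
    centers = km.cluster_centers_
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    sorted_sizes = sizes[order]
    # boundary index: first point where alpha of the mass is covered or the
    # size ratio to the next cluster jumps by beta
    csum = np.cumsum(sorted_sizes)
    boundary = k
    for i in range(k - 1):
        if csum[i] >= alpha * n or (
            sorted_sizes[i + 1] > 0 and sorted_sizes[i] / sorted_sizes[i + 1] >= beta
        ):
            boundary = i + 1
            break
    large = set(order[:boundary].tolist())
    large_centers = centers[sorted(large)]
    scores = np.empty(n)
    for i in range(n):
        if labels[i] in large:
            scores[i] = np.linalg.norm(X[i] - centers[labels[i]])
        else:
            scores[i] = np.min(np.linalg.norm(large_centers - X[i], axis=1))
    return scores


def score_ocsvm(X, kernel: str = "rbf", nu: float = 0.1, **_) -> np.ndarray:
    """One-class SVM; score = negated decision function (margin distance)."""
    X = np.asarray(X, dtype=float)
    # scale-free gamma keeps rbf/sigmoid usable on raw log intensities
    clf = OneClassSVM(kernel=kernel, nu=nu, gamma="scale")
    clf.fit(X)
    return -clf.decision_function(X)


def score_abod(X, n_neighbors: int = 10, cache: DistanceCache | None = None) -> np.ndarray:
    """Fast angle-based outlier detection.

    For each point, the variance of the weighted cosine between all pairs
    of difference vectors to its k nearest neighbours is computed; outliers
    sit at the rim and see others under a narrow angle range, so a SMALL
    variance means outlying.  The returned score is the negated variance.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = min(n_neighbors, n - 1)
    D = (cache or DistanceCache(X)).distances("euclidean")
    _, idx = _neighbor_distances(D, k)
    scores = np.empty(n)
    for i in range(n):
        diffs = X[idx[i]] - X[i]
        norms_sq = np.einsum("ij,ij->i", diffs, diffs)
        ok = norms_sq > 0
        diffs, norms_sq = diffs[ok], norms_sq[ok]
        m = diffs.shape[0]
        if m < 2:
            scores[i] = 0.0
            continue
        dots = diffs @ diffs.T
        denom = np.outer(norms_sq, norms_sq)
        with np.errstate(divide="ignore", invalid="ignore"):
            W = dots / denom
        iu = np.triu_indices(m, k=1)
        scores[i] = -np.var(W[iu])
    return scores


# ------------------------------------------------------------- distribution

def score_ecod(X, **_) -> np.ndarray:
    """Empirical-cumulative-distribution outlier score.

    Per feature, left- and right-tail ECDF probabilities are turned into
    negative log tail weights and summed over features; the per-sample
    score is the maximum of the left, right and skewness-directed sums.
    Parameter-free apart from the flagging contamination.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    # ECDF with the sample itself included: P(x <= xi), P(x >= xi)
    ranks_le = np.empty_like(X)
    ranks_ge = np.empty_like(X)
    for j in range(d):
        col = X[:, j]
        sorted_col = np.sort(col)
        ranks_le[:, j] = np.searchsorted(sorted_col, col, side="right") / n
        ranks_ge[:, j] = (n - np.searchsorted(sorted_col, col, side="left")) / n
    with np.errstate(divide="ignore"):
        o_left = -np.log(ranks_le)
        o_right = -np.log(ranks_ge)
    sk = skew(X, axis=0)
    use_left = sk < 0
    o_auto = np.where(use_left[None, :], o_left, o_right)
    return np.maximum.reduce([o_left.sum(axis=1), o_right.sum(axis=1),
                              o_auto.sum(axis=1)])


# ----------------------------------------------------------------- ensembles

def score_iforest(X, n_estimators: int = 100, seed: int = 0, **_) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    clf = IsolationForest(n_estimators=n_estimators, random_state=seed)
    clf.fit(X)
    return -clf.score_samples(X)


def _zscore(scores: np.ndarray) -> np.ndarray:
    sd = scores.std()
    return (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)


def score_feature_bagging(X, n_estimators: int = 10, seed: int = 0,
                          base_n_neighbors: int = 10, **_) -> np.ndarray:
    """Feature bagging over LOF base detectors.

    Each estimator draws a random feature subspace of size uniform in
    [d/2, d], scores it with LOF, and the z-normalized subspace scores are
    averaged.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    lo = max(1, d // 2)
    acc = np.zeros(n)
    for _ in range(n_estimators):
        size = int(rng.integers(lo, d + 1))
        feats = rng.choice(d, size=size, replace=False)
        acc += _zscore(score_lof(X[:, feats], n_neighbors=base_n_neighbors))
    return acc / n_estimators


def _lscp_pool_scores(X, pool_size: int, cache: DistanceCache | None) -> np.ndarray:
    """Fixed ladder of LOF/KNN base detectors; first `pool_size` are used."""
    ladder = [("lof", 5), ("knn", 5), ("lof", 10), ("knn", 10),
              ("lof", 15), ("knn", 15), ("lof", 20), ("knn", 20),
              ("lof", 25), ("knn", 25)]
    n = X.shape[0]
    out = np.empty((pool_size, n))
    for i, (kind, k) in enumerate(ladder[:pool_size]):
        k = min(k, n - 1)
        if kind == "lof":
            out[i] = _zscore(score_lof(X, n_neighbors=k, cache=cache))
        else:
            out[i] = _zscore(score_knn(X, n_neighbors=k, cache=cache))
    return out


def score_lscp(X, pool_size: int = 6, seed: int = 0, local_k: int = 10,
               n_select: int = 2, cache: DistanceCache | None = None) -> np.ndarray:
    """Locally selective combination of a parallel LOF/KNN detector pool.

    The pseudo ground truth is the mean of the z-normalized pool scores.
    For each sample, a local region is formed from its nearest neighbours
    under randomly drawn feature subspaces; the detectors most correlated
    with the pseudo target on that region are selected and their scores
    averaged for the sample.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    cache = cache or DistanceCache(X)
    pool = _lscp_pool_scores(X, pool_size, cache)
    target = pool.mean(axis=0)

    k = min(local_k, n - 1)
    # local region: union of kNN memberships over random half-feature subspaces
    region_sets: list[set[int]] = [set() for _ in range(n)]
    n_iter = 4
    for _ in range(n_iter):
        feats = rng.choice(d, size=max(1, d // 2), replace=False)
        Dsub = squareform(pdist(X[:, feats]))
        np.fill_diagonal(Dsub, np.inf)
        idx = np.argsort(Dsub, axis=1, kind="stable")[:, :k]
        for i in range(n):
            region_sets[i].update(idx[i].tolist())

    scores = np.empty(n)
    n_sel = min(n_select, pool_size)
    for i in range(n):
        region = np.fromiter(region_sets[i], dtype=int)
        if region.size < 3:
            scores[i] = target[i]
            continue
        t = target[region]
        P = pool[:, region]
        tc = t - t.mean()
        Pc = P - P.mean(axis=1, keepdims=True)
        denom = np.sqrt((Pc**2).sum(axis=1) * (tc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corrs = np.where(denom > 0, Pc @ tc / np.where(denom > 0, denom, 1.0), 0.0)
        best = np.argsort(-corrs, kind="stable")[:n_sel]
        scores[i] = pool[best, i].mean()
    return scores


# ------------------------------------------------------------------ flagging

def flags_from_scores(scores: np.ndarray, contamination: float) -> np.ndarray:
    """Boolean flags: score strictly above the (1 - contamination) quantile.

    Degenerate score vectors (all equal) flag nothing.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return np.zeros(0, dtype=bool)
    if np.allclose(scores, scores[0]):
        return np.zeros(scores.shape, dtype=bool)
    thresh = np.percentile(scores, 100.0 * (1.0 - contamination))
    return scores > thresh
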