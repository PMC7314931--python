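"""dFC state identification: k-means over k = 2..12 with silhouette selection.

Rows of the dynamic matrix (one per window index, concatenating all
subjects' edge vectors) are clustered with Euclidean k-means. The candidate
k with the highest mean silhouette is selected (ties toward smaller k), the
full silhouette-vs-k curve is always retained, and states are renumbered by
descending occupancy so labels are stable across seeds.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger("dfcnet")

__all__ = [
    "kmeans",
    "silhouette",
    "select_k",
    "state_mean_dfc",
    "DFCStateClustering",
]


def kmeans(
    matrix: np.ndarray,
    k: int,
    n_restarts: int = 50,
    max_iter: int = 300,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Euclidean k-means: best of ``n_restarts`` random initializations.

    Returns (labels, centroids, inertia); labels are 0-based here (state
    renumbering happens at the estimator level). Deterministic given
    ``rng_seed``.
    """
    matrix = np.asarray(matrix, dtype=float)
    w = matrix.shape[0]
    if k > w:
        raise ValueError(f"k={k} exceeds the number of samples {w}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        tol=1e-6,
        random_state=rng_seed % (2**31),
    ).fit(matrix)
    return km.labels_.astype(int), km.cluster_centers_, float(km.inertia_)


def silhouette(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score with Euclidean distance.

    Per sample, s = (b - a) / max(a, b) where a is the mean intra-cluster
    distance and b the smallest mean distance to another cluster; singleton
    clusters contribute 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(matrix, float), labels, metric="euclidean"))


def select_k(silhouettes: dict[int, float]) -> int:
    """argmax of mean silhouette over candidate k; ties toward smaller k."""
    best_k, best_s = None, -np.inf
    for k in sorted(silhouettes):
        s = silhouettes[k]
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return int(best_k)


def _renumber_by_occupancy(labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Relabel 0-based cluster ids to 1..k by descending window count
    (ties by first occurrence); returns (labels_1based, order) where
    ``order[new-1] = old``."""
    counts = np.bincount(labels, minlength=k)
    first = np.full(k, np.iinfo(np.int64).max)
    for i, lab in enumerate(labels):
        if first[lab] == np.iinfo(np.int64).max:
            first[lab] = i
    order = sorted(range(k), key=lambda c: (-counts[c], first[c]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    return remap[labels], np.asarray(order)


def state_mean_dfc(window_corrs: np.ndarray, labels: np.ndarray, k: int | None = None) -> np.ndarray:
    """Per-subject per-state mean of raw windowed correlations.

    Parameters
    ----------
    window_corrs : (S, W, E) or (W, E) array
        Windowed edge correlations per subject.
    labels : (W,) array of 1-based state labels.
    k : number of states (defaults to max label).

    Returns
    -------
    (S, K, E) array; states with zero occupancy are NaN.
    """
    arr = np.asarray(window_corrs, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != arr.shape[1]:
        raise ValueError("labels length must equal the number of windows")
    if k is None:
        k = int(labels.max())
    s, _, e = arr.shape
    out = np.full((s, k, e), np.nan)
    for state in range(1, k + 1):
        m = labels == state
        if m.any():
            out[:, state - 1, :] = arr[:, m, :].mean(axis=1)
    return out[0] if squeeze else out


class DFCStateClustering(BaseEstimator, ClusterMixin):
    """Silhouette-selected k-means clustering of dynamic-matrix rows.

    Parameters
    ----------
    k_min, k_max : int
        Candidate cluster counts (defaults 2 and 12).
    n_restarts : int, default 50
        Random initializations per k; the best inertia wins.
    max_iter : int, default 300
    random_state : int, default 0
    k : int or None
        Force a specific k and skip selection (the silhouette curve is still
        computed over the candidate range when ``scan_all`` is True).

    Attributes
    ----------
    k_ : selected number of states.
    labels_ : (W,) 1-based state labels, renumbered by descending occupancy.
    centroids_ : (k_, D) cluster centers in renumbered order.
    silhouette_by_k_ : dict k -> mean silhouette.
    occupancy_ : (k_,) window counts per state.
    inertia_ : within-cluster sum of squares at the selected k.
    """

    def __init__(self, k_min: int = 2, k_max: int = 12, n_restarts: int = 50,
                 max_iter: int = 300, random_state: int = 0, k: int | None = None,
                 scan_all: bool = False):
        self.k_min = k_min
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state
        self.k = k
        self.scan_all = scan_all

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D windows x features matrix")
        sil: dict[int, float] = {}
        runs: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
        if self.k is None or self.scan_all:
            k_hi = min(self.k_max, X.shape[0] - 1)
            for k in range(self.k_min, k_hi + 1):
                labels, centroids, inertia = kmeans(
                    X, k, self.n_restarts, self.max_iter, self.random_state
                )
                runs[k] = (labels, centroids, inertia)
                sil[k] = silhouette(X, labels) if len(np.unique(labels)) > 1 else -1.0
        if self.k is not None:
            k_sel = int(self.k)
            if k_sel not in runs:
                runs[k_sel] = kmeans(X, k_sel, self.n_restarts, self.max_iter, self.random_state)
        else:
            k_sel = select_k(sil)
        labels0, centroids, inertia = runs[k_sel]
        labels, order = _renumber_by_occupancy(labels0, k_sel)
        self.k_ = k_sel
        self.labels_ = labels
        self.centroids_ = centroids[order]
        self.silhouette_by_k_ = sil
        self.occupancy_ = np.bincount(labels, minlength=k_sel + 1)[1:]
        self.inertia_ = inertia
        logger.info(
            "selected k=%d (silhouette %s)", k_sel,
            {kk: round(vv, 3) for kk, vv in sil.items()},
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
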