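"""K-means clustering of the genes x samples anomaly-score matrix.

Groups panel genes by their per-sample anomaly profile.  Lloyd iterations
with k-means++ seeding, best of ``n_init`` restarts by inertia.  Distances
are plain Euclidean on the raw scores — anomaly scores already share the
(0, 1] scale by construction, so rows are not rescaled.

Determinism: the restart initialisations are drawn against the canonical
(sorted-by-symbol) row order, so the result is invariant to the order in
which genes appear in the matrix.  An empty cluster arising during
iteration is re-seeded at the point currently farthest from its assigned
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["ClusteringError", "ClusteringResult", "kmeans", "choose_k", "mean_silhouette"]


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class ClusteringResult:
    """Cluster assignments (1-based ids), centroids and diagnostics."""

    assignments: dict[str, int]
    centroids: np.ndarray  # k x n_samples
    inertia: float
    k: int
    seed: int
    inertia_trace: tuple[float, ...]  # per-Lloyd-iteration inertia, best restart


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        names = [str(s) for s in matrix.index]
    else:
        X = np.asarray(matrix, dtype=float)
        names = [str(i) for i in range(X.shape[0])]
    if X.ndim != 2:
        raise ClusteringError("matrix must be 2-D (rows = genes)")
    if not np.isfinite(X).all():
        raise ClusteringError("matrix must be finite")
    return X, names


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0.0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    k = centers.shape[0]
    trace: list[float] = []
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        dist2 = cdist(X, centers, metric="sqeuclidean")
        labels = dist2.argmin(axis=1)
        # empty-cluster rule: re-seed at the point farthest from its centroid
        for j in range(k):
            if not (labels == j).any():
                far = dist2[np.arange(X.shape[0]), labels].argmax()
                labels[far] = j
        new_centers = np.stack([X[labels == j].mean(axis=0) for j in range(k)])
        inertia = float(((X - new_centers[labels]) ** 2).sum())
        trace.append(inertia)
        shift = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
        centers = new_centers
        if shift < tol:
            break
    return labels, centers, trace[-1], trace


def kmeans(
    matrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusteringResult:
    """Cluster matrix rows into k groups (best of ``n_init`` seeded restarts).

    ``matrix`` may be a DataFrame (index = gene symbols) or an ndarray.
    """
    X, names = _as_matrix(matrix)
    n = X.shape[0]
    if k < 1:
        raise ClusteringError("k must be >= 1")
    if k > n:
        raise ClusteringError(f"k={k} exceeds number of rows ({n})")
    # canonical row order so the result never depends on input gene order
    order = np.argsort(np.asarray(names))
    Xc = X[order]
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_init):
        centers0 = _kmeanspp_init(Xc, k, rng)
        labels, centers, inertia, trace = _lloyd(Xc, centers0, max_iter, tol)
        if best is None or inertia < best[0] - 1e-12:
            best = (inertia, labels, centers, trace)
    inertia, labels, centers, trace = best
    assignments = {
        names[row]: int(labels[i]) + 1 for i, row in enumerate(order)
    }
    return ClusteringResult(
        assignments=assignments,
        centroids=centers,
        inertia=inertia,
        k=k,
        seed=seed,
        inertia_trace=tuple(trace),
    )


def mean_silhouette(matrix, assignments: dict[str, int]) -> float:
    """Mean Euclidean silhouette width of a clustering (singletons score 0)."""
    X, names = _as_matrix(matrix)
    labels = np.array([assignments[n] for n in names])
    D = cdist(X, X)
    svals = np.zeros(len(names))
    for i in range(len(names)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = np.inf
        for lab in np.unique(labels):
            if lab == labels[i]:
                continue
            b = min(b, D[i, labels == lab].mean())
        denom = max(a, b)
        svals[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(svals.mean())


def choose_k(matrix, k_range=range(2, 9), seed: int = 0) -> int:
    """Pick k by maximal mean silhouette over ``k_range`` (ties -> smallest k)."""
    X, _ = _as_matrix(matrix)
    n = X.shape[0]
    if n < 3:
        raise ClusteringError("need at least 3 rows to select k")
    candidates = [k for k in k_range if 2 <= k <= n - 1]
    if not candidates:
        raise ClusteringError(f"no admissible k in range for {n} rows")
    best_k, best_s = None, -np.inf
    for k in sorted(candidates):
        res = kmeans(matrix, k, seed=seed)
        s = mean_silhouette(matrix, res.assignments)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k
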