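"""Isolation Forest, implemented from first principles.

An isolation tree recursively partitions a subsample with axis-parallel
random splits (dimension uniform among non-constant dimensions, split point
uniform in the subset's range).  Points that are easier to isolate — i.e.
reach small external nodes after few splits — are anomalous.  The anomaly
score of a point x is

    s(x) = 2 ** (-E[h(x)] / c(psi))

where ``E[h(x)]`` is the mean path length over trees (edges traversed plus
``c(size)`` for the external node reached), ``psi`` the subsample size, and
``c(n)`` the average unsuccessful-search path length of a binary search
tree on n points.  Scores lie in (0, 1]; a point with the average path
length of the training subsample scores exactly 0.5.

Degenerate inputs are well defined: an all-constant subsample terminates
immediately as a single external node, so every point traverses zero edges
and scores 0.5.

The ensemble is deterministic given (data, params): a single seeded
generator is consumed tree-index major (subsample draw, then that tree's
splits, then the next tree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EULER_GAMMA",
    "ForestParams",
    "IsolationForest",
    "harmonic_c",
    "fit_forest",
    "path_length",
    "anomaly_scores",
]

EULER_GAMMA = 0.5772156649

# Tree representation (nested tuples, cheap to build and traverse):
#   external node: (size,)
#   internal node: (split_dim, split_value, left, right)


def harmonic_c(n: int) -> float:
    """Path-length normalizer c(n).

    Uses the harmonic-number approximation ``H(i) = ln(i) + gamma``
    uniformly (including small i):  ``c(n) = 2 H(n-1) - 2 (n-1)/n`` for
    n >= 2 and 0 for n <= 1.
    """
    if n < 0:
        raise ValueError(f"negative node size: {n}")
    if n <= 1:
        return 0.0
    return 2.0 * (math.log(n - 1) + EULER_GAMMA) - 2.0 * (n - 1) / n


@dataclass(frozen=True)
class ForestParams:
    """Ensemble parameters.

    n_trees
        Number of isolation trees (default 100).
    subsample
        Training points per tree, psi; ``None`` means ``min(256, n)``.
        Clamped to ``[2, n]`` at fit time.
    max_depth
        Depth cap; ``None`` means ``ceil(log2(psi))``.
    seed
        Seed for the shared generator.
    """

    n_trees: int = 100
    subsample: int | None = None
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.subsample is not None and self.subsample < 1:
            raise ValueError("subsample must be positive")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be positive")


def _build_tree(
    X: np.ndarray, idx: np.ndarray, depth: int, max_depth: int, rng: np.random.Generator
) -> tuple:
    n = idx.size
    if n <= 1 or depth >= max_depth:
        return (n,)
    sub = X[idx]
    mins = sub.min(axis=0)
    maxs = sub.max(axis=0)
    nonconst = np.flatnonzero(maxs > mins)
    if nonconst.size == 0:  # constant subset: isolate no further
        return (n,)
    dim = int(nonconst[rng.integers(nonconst.size)])
    split = float(rng.uniform(mins[dim], maxs[dim]))
    mask = X[idx, dim] < split
    left = _build_tree(X, idx[mask], depth + 1, max_depth, rng)
    right = _build_tree(X, idx[~mask], depth + 1, max_depth, rng)
    return (dim, split, left, right)


def _tree_path_length(tree: tuple, x: np.ndarray) -> float:
    depth = 0
    node = tree
    while len(node) == 4:
        dim, split, left, right = node
        node = left if x[dim] < split else right
        depth += 1
    return depth + harmonic_c(node[0])


class IsolationForest:
    """A fitted ensemble of isolation trees.

    Use :meth:`fit` (or the module-level :func:`fit_forest`) on an
    ``n x d`` matrix, then :meth:`score` to obtain anomaly scores.
    """

    def __init__(self, params: ForestParams | None = None) -> None:
        self.params = params or ForestParams()
        self.trees_: list[tuple] | None = None
        self.psi_: int | None = None
        self.n_features_: int | None = None

    def fit(self, data) -> "IsolationForest":
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise ValueError("training data must be an n x d matrix")
        n, d = X.shape
        if n < 2:
            raise ValueError(f"need at least 2 training points, got {n}")
        if not np.isfinite(X).all():
            raise ValueError("training data must be finite")
        p = self.params
        psi = p.subsample if p.subsample is not None else min(256, n)
        psi = max(2, min(psi, n))  # clamp; psi=1 would degenerate c(psi)=0
        max_depth = p.max_depth if p.max_depth is not None else max(1, math.ceil(math.log2(psi)))
        rng = np.random.default_rng(p.seed)
        trees = []
        for _ in range(p.n_trees):
            idx = rng.choice(n, size=psi, replace=False)
            trees.append(_build_tree(X, idx, 0, max_depth, rng))
        self.trees_ = trees
        self.psi_ = psi
        self.n_features_ = d
        return self

    def _check_points(self, points) -> np.ndarray:
        if self.trees_ is None:
            raise ValueError("forest is not fitted")
        P = np.asarray(points, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
        if P.shape[1] != self.n_features_:
            raise ValueError(
                f"dimension mismatch: forest has {self.n_features_} "
                f"feature(s), points have {P.shape[1]}"
            )
        return P

    def path_length(self, points) -> np.ndarray:
        """Mean path length E[h(x)] over trees, per point."""
        P = self._check_points(points)
        out = np.empty(P.shape[0])
        for i, x in enumerate(P):
            out[i] = sum(_tree_path_length(t, x) for t in self.trees_) / len(self.trees_)
        return out

    def score(self, points) -> np.ndarray:
        """Anomaly scores ``2**(-E[h]/c(psi))`` in (0, 1]; higher = more isolated."""
        eh = self.path_length(points)
        return 2.0 ** (-eh / harmonic_c(self.psi_))


def fit_forest(data, params: ForestParams | None = None) -> IsolationForest:
    return IsolationForest(params).fit(data)


def path_length(forest: IsolationForest, x) -> float | np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim <= 1 and forest.n_features_ is not None and x.size == forest.n_features_:
        return float(forest.path_length(x.reshape(1, -1))[0])
    return forest.path_length(x)


def anomaly_scores(forest: IsolationForest, points) -> np.ndarray:
    return forest.score(points)
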