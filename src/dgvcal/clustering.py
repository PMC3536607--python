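"""Cross-validation grouping by K-means on relationship profiles.

Validation folds built from random splits of a pedigreed population leak
family information: close relatives of every validation animal sit in
training.  Instead, animals are partitioned by K-means so that pedigree
relatedness is high within groups and low between groups.  Each animal is
represented by its row of the difference matrix D = max(A) - A (zero
diagonal), i.e. by its profile of dissimilarities to every other animal,
and rows are clustered as Euclidean coordinates.

The K-means itself is Hartigan-Wong style: after a Lloyd pass, repeated
optimal-transfer sweeps move single points whenever the move lowers the
within-cluster sum of squares using the exact n/(n-1), n/(n+1) corrected
costs, so the returned partition is 1-swap optimal.  Multiple seeded
restarts are taken and the best objective wins (first found on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit

from .pedigree import AmaxReport, RelationshipMatrix, amax_report

__all__ = [
    "ClusterAssignment",
    "difference_matrix",
    "kmeans_groups",
    "clustering_quality",
]


@dataclass
class ClusterAssignment:
    """Group labels (1..k) for a list of animals."""

    ids: np.ndarray
    labels: np.ndarray
    k: int
    objective: float = np.nan

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels length mismatch")
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if len(present) < self.k:
            raise ValueError("empty group in assignment")

    def as_mapping(self) -> dict:
        return dict(zip(self.ids, self.labels))

    @property
    def group_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()

    def members(self, group: int) -> np.ndarray:
        return self.ids[self.labels == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.ids, "group": self.labels})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ClusterAssignment":
        frame = pd.read_csv(path, sep="\t")
        labels = frame["group"].to_numpy()
        return cls(ids=frame["animal"].to_numpy(), labels=labels, k=int(labels.max()))


def difference_matrix(A: RelationshipMatrix) -> np.ndarray:
    """D with d_ij = max(A) - a_ij off-diagonal, zero diagonal.

    Using the matrix maximum (not 1) keeps dissimilarities non-negative for
    inbred pedigrees whose diagonal exceeds 1.
    """
    V = A.values
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValueError("relationship matrix must be symmetric")
    D = V.max() - V
    np.fill_diagonal(D, 0.0)
    return D


@njit(cache=True)
def _lloyd(X, centers, labels):
    n, d = X.shape
    k = centers.shape[0]
    changed = 0
    for i in range(n):
        best = -1
        bestd = np.inf
        for c in range(k):
            dist = 0.0
            for t in range(d):
                diff = X[i, t] - centers[c, t]
                dist += diff * diff
            if dist < bestd:
                bestd = dist
                best = c
        if labels[i] != best:
            labels[i] = best
            changed += 1
    return changed


@njit(cache=True)
def _recompute_centers(X, labels, k):
    n, d = X.shape
    centers = np.zeros((k, d))
    counts = np.zeros(k, dtype=np.int64)
    for i in range(n):
        counts[labels[i]] += 1
        for t in range(d):
            centers[labels[i], t] += X[i, t]
    for c in range(k):
        if counts[c] > 0:
            for t in range(d):
                centers[c, t] /= counts[c]
    return centers, counts


@njit(cache=True)
def _hartigan_sweep(X, labels, centers, counts):
    """One optimal-transfer pass; returns number of moves."""
    n, d = X.shape
    k = centers.shape[0]
    moves = 0
    for i in range(n):
        c = labels[i]
        if counts[c] <= 1:
            continue
        # removal cost from own cluster
        dc = 0.0
        for t in range(d):
            diff = X[i, t] - centers[c, t]
            dc += diff * diff
        removal = counts[c] / (counts[c] - 1.0) * dc
        best = c
        best_cost = removal
        for c2 in range(k):
            if c2 == c:
                continue
            dist = 0.0
            for t in range(d):
                diff = X[i, t] - centers[c2, t]
                dist += diff * diff
            cost = counts[c2] / (counts[c2] + 1.0) * dist
            if cost < best_cost - 1e-12:
                best_cost = cost
                best = c2
        if best != c:
            for t in range(d):
                centers[c, t] = (centers[c, t] * counts[c] - X[i, t]) / (counts[c] - 1)
                centers[best, t] = (centers[best, t] * counts[best] + X[i, t]) / (counts[best] + 1)
            counts[c] -= 1
            counts[best] += 1
            labels[i] = best
            moves += 1
    return moves


@njit(cache=True)
def _sse(X, labels, centers):
    n, d = X.shape
    total = 0.0
    for i in range(n):
        for t in range(d):
            diff = X[i, t] - centers[labels[i], t]
            total += diff * diff
    return total


def _single_run(X: np.ndarray, k: int, init_idx: np.ndarray, rng: np.random.Generator):
    n = X.shape[0]
    centers = X[init_idx].copy()
    labels = np.full(n, -1, dtype=np.int64)
    for _ in range(100):
        changed = _lloyd(X, centers, labels)
        centers, counts = _recompute_centers(X, labels, k)
        # repair empty clusters with the point farthest from its center
        while (counts == 0).any():
            empty = int(np.flatnonzero(counts == 0)[0])
            dists = ((X - centers[labels]) ** 2).sum(axis=1)
            dists[counts[labels] <= 1] = -np.inf
            far = int(np.argmax(dists))
            counts[labels[far]] -= 1
            labels[far] = empty
            counts[empty] += 1
            centers, counts = _recompute_centers(X, labels, k)
        if changed == 0:
            break
    for _ in range(200):
        if _hartigan_sweep(X, labels, centers, counts) == 0:
            break
    return labels, _sse(X, labels, centers)


def kmeans_groups(
    D: np.ndarray,
    k: int = 5,
    restarts: int = 50,
    seed: int = 0,
    ids: np.ndarray | None = None,
) -> ClusterAssignment:
    """Hartigan-Wong K-means over the rows of a dissimilarity matrix.

    Rows of ``D`` are treated as Euclidean coordinate vectors.  ``restarts``
    random initializations (distinct rows as initial centers) are run and
    the lowest within-cluster sum of squares kept.  Deterministic under
    ``seed``.
    """
    D = np.ascontiguousarray(D, dtype=np.float64)
    n = D.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot form k={k} groups from {n} animals")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 0x6B6D])))
    best_labels = None
    best_obj = np.inf
    for _ in range(restarts):
        init_idx = rng.choice(n, size=k, replace=False)
        labels, obj = _single_run(D, k, init_idx, rng)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_labels = labels
    if ids is None:
        ids = np.arange(n)
    return ClusterAssignment(ids=np.asarray(ids), labels=best_labels + 1, k=k, objective=float(best_obj))


def clustering_quality(assignment: ClusterAssignment, A: RelationshipMatrix) -> AmaxReport:
    """Table-3-style a_max within/between diagnostics for a clustering."""
    return amax_report(A, assignment)
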