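"""Sequential dominant-set partitioning of FCGs via replicator dynamics.

The dominant set of a weighted graph W is the support of the simplex
vector y maximizing the set-compactness F(y) = yᵀWy over the standard
simplex Δ = {y : y_i ≥ 0, Σ y_i = 1}.  The replicator recursion

    y_i ← y_i (W y)_i / (yᵀ W y)

preserves the simplex and, for symmetric non-negative W, never
decreases F.  Components outside the dominant set decay geometrically;
the surviving support is the most cohesive group of vertices.

A full partition is obtained sequentially: extract the dominant set,
remove its vertices, repeat on the rest; residual nodes with no
remaining weight become singletons.  Clusters are ranked by cohesive
index (CI) — the mean intracluster strength (within-cluster weighted
degree) of their members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .connectivity import FCGSeries

__all__ = [
    "ZeroCohesionError",
    "Partition",
    "ClusterTimeline",
    "replicator_step",
    "dominant_set",
    "partition",
    "cohesive_index",
    "dominant_timeline",
    "top_k_edges",
    "DominantSetClustering",
]


class ZeroCohesionError(ValueError):
    """Raised when yᵀWy = 0, e.g. on an edgeless graph: no dominant set exists."""


@dataclass
class Partition:
    """Disjoint exhaustive labeling of nodes into sequentially extracted clusters.

    ``labels[i]`` is 1 for the first-extracted (most prominent) cluster,
    2 for the second, and so on.  ``ci[c]`` is the cohesive index of
    cluster c+1; ``support_weights[c]`` the replicator weights of its
    members (None for singleton residue clusters).
    """

    labels: np.ndarray
    ci: np.ndarray
    support_weights: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def dominant_label(self) -> int:
        """Label of the cluster with the highest cohesive index (ties → lowest label)."""
        return int(np.argmax(self.ci)) + 1


@dataclass
class ClusterTimeline:
    """Dominant-cluster membership raster [n_roi × n_latencies]."""

    membership: np.ndarray  # bool
    latencies_ms: np.ndarray


def _check_w(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    return W


def replicator_step(y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One replicator-dynamics update; the output stays on the simplex."""
    W = _check_w(W)
    y = np.asarray(y, dtype=float)
    wy = W @ y
    f = y @ wy
    if f <= 0:
        raise ZeroCohesionError("y'Wy = 0: graph carries no cohesion under y")
    return y * wy / f


def dominant_set(
    W: np.ndarray,
    init: np.ndarray | None = None,
    max_iter: int = 10_000,
    tol: float = 1e-10,
    support_eps: float = 1e-5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Dominant set of W: (support indices, simplex weights y, converged).

    Iterates the replicator recursion from the simplex barycenter (or a
    seeded random strictly positive point if ``rng`` is given, or a
    caller-supplied ``init``) until the L1 change drops below ``tol`` or
    ``max_iter`` is reached; the support is {i : y_i > support_eps}.
    """
    W = _check_w(W)
    n = W.shape[0]
    if init is not None:
        y = np.asarray(init, dtype=float)
        if y.shape != (n,) or np.any(y < 0) or not np.isclose(y.sum(), 1.0):
            raise ValueError("init must be a simplex point of length N")
    elif rng is not None:
        y = rng.uniform(0.1, 1.0, size=n)
        y /= y.sum()
    else:
        y = np.full(n, 1.0 / n)

    converged = False
    for _ in range(max_iter):
        y_next = replicator_step(y, W)
        if np.abs(y_next - y).sum() < tol:
            y = y_next
            converged = True
            break
        y = y_next
    if not converged:
        warnings.warn(
            f"replicator dynamics did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    support = np.flatnonzero(y > support_eps)
    return support, y, converged


def cohesive_index(W: np.ndarray, cluster: np.ndarray) -> float:
    """Mean intracluster strength: average within-cluster weighted degree."""
    cluster = np.asarray(cluster, dtype=int)
    if cluster.size == 0:
        raise ValueError("cluster must be non-empty")
    W = _check_w(W)
    sub = W[np.ix_(cluster, cluster)]
    return float(sub.sum(axis=1).mean())


def partition(
    W: np.ndarray,
    max_iter: int = 10_000,
    tol: float = 1e-10,
    support_eps: float = 1e-5,
    rng: np.random.Generator | None = None,
) -> Partition:
    """Sequential dominant-set partition of all nodes.

    Repeats: find the dominant set among remaining nodes, label it,
    remove it.  When the remaining subgraph has no weight left, each
    remaining node becomes its own singleton cluster (in index order).
    """
    W = _check_w(W)
    n = W.shape[0]
    labels = np.zeros(n, dtype=int)
    supports: list = []
    remaining = np.arange(n)
    label = 1
    while remaining.size:
        sub = W[np.ix_(remaining, remaining)]
        if sub.sum() <= 0:
            for node in remaining:
                labels[node] = label
                supports.append(None)
                label += 1
            break
        if remaining.size == 1:
            labels[remaining[0]] = label
            supports.append(None)
            break
        support, y, _ = dominant_set(
            sub, max_iter=max_iter, tol=tol, support_eps=support_eps, rng=rng
        )
        if support.size == 0:  # pathological; guarantee progress
            support = np.array([int(np.argmax(y))])
        nodes = remaining[support]
        labels[nodes] = label
        supports.append(y[support])
        remaining = np.setdiff1d(remaining, nodes)
        label += 1

    n_clusters = int(labels.max())
    ci = np.array(
        [cohesive_index(W, np.flatnonzero(labels == c + 1)) for c in range(n_clusters)]
    )
    return Partition(labels=labels, ci=ci, support_weights=supports)


def dominant_timeline(fcgs: FCGSeries, **kwargs) -> ClusterTimeline:
    """Membership raster of the highest-CI cluster at each latency.

    Latencies whose trimmed FCG is empty yield an all-false column.
    """
    n_lat = fcgs.n_latencies
    membership = np.zeros((fcgs.n_roi, n_lat), dtype=bool)
    for t in range(n_lat):
        W = fcgs.adjacency[t]
        if W.sum() <= 0:
            continue
        part = partition(W, **kwargs)
        membership[part.members(part.dominant_label()), t] = True
    return ClusterTimeline(membership=membership, latencies_ms=fcgs.latencies_ms)


def top_k_edges(
    W: np.ndarray,
    mask: np.ndarray | None = None,
    k_percent: float = 5.0,
) -> list[tuple[int, int, float]]:
    """Strongest significant edges: the ⌊k% · N(N−1)/2⌋ largest.

    Among upper-triangle entries where ``mask`` is true, keeps the
    ⌊k_percent/100 · N(N−1)/2⌋ largest weights (fewer if fewer are
    significant).  Ties break deterministically by pair index order.
    Returns a list of (u, v, weight) with u < v.
    """
    W = _check_w(W)
    if not (0 < k_percent <= 100):
        raise ValueError("k_percent must be in (0, 100]")
    n = W.shape[0]
    iu, iv = np.triu_indices(n, k=1)
    weights = W[iu, iv]
    if mask is None:
        keep = np.ones(iu.size, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        keep = mask[iu, iv]
    n_keep = int(np.floor(k_percent / 100.0 * iu.size))
    cand = np.flatnonzero(keep)
    # stable sort on descending weight: ties retain pair-index order
    order = cand[np.argsort(-weights[cand], kind="stable")][:n_keep]
    return [(int(iu[i]), int(iv[i]), float(weights[i])) for i in order]


class DominantSetClustering(BaseEstimator, ClusterMixin):
    """Scikit-learn-style wrapper around sequential dominant-set partitioning.

    Expects a precomputed symmetric non-negative affinity matrix, like
    ``sklearn.cluster.SpectralClustering(affinity="precomputed")``.
    The number of clusters is not fixed in advance; it emerges from the
    sequential extraction.

    Attributes
    ----------
    labels_ : ndarray of shape (n_nodes,)
        0-based cluster labels ordered by extraction (0 = first
        dominant set).
    cohesion_ : ndarray of shape (n_clusters_,)
        Cohesive index of each cluster.
    n_clusters_ : int
    """

    def __init__(
        self,
        max_iter: int = 10_000,
        tol: float = 1e-10,
        support_eps: float = 1e-5,
        random_state: int | None = None,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.support_eps = support_eps
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _check_w(np.asarray(X, dtype=float))
        if not np.allclose(X, X.T):
            raise ValueError("affinity matrix must be symmetric")
        rng = (
            np.random.default_rng(self.random_state)
            if self.random_state is not None
            else None
        )
        part = partition(
            X,
            max_iter=self.max_iter,
            tol=self.tol,
            support_eps=self.support_eps,
            rng=rng,
        )
        self.partition_ = part
        self.labels_ = part.labels - 1
        self.cohesion_ = part.ci
        self.n_clusters_ = part.n_clusters
        return self
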