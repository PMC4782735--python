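"""Non-Euclidean Relational Clustering (NERC).

NERC partitions a dissimilarity matrix into k groups without building a
tree and without embedding the data in a Euclidean space. One restart runs
three steps:

1. *Initialization* — k samples are drawn at random, each seeding its own
   cluster.
2. *Allocation* — repeatedly, the globally smallest dissimilarity between
   any unassigned and any assigned sample is found and the unassigned
   sample joins that neighbour's cluster (a single-linkage-style greedy
   growth) until everything is assigned. If any group ends up with a single
   member the restart re-seeds and tries again.
3. *Reallocation* — each sample's average dissimilarity to every cluster is
   computed (excluding itself from its own cluster's average). While some
   sample would be better off elsewhere, one such sample is picked uniformly
   at random and moved to its best cluster; averages are recomputed after
   every single move. A cap on the number of moves guards against cycling
   when no fully satisfied assignment exists.

The procedure reaches a local optimum of the mean within-group
dissimilarity; it is therefore repeated over many independent restarts and
the partition with the smallest pooled mean within-group distance wins.

The estimator :class:`NERC` follows the scikit-learn clusterer protocol and
treats its input as a precomputed dissimilarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "NERC",
    "NERCResult",
    "nerc",
    "nerc_initialize",
    "nerc_allocate",
    "nerc_reallocate",
    "mean_within_group_distance",
]

#: moves are taken only on strictly smaller average distance, beyond this
_IMPROVE_TOL = 1e-12
#: consecutive re-seeding attempts allowed when allocation yields singletons
_MAX_ALLOC_RETRIES = 100

UNASSIGNED = -1


@dataclass
class NERCResult:
    """Outcome of a NERC run (one restart or the best of many).

    converged=True guarantees the exact fixed point: no sample has a
    strictly smaller average distance to any other cluster than to its own.
    """

    labels: np.ndarray
    n_clusters: int
    mean_within_distance: float
    restarts_run: int
    reassignments_used: int
    converged: bool


def _as_square(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return np.asarray(d.data, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity input must be a square matrix")
    if np.max(np.abs(d - d.T)) > 1e-9 or np.max(np.abs(np.diag(d))) > 1e-9:
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    return d


def _check_k(k: int, n: int) -> None:
    if not (2 <= k <= n // 2):
        raise ValueError(
            f"number of clusters must be an integer >= 2 and no greater than "
            f"half the number of samples (got k={k} for n={n}; the lower bound "
            f"avoids a single all-inclusive group, the upper bound avoids "
            f"clusters of one)"
        )


def nerc_initialize(d, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seed k clusters with k distinct random samples; everyone else unassigned."""
    d = _as_square(d)
    n = d.shape[0]
    _check_k(k, n)
    labels = np.full(n, UNASSIGNED, dtype=np.int64)
    seeds = rng.choice(n, size=k, replace=False)
    labels[seeds] = np.arange(k)
    return labels


def nerc_allocate(d, labels: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Grow the seeded clusters greedily until every sample is assigned.

    At each step the smallest dissimilarity between any unassigned and any
    assigned sample decides the join; ties break on the lowest
    (unassigned index, assigned index) pair so the step is deterministic.
    The caller is responsible for re-seeding when a finished allocation
    contains a singleton group.
    """
    d = _as_square(d)
    labels = np.asarray(labels, dtype=np.int64).copy()
    n = d.shape[0]
    assigned = labels != UNASSIGNED
    k = labels[assigned].max() + 1 if assigned.any() else 0
    if np.unique(labels[assigned]).size != k:
        raise ValueError("partial partition must contain exactly one seed per cluster")

    # Prim-style: for each unassigned sample track its nearest assigned
    # neighbour (lowest index on distance ties).
    nearest_dist = np.full(n, np.inf)
    nearest_to = np.full(n, -1, dtype=np.int64)
    for j in np.flatnonzero(assigned):
        better = ~assigned & (d[:, j] < nearest_dist)
        nearest_dist[better] = d[better, j]
        nearest_to[better] = j
    while not assigned.all():
        masked = np.where(assigned, np.inf, nearest_dist)
        u = int(np.argmin(masked))
        labels[u] = labels[nearest_to[u]]
        assigned[u] = True
        du = d[:, u]
        closer = ~assigned & (
            (du < nearest_dist) | ((du == nearest_dist) & (u < nearest_to))
        )
        nearest_dist[closer] = du[closer]
        nearest_to[closer] = u
    return labels


def _cluster_sums(d: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    onehot = np.zeros((d.shape[0], k))
    onehot[np.arange(d.shape[0]), labels] = 1.0
    return d @ onehot  # [s, c] = total distance from s to members of c


def mean_within_group_distance(d, labels: np.ndarray) -> float:
    """Pooled mean dissimilarity over all within-cluster pairs.

    All within-cluster pairs across all clusters contribute equally (the
    mean is pooled, not a mean of per-cluster means). Every cluster must
    have at least two members, otherwise it contributes no pairs and the
    criterion is undefined.
    """
    d = _as_square(d)
    labels = np.asarray(labels, dtype=np.int64)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every cluster needs >= 2 members (singletons have no within pairs)")
    same = labels[:, None] == labels[None, :]
    total = d[same].sum() / 2.0
    n_pairs = (counts * (counts - 1) // 2).sum()
    return float(total / n_pairs)


def nerc_reallocate(
    d,
    labels: np.ndarray,
    max_reassignments: int = 1000,
    rng: np.random.Generator | None = None,
) -> NERCResult:
    """Iteratively move misplaced samples to their closest cluster, one at a time.

    A sample is misplaced when its average distance to some other cluster is
    strictly smaller than to its own (own-cluster average excludes the
    sample itself). One misplaced sample is chosen uniformly at random and
    moved per iteration; averages are refreshed after every move. Moves that
    would shrink a cluster below two members are skipped when choosing.
    ``max_reassignments`` counts successful moves; hitting it (or being left
    with only guard-blocked misplaced samples) yields ``converged=False``.
    """
    d = _as_square(d)
    if rng is None:
        rng = np.random.default_rng()
    labels = np.asarray(labels, dtype=np.int64).copy()
    n = d.shape[0]
    k = int(labels.max()) + 1
    uniq, counts_ = np.unique(labels, return_counts=True)
    if uniq.size != k or (uniq != np.arange(k)).any():
        raise ValueError("labels must use every cluster id 0..k-1")
    counts = np.zeros(k, dtype=np.int64)
    counts[uniq] = counts_
    if counts.min() < 2:
        raise ValueError("reallocation requires every cluster to start with >= 2 members")
    sums = _cluster_sums(d, labels, k)

    idx = np.arange(n)
    moves = 0
    while True:
        own = sums[idx, labels] / (counts[labels] - 1)
        avg = sums / counts
        avg[idx, labels] = np.inf
        best_other = avg.min(axis=1)
        target = avg.argmin(axis=1)
        misplaced = best_other < own - _IMPROVE_TOL
        if not misplaced.any():
            converged = True
            break
        movable = misplaced & (counts[labels] > 2)
        if not movable.any() or moves >= max_reassignments:
            converged = False
            break
        s = int(rng.choice(np.flatnonzero(movable)))
        old, new = labels[s], int(target[s])
        sums[:, old] -= d[:, s]
        sums[:, new] += d[:, s]
        counts[old] -= 1
        counts[new] += 1
        labels[s] = new
        moves += 1

    return NERCResult(
        labels=labels,
        n_clusters=k,
        mean_within_distance=mean_within_group_distance(d, labels),
        restarts_run=1,
        reassignments_used=moves,
        converged=converged,
    )


def _one_restart(
    d: np.ndarray, k: int, max_reassignments: int, rng: np.random.Generator
) -> NERCResult:
    for _ in range(_MAX_ALLOC_RETRIES):
        labels = nerc_allocate(d, nerc_initialize(d, k, rng), rng)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() >= 2:
            return nerc_reallocate(d, labels, max_reassignments, rng)
    raise RuntimeError(
        f"allocation produced a singleton group in {_MAX_ALLOC_RETRIES} "
        f"consecutive attempts; the data may not support k={k} clusters"
    )


def nerc(
    d,
    n_clusters: int = 2,
    n_restarts: int = 1000,
    max_reassignments: int = 1000,
    seed: int | None = None,
) -> NERCResult:
    """Run NERC over many independent restarts and keep the best partition.

    Parameters mirror the reference signature: the number of clusters k
    (2 <= k <= n/2), the number of restarts (the method is heuristic and
    finds a local optimum, so many restarts are recommended; default 1000)
    and the per-restart reassignment cap. The winner is the restart with
    the smallest pooled mean within-group distance; ties keep the first
    encountered. Deterministic given ``seed``.
    """
    d = _as_square(d)
    _check_k(n_clusters, d.shape[0])
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    best: NERCResult | None = None
    for stream in streams:
        result = _one_restart(d, n_clusters, max_reassignments, np.random.default_rng(stream))
        if best is None or result.mean_within_distance < best.mean_within_distance:
            best = result
    best.restarts_run = n_restarts
    return best


class NERC(ClusterMixin, BaseEstimator):
    """Non-Euclidean Relational Clustering on a precomputed dissimilarity matrix.

    Parameters
    ----------
    n_clusters : int, default=2
        Number of groups k; must satisfy 2 <= k <= n_samples / 2.
    n_restarts : int, default=1000
        Independent initialize/allocate/reallocate cycles; the best restart
        by mean within-group distance is returned.
    max_reassignments : int, default=1000
        Cap on optimizer moves within one restart.
    random_state : int or None, default=None
        Seed for all restarts; identical seeds give identical results.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster id (0..k-1) per sample.
    mean_within_distance_ : float
        Pooled mean dissimilarity over within-cluster pairs (the selection
        criterion).
    n_reassignments_ : int
        Optimizer moves used by the winning restart.
    converged_ : bool
        True when the winning restart reached the exact fixed point.

    Examples
    --------
    >>> import numpy as np
    >>> d = np.array([[0, .1, .9, .9], [.1, 0, .9, .9],
    ...               [.9, .9, 0, .1], [.9, .9, .1, 0]])
    >>> NERC(n_clusters=2, n_restarts=20, random_state=0).fit_predict(d)
    array([...])
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_restarts: int = 1000,
        max_reassignments: int = 1000,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_reassignments = max_reassignments
        self.random_state = random_state

    def fit(self, X, y=None):
        """Cluster a precomputed square dissimilarity matrix (or skbio DistanceMatrix)."""
        result = nerc(
            X,
            n_clusters=self.n_clusters,
            n_restarts=self.n_restarts,
            max_reassignments=self.max_reassignments,
            seed=self.random_state,
        )
        self.labels_ = result.labels
        self.mean_within_distance_ = result.mean_within_distance
        self.n_reassignments_ = result.reassignments_used
        self.converged_ = result.converged
        self.result_ = result
        return self
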