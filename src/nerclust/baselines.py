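"""Comparison clusterings: linkage trees cut to k groups, and k-means on a
principal-coordinates embedding of a dissimilarity matrix.

These are the conventional alternatives NERC is benchmarked against:

* single, complete and UPGMA (average) agglomerative clustering of the
  dissimilarity matrix, converted to discrete clusters by cutting the tree
  so exactly k groups remain;
* k-means on a distance-based ordination. An unconstrained distance-based
  RDA is mathematically principal coordinates analysis (PCoA), so the
  embedding is computed directly: double-centre -(1/2) d^2, eigendecompose,
  keep the positive-eigenvalue axes scaled by sqrt(eigenvalue). Sørensen
  dissimilarities are non-Euclidean, so negative eigenvalues appear; those
  axes are reported but dropped (no Cailliez/Lingoes correction), keeping
  the Euclidean-vs-non-Euclidean comparison about the input metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .distances import OccurrenceMatrix, euclidean_distance, sorensen_dissimilarity, to_presence_absence
from .nerc import _as_square

__all__ = [
    "LinkageClustering",
    "PCoAKMeans",
    "OrdinationResult",
    "linkage_cluster",
    "pcoa",
    "kmeans_cluster",
    "kmeans_on_distance",
]

_LINKAGE_METHODS = {"single": "single", "complete": "complete", "upgma": "average"}

#: eigenvalues below this fraction of the largest are treated as zero
_EIG_REL_TOL = 1e-10


@dataclass
class OrdinationResult:
    """PCoA embedding: site coordinates on the retained (positive) axes.

    ``eigenvalues`` holds the full spectrum in decreasing order, negative
    values included, so the non-Euclidean mass is visible;
    ``coordinates`` has one column per strictly positive eigenvalue,
    scaled by sqrt(eigenvalue) and centred.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def linkage_cluster(d, method: str, k: int) -> np.ndarray:
    """Agglomerate with the named linkage and cut the tree into k groups."""
    d = _as_square(d)
    n = d.shape[0]
    if method not in _LINKAGE_METHODS:
        raise ValueError(f"method must be one of {sorted(_LINKAGE_METHODS)}")
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}]")
    Z = linkage(squareform(d, checks=False), method=_LINKAGE_METHODS[method])
    return cut_tree(Z, n_clusters=k).ravel().astype(np.int64)


def pcoa(d) -> OrdinationResult:
    """Principal coordinates analysis of a dissimilarity matrix.

    Double-centres B = -(1/2) J d^2 J (J the centring projector), takes the
    symmetric eigendecomposition, and scales eigenvectors of strictly
    positive eigenvalues by sqrt(eigenvalue). For Euclidean input the
    embedding reproduces the distances exactly; non-Euclidean input leaves
    negative eigenvalues whose axes are dropped.
    """
    d = _as_square(d)
    n = d.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = _EIG_REL_TOL * max(eigval.max(initial=0.0), 1.0)
    keep = eigval > tol
    if not keep.any():
        raise ValueError("no positive eigenvalues: degenerate (all-zero?) dissimilarity matrix")
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    coords = coords - coords.mean(axis=0)  # numerically re-centre
    return OrdinationResult(coordinates=coords, eigenvalues=eigval)


def kmeans_cluster(
    coords,
    k: int,
    restarts: int = 100,
    random_state: int | None = None,
) -> np.ndarray:
    """Lloyd's k-means on ordination coordinates, best of ``restarts`` by WCSS.

    Initial centroids are random data points (Forgy); an emptied cluster is
    re-seeded at a far point. Deterministic given ``random_state``.
    """
    if isinstance(coords, OrdinationResult):
        coords = coords.coordinates
    coords = np.asarray(coords, dtype=float)
    if not (1 <= k <= coords.shape[0]):
        raise ValueError(f"k must be in [1, {coords.shape[0]}]")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        algorithm="lloyd",
        random_state=random_state,
    )
    return km.fit_predict(coords).astype(np.int64)


def kmeans_on_distance(
    m: OccurrenceMatrix,
    k: int,
    metric: str = "sorensen",
    restarts: int = 100,
    random_state: int | None = None,
) -> np.ndarray:
    """Full pipeline: occurrences -> presence/absence -> distance -> PCoA -> k-means.

    ``metric="sorensen"`` uses the Sørensen dissimilarity (non-Euclidean);
    ``metric="euclidean"`` uses Euclidean distances between the same 0/1
    site vectors, isolating the effect of the metric.
    """
    binary = to_presence_absence(m)
    if metric == "sorensen":
        dm = sorensen_dissimilarity(binary)
    elif metric == "euclidean":
        dm = euclidean_distance(binary)
    else:
        raise ValueError("metric must be 'sorensen' or 'euclidean'")
    return kmeans_cluster(pcoa(dm), k, restarts=restarts, random_state=random_state)


class LinkageClustering(ClusterMixin, BaseEstimator):
    """Agglomerative clustering of a precomputed dissimilarity matrix.

    Parameters
    ----------
    n_clusters : int, default=2
        Number of groups after cutting the tree.
    linkage : {"single", "complete", "upgma"}, default="upgma"
        Inter-cluster distance update; "upgma" is average linkage.

    Attributes
    ----------
    labels_ : ndarray of cluster ids per sample.
    """

    def __init__(self, n_clusters: int = 2, linkage: str = "upgma"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def fit(self, X, y=None):
        self.labels_ = linkage_cluster(X, self.linkage, self.n_clusters)
        return self


class PCoAKMeans(ClusterMixin, BaseEstimator):
    """k-means on a PCoA embedding of site-by-species occurrence data.

    ``fit`` expects samples-by-features input per scikit-learn convention:
    sites as rows, species as columns (counts or presences; thresholded
    internally).

    Parameters
    ----------
    n_clusters : int, default=2
    metric : {"sorensen", "euclidean"}, default="sorensen"
        Distance computed between presence/absence site vectors before the
        embedding.
    n_restarts : int, default=100
        k-means restarts; best by within-cluster sum of squares.
    random_state : int or None

    Attributes
    ----------
    labels_ : ndarray of cluster ids per site.
    ordination_ : OrdinationResult of the embedding clustered.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        metric: str = "sorensen",
        n_restarts: int = 100,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.metric = metric
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        import pandas as pd

        if self.metric not in ("sorensen", "euclidean"):
            raise ValueError("metric must be 'sorensen' or 'euclidean'")
        X = np.asarray(X)
        m = OccurrenceMatrix(pd.DataFrame(X.T))  # back to species x sites
        binary = to_presence_absence(m)
        dm = sorensen_dissimilarity(binary) if self.metric == "sorensen" else euclidean_distance(binary)
        self.ordination_ = pcoa(dm)
        self.labels_ = kmeans_cluster(
            self.ordination_, self.n_clusters, restarts=self.n_restarts, random_state=self.random_state
        )
        return self
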