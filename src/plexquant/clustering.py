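"""Unsupervised clustering engines and density-based cluster trimming.

Bead populations are identified by generic clustering on one or two
channels. Four engines are exposed behind a single dispatcher:

``clara``
    Clustering LARge Applications: partitioning around medoids (PAM) run
    on random subsets, with each candidate medoid set scored by the
    dissimilarity of *all* points to it. The default engine; the
    subsampling makes it cheap on large event files and reproducible
    under a fixed seed. PAM and CLARA are implemented here (BUILD + SWAP
    local search).
``kmeans`` / ``dbscan`` / ``gmm``
    Thin wrappers around scikit-learn's KMeans, DBSCAN and
    GaussianMixture.

Labels are integers ``0..k-1``; ``-1`` marks noise (DBSCAN) or events
trimmed away from a cluster's periphery.

Trimming removes the fraction ``trim`` of each cluster's members that
lie furthest from the cluster's density-estimated center. Distances are
computed on per-dimension standardized axes so that the fraction is
scale-free -- the raw numerical range of a cytometer channel depends on
the detector and would otherwise dominate the distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde
from sklearn.cluster import DBSCAN, KMeans
from sklearn.mixture import GaussianMixture

from .errors import DataError, FitError

NOISE = -1  # label for trimmed / noise events

_METHODS = ("clara", "pam", "kmeans", "dbscan", "gmm")


@dataclass(frozen=True)
class ClusterParams:
    """Settings for :func:`cluster_events`.

    ``trim`` is the fraction (0 <= trim < 1) of each cluster's most
    distant members to discard; ``k`` is the expected cluster count
    (for DBSCAN it is only checked against the number of clusters
    found).
    """

    method: str = "clara"
    k: int = 2
    trim: float = 0.0
    seed: int | None = None
    # clara
    n_subsets: int = 5
    subset_size: int | None = None
    # dbscan
    eps: float = 0.5
    min_pts: int = 5
    # gmm
    covariance: str = "full"
    max_iter: int = 200
    tol: float = 1e-4

    def __post_init__(self):
        if self.method not in _METHODS:
            raise DataError(f"unknown clustering method {self.method!r}; "
                            f"choose one of {_METHODS}")
        if not 0 <= self.trim < 1:
            raise DataError(f"trim must be in [0, 1), got {self.trim}")
        if self.method != "dbscan" and self.k < 1:
            raise DataError(f"k must be >= 1, got {self.k}")
        if self.method == "dbscan":
            if not self.eps > 0:
                raise DataError(f"eps must be > 0, got {self.eps}")
            if self.min_pts < 1:
                raise DataError(f"min_pts must be >= 1, got {self.min_pts}")


@dataclass
class ClusterResult:
    labels: np.ndarray            # (n,) int, NOISE = -1
    centers: np.ndarray           # (k, d)
    objective: float              # method-specific fit score
    method: str
    params: ClusterParams | None = None
    posteriors: np.ndarray | None = None  # (n, k), gmm only

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if len(self.labels) else 0


def _as_matrix(points) -> np.ndarray:
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise DataError(f"points must be a 1-D or 2-D array, got shape {x.shape}")
    return x


# ---------------------------------------------------------------------------
# partitioning around medoids
# ---------------------------------------------------------------------------


def _pam_build(dist: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD initialization, starting from the most central point."""
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    nearest = dist[medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum of reductions in nearest distance
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, dist[c])
    return np.asarray(medoids)


def _pam_swap(dist: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """SWAP local search: apply the best improving (medoid, candidate)
    swap repeatedly, so the objective never increases across steps."""
    n = dist.shape[0]
    medoids_arr = np.asarray(medoids).copy()
    while True:
        med_d = dist[medoids_arr]                      # (k, n)
        order = np.argsort(med_d, axis=0, kind="stable")
        d1 = med_d[order[0], np.arange(n)]             # nearest medoid distance
        d2 = (
            med_d[order[1], np.arange(n)]
            if len(medoids_arr) > 1
            else np.full(n, np.inf)
        )
        which = order[0]                               # index into medoids_arr
        current = d1.sum()
        best = (0.0, None, None)
        non_medoids = np.setdiff1d(np.arange(n), medoids_arr, assume_unique=False)
        if len(non_medoids) == 0:
            break
        for j in range(len(medoids_arr)):
            # nearest distance with medoid j removed
            without_j = np.where(which == j, d2, d1)
            # objective after swapping j for each candidate h
            cand = np.minimum(without_j[:, None], dist[:, non_medoids]).sum(axis=0)
            i = int(np.argmin(cand))
            delta = cand[i] - current
            if delta < best[0] - 1e-12:
                best = (delta, j, non_medoids[i])
        if best[1] is None:
            break
        medoids_arr[best[1]] = best[2]
    med_d = dist[medoids_arr]
    return np.sort(medoids_arr), float(med_d.min(axis=0).sum())


def _pam_on_matrix(
    dist: np.ndarray, k: int, seed: int | None = None, restarts: int = 8
) -> tuple[np.ndarray, float]:
    """BUILD + SWAP with seeded random restarts.

    The SWAP descent is run from the BUILD initialization and from
    ``restarts`` random medoid sets; the best local optimum wins. The
    restarts guard against the (rare) local optima of a single steepest
    descent while keeping the search deterministic for a given seed.
    """
    n = dist.shape[0]
    best_medoids, best_obj = _pam_swap(dist, _pam_build(dist, k))
    if k < n:
        rng = np.random.default_rng(0 if seed is None else seed)
        for _ in range(restarts):
            start = rng.choice(n, size=k, replace=False)
            medoids, obj = _pam_swap(dist, start)
            if obj < best_obj - 1e-12:
                best_medoids, best_obj = medoids, obj
    return best_medoids, best_obj


def pam(points, k: int, seed: int | None = None) -> ClusterResult:
    """Partitioning around medoids (k-medoids, BUILD + SWAP).

    Medoids are data points; the objective is the total Euclidean
    dissimilarity of all points to their nearest medoid. The SWAP
    descent is restarted from a few seeded random initializations, so
    results are reproducible for a fixed seed.
    """
    x = _as_matrix(points)
    n = len(x)
    if n < k:
        raise DataError(f"pam requires at least k={k} points, got {n}")
    dist = cdist(x, x)
    medoids, objective = _pam_on_matrix(dist, k, seed=seed)
    labels = np.argmin(dist[medoids], axis=0)
    return ClusterResult(
        labels=labels,
        centers=x[medoids],
        objective=objective,
        method="pam",
    )


def clara(
    points,
    k: int,
    n_subsets: int = 5,
    subset_size: int | None = None,
    seed: int | None = None,
) -> ClusterResult:
    """CLARA: PAM on random subsets, scored on the full data set.

    For each of ``n_subsets`` subsets of size ``subset_size`` (default
    ``min(n, 40 + 2k)``, the classical choice) PAM is run on the subset
    and the resulting medoids are scored by the total dissimilarity of
    *all* points to them; the best-scoring medoid set wins. With
    ``subset_size >= n`` this is exactly PAM on the full data.
    """
    x = _as_matrix(points)
    n = len(x)
    if n < k:
        raise DataError(f"clara requires at least k={k} points, got {n}")
    if subset_size is None:
        subset_size = min(n, 40 + 2 * k)
    if subset_size < k:
        raise DataError(f"subset_size ({subset_size}) must be >= k ({k})")
    rng = np.random.default_rng(seed)

    best_obj = np.inf
    best_medoids: np.ndarray | None = None
    if subset_size >= n:
        subsets = [np.arange(n)]
    else:
        subsets = [
            np.sort(rng.choice(n, size=subset_size, replace=False))
            for _ in range(n_subsets)
        ]
    for idx in subsets:
        sub = x[idx]
        med_local, _ = _pam_on_matrix(cdist(sub, sub), k, seed=seed)
        med_coords = sub[med_local]
        d = cdist(med_coords, x)
        obj = float(d.min(axis=0).sum())
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_medoids = med_coords
    assert best_medoids is not None
    labels = np.argmin(cdist(best_medoids, x), axis=0)
    return ClusterResult(
        labels=labels,
        centers=best_medoids,
        objective=best_obj,
        method="clara",
    )


# ---------------------------------------------------------------------------
# scikit-learn engines
# ---------------------------------------------------------------------------


def kmeans(points, k: int, seed: int | None = None) -> ClusterResult:
    """k-means with k-means++ initialization and 10 restarts."""
    x = _as_matrix(points)
    if len(x) < k:
        raise DataError(f"kmeans requires at least k={k} points, got {len(x)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    return ClusterResult(
        labels=km.labels_.astype(int),
        centers=km.cluster_centers_,
        objective=float(km.inertia_),
        method="kmeans",
    )


def dbscan(points, eps: float, min_pts: int = 5) -> ClusterResult:
    """Density-based clustering; unreachable points get the noise label."""
    if not eps > 0:
        raise DataError(f"eps must be > 0, got {eps}")
    x = _as_matrix(points)
    db = DBSCAN(eps=eps, min_samples=min_pts).fit(x)
    labels = db.labels_.astype(int)
    n_clusters = labels.max() + 1 if len(labels) else 0
    centers = np.vstack(
        [x[labels == c].mean(axis=0) for c in range(n_clusters)]
    ) if n_clusters else np.empty((0, x.shape[1]))
    return ClusterResult(
        labels=labels, centers=centers, objective=float("nan"), method="dbscan"
    )


def gmm(
    points,
    k: int,
    covariance: str = "full",
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> ClusterResult:
    """Gaussian mixture fitted by EM; hard labels by maximum posterior."""
    x = _as_matrix(points)
    if len(x) < k:
        raise DataError(f"gmm requires at least k={k} points, got {len(x)}")
    gm = GaussianMixture(
        n_components=k,
        covariance_type=covariance,
        max_iter=max_iter,
        tol=tol,
        n_init=3,
        random_state=seed,
    ).fit(x)
    if not gm.converged_:
        raise FitError(
            f"EM did not converge within {max_iter} iterations "
            f"(n_iter={gm.n_iter_})"
        )
    post = gm.predict_proba(x)
    return ClusterResult(
        labels=np.argmax(post, axis=1).astype(int),
        centers=gm.means_,
        objective=float(gm.score(x) * len(x)),  # total log-likelihood
        method="gmm",
        posteriors=post,
    )


def cluster_events(points, params: ClusterParams) -> ClusterResult:
    """Dispatch to the engine named in ``params.method``.

    For DBSCAN the number of clusters is data-driven; if it differs from
    ``params.k`` an error is raised, because downstream analyte-ID
    assignment is positional and silently mislabelled beads are worse
    than a failure.
    """
    x = _as_matrix(points)
    if params.method == "pam":
        res = pam(x, params.k, seed=params.seed)
    elif params.method == "clara":
        res = clara(
            x,
            params.k,
            n_subsets=params.n_subsets,
            subset_size=params.subset_size,
            seed=params.seed,
        )
    elif params.method == "kmeans":
        res = kmeans(x, params.k, seed=params.seed)
    elif params.method == "gmm":
        res = gmm(
            x,
            params.k,
            covariance=params.covariance,
            seed=params.seed,
            max_iter=params.max_iter,
            tol=params.tol,
        )
    else:  # dbscan
        res = dbscan(x, eps=params.eps, min_pts=params.min_pts)
        if res.n_clusters != params.k:
            raise DataError(
                f"dbscan found {res.n_clusters} clusters but {params.k} were "
                "expected; tune eps/min_pts or use a partitioning method"
            )
    res.params = params
    return res


# ---------------------------------------------------------------------------
# density center and trimming
# ---------------------------------------------------------------------------


def density_center(points) -> np.ndarray:
    """Cluster center as the per-dimension mode of a Gaussian KDE.

    Each dimension is treated independently: a 1-D Gaussian kernel
    density estimate (Silverman bandwidth) is evaluated on a 512-point
    grid and the grid argmax taken. Robust to asymmetric tails, unlike
    the mean. Degenerate dimensions (single point or zero spread)
    return their common value.
    """
    x = _as_matrix(points)
    if len(x) == 0:
        raise DataError("density_center requires at least one point")
    center = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        col = x[:, j]
        if len(col) < 3 or np.ptp(col) == 0 or col.std() == 0:
            center[j] = float(np.median(col))
            continue
        kde = gaussian_kde(col, bw_method="silverman")
        grid = np.linspace(col.min(), col.max(), 512)
        center[j] = float(grid[np.argmax(kde(grid))])
    return center


def trim_cluster(points, labels, trim: float) -> np.ndarray:
    """Mark the ``ceil(trim * m)`` most distant members of each cluster
    as noise.

    Distances are Euclidean to the cluster's :func:`density_center`,
    after standardizing every dimension by the cluster's own spread so
    the fraction does not depend on channel units. ``trim=0`` returns
    the labels unchanged. Already-noise labels are preserved.
    """
    if not 0 <= trim < 1:
        raise DataError(f"trim must be in [0, 1), got {trim}")
    x = _as_matrix(points)
    labels = np.asarray(labels, dtype=int).copy()
    if trim == 0:
        return labels
    for c in np.unique(labels):
        if c == NOISE:
            continue
        members = np.flatnonzero(labels == c)
        m = len(members)
        n_drop = math.ceil(round(trim * m, 9))
        if n_drop == 0:
            continue
        pts = x[members]
        center = density_center(pts)
        scale = pts.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        d = np.sqrt((((pts - center) / scale) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[::-1]  # most distant first
        labels[members[order[:n_drop]]] = NOISE
    return labels
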