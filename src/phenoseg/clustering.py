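"""K-means clustering of surface feature histograms on the simplex.

Three methods, differing only in the representation the Euclidean k-means
objective ``E = sum_i sum_j zeta_ij d(x_i, mu_j)^2`` is minimized in:

* ``km``  — plain k-means on the normalized histograms directly (baseline).
* ``hc1`` — square-root transform first; squared Euclidean distance in this
  space is the Hellinger distance between the original histograms.  Cluster
  representatives are recomputed as means of the *original* histograms over
  the final assignments, so they lie on the simplex.
* ``hc2`` — zero-replacement then centered log-ratio transform; Euclidean
  distance in this space is the Aitchison distance.  Representatives are
  mapped back to the simplex by the inverse clr (softmax).

The k-means core is an EM-style alternation: E-step assigns each row to the
nearest centroid (ties to the lowest cluster id); M-step recomputes
centroids as means of the assigned rows.  The objective trace is recorded
per iteration and is non-increasing.  Empty clusters are repaired by
re-seeding with the row farthest from its current centroid.  Everything is
deterministic given the seed; the best of ``n_restarts`` runs by final
objective is returned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from phenoseg.features import HistogramSet
from phenoseg.io import PointCloud
from phenoseg.simplex import clr_inverse, clr_transform, replace_zeros, sqr_transform

__all__ = ["ClusterConfig", "ClusterModel", "KMeansResult", "kmeans",
           "cluster_histograms", "attach_clusters", "UNCLUSTERED"]

#: Sentinel cluster id for points dropped before clustering.
UNCLUSTERED = -1

_METHODS = ("km", "hc1", "hc2")


@dataclass(frozen=True)
class ClusterConfig:
    """Configuration of a clustering run.

    Attributes
    ----------
    k : int
        Number of clusters (>= 1, at most the number of rows).
    method : {"km", "hc1", "hc2"}
        Data representation (see module docstring).
    max_iter, tol : int, float
        EM iteration cap and relative objective-change threshold.
    n_restarts : int
        Independent seeded initializations; best final objective wins.
    seed : int
        Master seed; same seed + same input gives identical assignments.
    epsilon : float or None
        Zero-replacement constant for the clr path; None means 1/m.
    init : {"auto", "k-means++", "random"}
        Seeding strategy.  "auto" (default) enumerates every k-subset of
        rows as an initialization when there are no more such subsets than
        restarts — on tiny problems this reliably reaches the global
        optimum, which probabilistic seeding can systematically miss — and
        otherwise behaves like "k-means++".
    """

    k: int = 2
    method: str = "hc2"
    max_iter: int = 300
    tol: float = 1e-6
    n_restarts: int = 5
    seed: int = 0
    epsilon: float | None = None
    init: str = "auto"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.init not in ("auto", "k-means++", "random"):
            raise ValueError("init must be 'auto', 'k-means++' or 'random'")


@dataclass
class KMeansResult:
    """Raw k-means output in the working space."""

    assignments: NDArray[np.int64]
    centroids: NDArray[np.float64]
    objective: float
    objective_trace: NDArray[np.float64]
    n_iter: int
    restart_index: int


@dataclass
class ClusterModel:
    """Clustering of a histogram set with simplex-valued representatives."""

    assignments: NDArray[np.int64]
    centroids_simplex: NDArray[np.float64]
    centroids_transformed: NDArray[np.float64]
    objective: float
    objective_trace: NDArray[np.float64]
    n_iter: int
    restart_index: int
    method: str
    config: ClusterConfig

    @property
    def k(self) -> int:
        return len(self.centroids_simplex)


# ---------------------------------------------------------------------------
# k-means core
# ---------------------------------------------------------------------------

def _sq_dists(X: NDArray, C: NDArray) -> NDArray:
    """Squared Euclidean distances, shape (n, k); clipped at 0 for round-off."""
    d2 = (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ C.T
        + np.einsum("ij,ij->i", C, C)[None, :]
    )
    return np.maximum(d2, 0.0)


def _init_centroids(X: NDArray, k: int, rng: np.random.Generator, init: str) -> NDArray:
    n = len(X)
    if init == "random":
        return X[rng.choice(n, size=k, replace=False)].copy()
    # k-means++ seeding: next center drawn with probability proportional to
    # squared distance to the nearest existing center.
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = _sq_dists(X, centers[:1]).ravel()
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c:] = X[rng.choice(n, size=k - c, replace=True)]
            break
        centers[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, _sq_dists(X, centers[c: c + 1]).ravel())
    return centers


def _run_once(
    X: NDArray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    init: str,
    C0: NDArray | None = None,
) -> tuple[NDArray, NDArray, float, list[float], int]:
    n = len(X)
    C = C0.copy() if C0 is not None else _init_centroids(X, k, rng, init)
    trace: list[float] = []
    assign = np.full(n, -1, dtype=np.int64)
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(X, C)
        new_assign = np.argmin(d2, axis=1)  # argmin takes the lowest id on ties
        obj = float(d2[np.arange(n), new_assign].sum())
        trace.append(obj)
        converged = bool(np.array_equal(new_assign, assign))
        assign = new_assign
        # M-step with empty-cluster repair.
        counts = np.bincount(assign, minlength=k)
        for c in np.flatnonzero(counts == 0):
            far = int(np.argmax(d2[np.arange(n), assign]))
            assign[far] = c
            d2[far, :] = 0.0  # excluded from further farthest-point picks
            counts = np.bincount(assign, minlength=k)
            converged = False
        sums = np.zeros_like(C)
        np.add.at(sums, assign, X)
        C = sums / counts[:, None]
        if converged:
            break
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if prev > 0 and (prev - cur) / prev < tol:
                break
    # Final E-step so assignments and objective match the returned centroids.
    d2 = _sq_dists(X, C)
    assign = np.argmin(d2, axis=1)
    obj = float(d2[np.arange(n), assign].sum())
    trace.append(obj)
    return assign, C, obj, trace, len(trace)


def kmeans(X: NDArray, config: ClusterConfig) -> KMeansResult:
    """Best-of-restarts EM k-means with Euclidean distance.

    Deterministic given ``config.seed``; each restart draws from an
    independent substream of the master seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2D matrix")
    if len(X) < config.k:
        raise ValueError(f"need at least k={config.k} rows, got {len(X)}")
    best: KMeansResult | None = None
    exhaustive: list[tuple[int, ...]] | None = None
    init = config.init
    if init == "auto":
        init = "k-means++"
        from math import comb

        if comb(len(X), config.k) <= config.n_restarts:
            exhaustive = list(itertools.combinations(range(len(X)), config.k))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        C0 = None
        if exhaustive is not None and r < len(exhaustive):
            C0 = X[list(exhaustive[r])]
        assign, C, obj, trace, n_iter = _run_once(
            X, config.k, rng, config.max_iter, config.tol, init, C0
        )
        if best is None or obj < best.objective:
            best = KMeansResult(
                assignments=assign,
                centroids=C,
                objective=obj,
                objective_trace=np.asarray(trace),
                n_iter=n_iter,
                restart_index=r,
            )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Histogram clustering (transform, cluster, map back to the simplex)
# ---------------------------------------------------------------------------

def cluster_histograms(H: HistogramSet, config: ClusterConfig) -> ClusterModel:
    """Cluster normalized histograms with the configured representation.

    Simplex representatives: for ``km`` the centroids themselves (means of
    simplex points stay on the simplex); for ``hc1`` the means of the
    original histograms under the final assignments; for ``hc2`` the inverse
    clr of the working-space centroids.
    """
    X0 = H.histograms
    if config.k > len(X0):
        raise ValueError(f"k={config.k} exceeds number of histograms {len(X0)}")
    if config.method == "km":
        X = X0
    elif config.method == "hc1":
        X = sqr_transform(X0)
    else:
        X = clr_transform(replace_zeros(X0, config.epsilon))

    res = kmeans(X, config)

    if config.method == "km":
        simplex_centroids = res.centroids.copy()
    elif config.method == "hc1":
        k = config.k
        sums = np.zeros((k, X0.shape[1]))
        np.add.at(sums, res.assignments, X0)
        counts = np.bincount(res.assignments, minlength=k).astype(float)
        counts[counts == 0] = 1.0
        simplex_centroids = sums / counts[:, None]
    else:
        simplex_centroids = clr_inverse(res.centroids)

    return ClusterModel(
        assignments=res.assignments,
        centroids_simplex=simplex_centroids,
        centroids_transformed=res.centroids,
        objective=res.objective,
        objective_trace=res.objective_trace,
        n_iter=res.n_iter,
        restart_index=res.restart_index,
        method=config.method,
        config=config,
    )


def attach_clusters(
    pc: PointCloud, model: ClusterModel, index_map: NDArray[np.int64]
) -> NDArray[np.int64]:
    """Per-point cluster ids for the full cloud; dropped points get -1.

    ``index_map`` maps histogram rows to point indices (a
    ``HistogramSet.point_index_map``); it must cover every clustered row.
    """
    index_map = np.asarray(index_map, dtype=np.int64)
    if len(index_map) != len(model.assignments):
        raise ValueError(
            f"index map length {len(index_map)} != assignments {len(model.assignments)}"
        )
    if len(index_map) and (index_map.min() < 0 or index_map.max() >= len(pc)):
        raise ValueError("index map points outside the cloud")
    ids = np.full(len(pc), UNCLUSTERED, dtype=np.int64)
    ids[index_map] = model.assignments
    return ids
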