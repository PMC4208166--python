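"""Per-pixel k-means clustering.

The segmentation method treats every pixel of an M×N image as a training
sample: the image is reshaped to an L×d matrix (L = M·N, d the number of
stacked channels), and Lloyd's algorithm alternates a nearest-centroid
assignment under squared Euclidean distance with a centroid update to the
mean of each cluster, until the within-cluster sum of squares (inertia)
stops improving.

The implementation is written from first principles because the clustering
rule *is* the segmentation method; scikit-learn's KMeans serves only as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureMatrix", "ClusterResult", "build_features", "unflatten", "kmeans_fit"]


@dataclass(frozen=True)
class FeatureMatrix:
    """L×d per-pixel feature rows plus the (M, N) shape needed to un-flatten."""

    rows: np.ndarray
    shape: tuple[int, int]
    channel_names: tuple[str, ...]

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=np.float64)
        object.__setattr__(self, "rows", rows)
        if rows.ndim != 2:
            raise ValueError("feature rows must be a 2-D array")
        if rows.shape[0] != self.shape[0] * self.shape[1]:
            raise ValueError("row count does not match the stated image shape")
        if not np.all(np.isfinite(rows)):
            raise ValueError("feature rows contain non-finite values")


@dataclass
class ClusterResult:
    """Labels and centroids from one k-means fit.

    ``inertia_history`` records the within-cluster sum of squares after each
    assignment step; it is non-increasing by construction of Lloyd iterations.
    """

    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    n_iter: int
    inertia_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def build_features(
    img_channels: list[np.ndarray],
    channel_names: tuple[str, ...] | None = None,
) -> FeatureMatrix:
    """Stack H×W channel rasters into an L×d feature matrix, row-major.

    Row *i* holds the channel values of pixel *i* in row-major (C) order, so
    ``labels.reshape(H, W)`` restores image geometry.
    """
    if not img_channels:
        raise ValueError("at least one channel is required")
    arrays = [np.asarray(c, dtype=np.float64) for c in img_channels]
    shape = arrays[0].shape
    if len(shape) != 2:
        raise ValueError("channels must be 2-D rasters")
    for i, arr in enumerate(arrays):
        if arr.shape != shape:
            name = channel_names[i] if channel_names else f"channel {i}"
            raise ValueError(
                f"{name} has shape {arr.shape}, expected {shape} like channel 0"
            )
    rows = np.stack([a.ravel() for a in arrays], axis=1)
    names = tuple(channel_names) if channel_names else tuple(
        f"ch{i}" for i in range(len(arrays))
    )
    return FeatureMatrix(rows=rows, shape=shape, channel_names=names)


def unflatten(labels: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Reshape flat per-pixel labels back to the (M, N) image grid."""
    return np.asarray(labels).reshape(shape)


def _init_centroids(X: np.ndarray, k: int, rng: np.random.Generator, init: str) -> np.ndarray:
    if init == "random_points":
        idx = rng.choice(X.shape[0], size=k, replace=False)
        return X[idx].copy()
    if init == "kmeanspp":
        # Greedy D² seeding: first centroid uniform; each next one is the
        # best of several candidates drawn with probability proportional to
        # squared distance to the nearest chosen centroid (the candidate
        # minimizing the resulting potential wins). The greedy variant
        # markedly reduces the chance of a poor seeding on small data.
        n_candidates = 2 + int(np.log(k + 1))
        centroids = np.empty((k, X.shape[1]))
        centroids[0] = X[rng.integers(X.shape[0])]
        d2 = np.sum((X - centroids[0]) ** 2, axis=1)
        for j in range(1, k):
            total = d2.sum()
            if total <= 0.0:
                centroids[j] = X[rng.integers(X.shape[0])]
                continue
            cand_idx = rng.choice(X.shape[0], size=n_candidates, p=d2 / total)
            best_pot, best = np.inf, None
            for ci in cand_idx:
                pot = np.minimum(d2, np.sum((X - X[ci]) ** 2, axis=1)).sum()
                if pot < best_pot:
                    best_pot, best = pot, ci
            centroids[j] = X[best]
            d2 = np.minimum(d2, np.sum((X - centroids[j]) ** 2, axis=1))
        return centroids
    raise ValueError(f"unknown init {init!r}; choose 'kmeanspp' or 'random_points'")


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, float]:
    # Squared Euclidean distances to every centroid; argmin breaks ties by
    # lowest centroid index, which keeps runs deterministic.
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    return labels, inertia


def _assign_chunked(X: np.ndarray, centroids: np.ndarray, chunk: int = 65536):
    if X.shape[0] <= chunk:
        return _assign(X, centroids)
    labels = np.empty(X.shape[0], dtype=np.intp)
    inertia = 0.0
    for start in range(0, X.shape[0], chunk):
        sl = slice(start, start + chunk)
        labels[sl], part = _assign(X[sl], centroids)
        inertia += part
    return labels, inertia


def kmeans_fit(
    X: FeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    init: str = "kmeanspp",
    max_iter: int = 100,
    tol: float = 1e-6,
    n_init: int = 4,
) -> ClusterResult:
    """Run Lloyd's k-means on per-pixel feature rows.

    Parameters
    ----------
    X:
        A :class:`FeatureMatrix` or a plain L×d array.
    k:
        Number of clusters; must not exceed the number of distinct rows.
    seed:
        Seeds both initialization and restarts; fixed seed → identical result.
    init:
        ``"kmeanspp"`` (default) or ``"random_points"`` (plain random rows,
        matching the classical description of the algorithm).
    max_iter, tol:
        Iterations stop when the inertia improvement is ≤ *tol* or after
        *max_iter* assignment/update rounds.
    n_init:
        Number of seeded restarts; the fit with the lowest inertia is kept.

    Notes
    -----
    An empty cluster arising during an update is re-seeded at the point
    farthest from its assigned centroid, so the result never contains an
    empty cluster.
    """
    rows = X.rows if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)
    if rows.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    if k < 1:
        raise ValueError("k must be ≥ 1")
    n_distinct = np.unique(rows, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct feature rows ({n_distinct})"
        )
    if n_init < 1:
        raise ValueError("n_init must be ≥ 1")

    master = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(n_init):
        rng = np.random.default_rng(master.integers(2**31))
        result = _kmeans_single(rows, k, rng, init, max_iter, tol)
        if best is None or result.inertia < best.inertia - 1e-15:
            best = result
    assert best is not None
    return best


def _best_hartigan_move(rows, labels, centroids, k):
    """Single-point move with the largest exact SSE decrease, or None.

    Lloyd fixed points can be escaped by moves Lloyd never considers: the
    exact SSE change of moving x from cluster j (size n_j) to l (size n_l)
    is n_l/(n_l+1)·d(x,μ_l)² − n_j/(n_j−1)·d(x,μ_j)², which can be negative
    even when x is nearer μ_j. Returns (point index, target cluster, gain).
    """
    n = rows.shape[0]
    counts = np.bincount(labels, minlength=k).astype(float)
    d2 = ((rows[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    own = counts[labels]
    # a singleton's point may not move (its cluster would vanish)
    removal = np.full(n, -np.inf)
    movable = own > 1
    removal[movable] = (own[movable] / (own[movable] - 1)) * d2[
        np.arange(n), labels
    ][movable]
    addition = (counts / (counts + 1))[None, :] * d2
    addition[np.arange(n), labels] = np.inf
    best_target = np.argmin(addition, axis=1)
    gain = removal - addition[np.arange(n), best_target]
    i = int(np.argmax(gain))
    if gain[i] <= 1e-12:
        return None
    return i, int(best_target[i]), float(gain[i])


def _kmeans_single(
    rows: np.ndarray, k: int, rng: np.random.Generator, init: str, max_iter: int, tol: float
) -> ClusterResult:
    centroids = _init_centroids(rows, k, rng, init)
    labels, inertia = _assign_chunked(rows, centroids)
    history = [inertia]
    n_iter = 0
    for _escape in range(20):
        for n_iter in range(n_iter + 1, max_iter + 1):
            # Update step: each centroid moves to the mean of its members.
            for j in range(k):
                members = rows[labels == j]
                if members.shape[0] == 0:
                    # Re-seed a vanished cluster at the worst-fit point.
                    d2 = ((rows - centroids[labels]) ** 2).sum(axis=1)
                    centroids[j] = rows[int(np.argmax(d2))]
                else:
                    centroids[j] = members.mean(axis=0)
            labels, new_inertia = _assign_chunked(rows, centroids)
            history.append(new_inertia)
            if inertia - new_inertia <= tol:
                inertia = new_inertia
                break
            inertia = new_inertia
        # Converged for Lloyd; try a single-point escape move before
        # accepting the fixed point.
        move = _best_hartigan_move(rows, labels, centroids, k)
        if move is None or n_iter >= max_iter:
            break
        i, target, _ = move
        labels[i] = target
        for j in range(k):
            members = rows[labels == j]
            if members.shape[0]:
                centroids[j] = members.mean(axis=0)
        labels, inertia = _assign_chunked(rows, centroids)
        history.append(inertia)
    return ClusterResult(
        labels=labels,
        centroids=centroids,
        inertia=inertia,
        n_iter=n_iter,
        inertia_history=history,
    )
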