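"""Shape-based clustering of weight trajectories: DTW, DBA, k-means, elbow.

Dynamic time warping (DTW) measures the dissimilarity of two series as
the minimal cumulative pointwise cost over all monotone alignments
(warping paths) of their indices, so two trajectories with the same shape
but slightly shifted timing are close.  The local cost here is the
squared difference, and the reported distance is the square root of the
minimal path cost; k-means inertia uses the squared form (the objective
Lloyd iterations actually minimize).  No warping window is applied by
default; an optional Sakoe-Chiba band is available for speed.

Cluster prototypes are DTW barycenters (DBA): starting from a candidate
series, every member is aligned to it along its optimal warping path and
each barycenter coordinate is replaced by the mean of the member values
aligned to it, iterated to a fixed point.  k-means alternates DTW
assignment with DBA updates, keeps the best of several seeded restarts,
and repairs empty clusters by reseeding them at the point farthest from
its centroid.  After fitting, cluster labels are renumbered 1..k by
descending size, so cluster 1 is always the largest.

The number of clusters is chosen by the elbow of the inertia-vs-k curve
(maximum curvature, i.e. the largest second difference of the normalized
inertia), with the full curve reported so a human can override the
suggestion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DomainError

__all__ = [
    "ClusterModel",
    "ElbowScan",
    "dtw_distance",
    "dtw_path",
    "dba_barycenter",
    "kmeans_dtw",
    "elbow_scan",
]


def _dp_matrix(a: np.ndarray, b: np.ndarray, band: int | None = None) -> np.ndarray:
    """Cumulative squared-cost DP table, shape (len(a)+1, len(b)+1)."""
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo, j_hi = 1, m
        if band is not None:
            j_lo = max(1, i - band)
            j_hi = min(m, i + band)
        for j in range(j_lo, j_hi + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            D[i, j] = cost + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return D


def dtw_distance(a, b, squared: bool = False, band: int | None = None) -> float:
    """DTW distance between two series (square root of minimal path cost).

    ``squared=True`` returns the minimal sum of squared differences
    itself, the quantity k-means inertia accumulates.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise DomainError("dtw_distance: series must be non-empty")
    cost = _dp_matrix(a, b, band)[a.size, b.size]
    return float(cost) if squared else float(np.sqrt(cost))


def dtw_path(a, b, band: int | None = None) -> list[tuple[int, int]]:
    """Optimal warping path as 0-based index pairs from (0,0) to (n-1,m-1).

    Ties prefer the diagonal step, then the step in ``a`` — a fixed rule
    so alignments (and hence DBA) are deterministic.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    D = _dp_matrix(a, b, band)
    i, j = a.size, b.size
    path = [(i - 1, j - 1)]
    while (i, j) != (1, 1):
        moves = ((D[i - 1, j - 1], i - 1, j - 1), (D[i - 1, j], i - 1, j), (D[i, j - 1], i, j - 1))
        _, i, j = min(moves, key=lambda t: t[0])
        path.append((i - 1, j - 1))
    path.reverse()
    return path


def _batch_sq_dtw(X: np.ndarray, c: np.ndarray, return_dp: bool = False):
    """Squared DTW distance from every row of X (n, L) to series c (m,).

    Vectorized over the n series: the (L+1) x (m+1) DP recursion runs on
    length-n vectors.  Optionally returns the full DP stack for
    backtracking (shape (L+1, m+1, n)).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c = np.asarray(c, dtype=float).ravel()
    n, L = X.shape
    m = c.size
    D = np.full((L + 1, m + 1, n), np.inf)
    D[0, 0, :] = 0.0
    for i in range(1, L + 1):
        xi = X[:, i - 1]
        for j in range(1, m + 1):
            cost = (xi - c[j - 1]) ** 2
            D[i, j] = cost + np.minimum(np.minimum(D[i - 1, j], D[i, j - 1]), D[i - 1, j - 1])
    if return_dp:
        return D[L, m].copy(), D
    return D[L, m].copy()


def _dba_step(S: np.ndarray, bar: np.ndarray) -> tuple[np.ndarray, float]:
    """One DBA update: align every series to bar, average aligned values."""
    n, L = S.shape
    m = bar.size
    sq, D = _batch_sq_dtw(S, bar, return_dp=True)
    sums = np.zeros(m)
    counts = np.zeros(m)
    for s_idx in range(n):
        i, j = L, m
        while True:
            sums[j - 1] += S[s_idx, i - 1]
            counts[j - 1] += 1
            if i == 1 and j == 1:
                break
            d_diag = D[i - 1, j - 1, s_idx]
            d_up = D[i - 1, j, s_idx]
            d_left = D[i, j - 1, s_idx]
            if d_diag <= d_up and d_diag <= d_left:
                i, j = i - 1, j - 1
            elif d_up <= d_left:
                i -= 1
            else:
                j -= 1
    return sums / counts, float(sq.sum())


def dba_barycenter(
    series_set,
    init: np.ndarray | None = None,
    max_iter: int = 30,
    tol: float = 1e-6,
) -> np.ndarray:
    """DTW barycenter of a set of equal-length series.

    Iterates align-and-average from ``init`` (default: the elementwise
    mean) until the barycenter moves less than ``tol`` in any coordinate.
    The total squared-DTW cost to the set is non-increasing over
    iterations; if a step would increase it the previous barycenter is
    kept.
    """
    S = np.atleast_2d(np.asarray(series_set, dtype=float))
    if S.shape[0] == 0:
        raise DomainError("dba_barycenter: empty series set")
    bar = np.array(S.mean(axis=0) if init is None else init, dtype=float)
    prev_cost = float(_batch_sq_dtw(S, bar).sum())
    for _ in range(max_iter):
        new_bar, _ = _dba_step(S, bar)
        new_cost = float(_batch_sq_dtw(S, new_bar).sum())
        if new_cost > prev_cost + 1e-12:
            break
        moved = float(np.max(np.abs(new_bar - bar)))
        bar, prev_cost = new_bar, new_cost
        if moved < tol:
            break
    return bar


@dataclass
class ClusterModel:
    """Fitted DTW k-means model.

    ``assignments`` maps user_id -> 1-based cluster index; clusters are
    numbered by descending size.  ``inertia`` is the sum of squared DTW
    distances to assigned centroids; ``inertia_root`` is the corresponding
    sum of (unsquared) DTW distances, reported alongside because both
    readings of "total sum of distances" are in circulation.
    """

    k: int
    centroids: np.ndarray  # (k, L)
    assignments: dict[str, int]
    labels: np.ndarray  # (n,) 1-based, aligned with the fitted matrix rows
    inertia: float
    inertia_root: float
    n_iter: int
    seed: int
    converged: bool
    inertia_history: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "k": self.k,
            "centroids": np.asarray(self.centroids).tolist(),
            "assignments": self.assignments,
            "labels": np.asarray(self.labels).tolist(),
            "inertia": self.inertia,
            "inertia_root": self.inertia_root,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "converged": self.converged,
            "inertia_history": self.inertia_history,
        }
        return json.dumps(d, sort_keys=True, indent=2)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"user_id": list(self.assignments), "cluster": list(self.assignments.values())}
        )


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under squared DTW distance."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    closest = _batch_sq_dtw(X, X[idx[0]])
    while len(idx) < k:
        total = closest.sum()
        if total <= 0:  # all points coincide with a centroid
            idx.append(int(rng.integers(n)))
        else:
            probs = closest / total
            idx.append(int(rng.choice(n, p=probs)))
        closest = np.minimum(closest, _batch_sq_dtw(X, X[idx[-1]]))
    return X[idx].copy()


def _fit_once(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float,
    dba_max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n = X.shape[0]
    centroids = _kmeanspp_init(X, k, rng)
    labels = np.full(n, -1)
    history: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        dist = np.stack([_batch_sq_dtw(X, centroids[c]) for c in range(k)], axis=1)
        new_labels = dist.argmin(axis=1)  # ties -> lowest cluster index
        inertia = float(dist[np.arange(n), new_labels].sum())
        history.append(inertia)
        if np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels
        for c in range(k):
            members = X[labels == c]
            if members.shape[0] == 0:
                # reseed at the point farthest from its own centroid
                worst = int(dist[np.arange(n), labels].argmax())
                centroids[c] = X[worst]
                continue
            old_cost = float(_batch_sq_dtw(members, centroids[c]).sum())
            cand = dba_barycenter(members, init=centroids[c], max_iter=dba_max_iter, tol=tol)
            if float(_batch_sq_dtw(members, cand).sum()) <= old_cost:
                centroids[c] = cand
        it_done = it
    else:
        it_done = max_iter
    if converged:
        it_done = it
    inertia = history[-1]
    return centroids, labels, inertia, it_done, converged, history


def kmeans_dtw(
    matrix,
    k: int,
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 50,
    tol: float = 1e-6,
    dba_max_iter: int = 15,
) -> ClusterModel:
    """k-means under DTW with DBA centroids; best of ``n_init`` restarts.

    ``matrix`` is an (n, L) array or a DataFrame whose index provides
    user ids.  Deterministic given ``seed``.
    """
    if isinstance(matrix, pd.DataFrame):
        user_ids = [str(u) for u in matrix.index]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(matrix, dtype=float))
        user_ids = [str(i) for i in range(X.shape[0])]
    n = X.shape[0]
    if k < 1 or n < k:
        raise DomainError(f"kmeans_dtw: need n >= k >= 1, got n={n}, k={k}")

    root = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        fit = _fit_once(X, k, rng, max_iter, tol, dba_max_iter)
        if best is None or fit[2] < best[2]:
            best = fit
    centroids, labels, inertia, n_iter, converged, history = best

    # renumber clusters by descending size (stable tie-break on old index)
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels1 = remap[labels]
    centroids = centroids[order]

    dist_root = np.stack(
        [np.sqrt(_batch_sq_dtw(X, centroids[c])) for c in range(k)], axis=1
    )
    inertia_root = float(dist_root[np.arange(n), labels1 - 1].sum())
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments={u: int(c) for u, c in zip(user_ids, labels1)},
        labels=labels1,
        inertia=inertia,
        inertia_root=inertia_root,
        n_iter=n_iter,
        seed=seed,
        converged=converged,
        inertia_history=history,
    )


@dataclass
class ElbowScan:
    k_values: list[int]
    inertias: list[float]
    suggested_k: int
    low_confidence: bool
    models: dict[int, ClusterModel] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "inertia": self.inertias})


def knee_point(k_values, inertias) -> tuple[int, float]:
    """Locate the knee of an inertia-vs-k curve on the log scale.

    Inertia curves for clusterable data fall over orders of magnitude, so
    the knee is found on log-inertia: both axes are rescaled to [0, 1]
    and the knee is the k lying farthest below the chord joining the
    curve's endpoints.  Returns (k, depth) where depth is that maximal
    chord distance in normalized units; a shallow depth means no
    pronounced elbow.  (A raw second-difference rule degenerates on such
    curves: the first interior k always dominates.)
    """
    k_arr = np.asarray(k_values, dtype=float)
    y = np.log(np.maximum(np.asarray(inertias, dtype=float), 1e-300))
    if y.max() - y.min() < 1e-12:
        return int(k_arr[0]), 0.0
    xh = (k_arr - k_arr[0]) / (k_arr[-1] - k_arr[0])
    yh = (y - y.min()) / (y.max() - y.min())
    depth = (yh[0] + (yh[-1] - yh[0]) * xh) - yh
    best = int(np.argmax(depth))
    return int(k_arr[best]), float(depth[best])


def elbow_scan(
    matrix,
    k_range=range(2, 11),
    seed: int = 0,
    n_init: int = 4,
    keep_models: bool = False,
    **kmeans_kwargs,
) -> ElbowScan:
    """Fit k-means for each k and locate the inertia-curve knee.

    The suggestion is the maximum-curvature knee of the inertia curve on
    the log scale (see :func:`knee_point`).  A shallow knee (depth < 0.3)
    or a degenerate k range is flagged low-confidence; the full curve is
    always reported so the choice can be made by inspection, which is how
    the cluster count is normally settled in practice.
    """
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values:
        raise DomainError("elbow_scan: empty k range")
    inertias = []
    models = {}
    for k in k_values:
        model = kmeans_dtw(matrix, k, seed=seed, n_init=n_init, **kmeans_kwargs)
        inertias.append(model.inertia)
        if keep_models:
            models[k] = model
    if len(k_values) < 3:
        return ElbowScan(k_values, inertias, k_values[0], low_confidence=True, models=models)
    suggested, depth = knee_point(k_values, inertias)
    return ElbowScan(k_values, inertias, suggested, depth < 0.3, models=models)
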