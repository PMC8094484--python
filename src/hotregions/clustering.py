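"""K-means with within-cluster sum-of-squares objective and silhouette-guided
selection of the number of clusters.

The clusterer minimises

    WCSS = sum_i sum_{x in S_i} ||x - u_i||^2

over partitions S_1..S_k with centers u_i, and the number of clusters k is
chosen by maximising the average silhouette width

    s(x) = (b(x) - a(x)) / max(a(x), b(x)),

where a(x) is the mean distance from x to the other members of its cluster
and b(x) is the smallest mean distance from x to the members of any other
cluster. Points in singleton clusters take s(x) = 0 by convention.

The implementation is deliberately self-contained (k-means++ seeding,
Lloyd iterations, multiple restarts, farthest-point repair of empty
clusters) so that every numerical choice is explicit and deterministic
under a seed; library clusterers serve as independent cross-checks in the
test suite, not as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


class ClusteringError(Exception):
    pass


@dataclass
class PointSet:
    """An ordered collection of real vectors with per-point ids."""

    points: np.ndarray  # (n, d)
    ids: list[Hashable] | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        if pts.ndim != 2 or pts.shape[0] < 1:
            raise ClusteringError(f"need an (n, d) array with n >= 1, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ClusteringError("points contain non-finite entries")
        self.points = pts
        if self.ids is None:
            self.ids = list(range(pts.shape[0]))
        if len(self.ids) != pts.shape[0]:
            raise ClusteringError("ids length does not match number of points")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class ClusteringConfig:
    """Settings for k selection and the underlying k-means runs."""

    k_min: int = 2
    k_max: int = 10
    restarts: int = 10
    max_iters: int = 300
    tol: float = 1e-6  # relative WCSS change convergence threshold
    seed: int = 0

    def k_range(self, n: int) -> range:
        hi = min(self.k_max, n - 1)
        if not (2 <= self.k_min <= hi):
            raise ClusteringError(
                f"invalid k range [{self.k_min}, {hi}] for n={n}"
            )
        return range(self.k_min, hi + 1)


@dataclass
class ClusteringResult:
    k: int
    assignments: np.ndarray  # (n,) cluster index in 0..k-1
    centers: np.ndarray  # (k, d)
    wcss: float


@dataclass
class SilhouetteProfile:
    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    asw: float = field(init=False)

    def __post_init__(self) -> None:
        self.asw = float(np.mean(self.s))


def wcss(points: PointSet | np.ndarray, assignments: Sequence[int], centers: np.ndarray) -> float:
    """Within-cluster sum of squared distances to the assigned centers."""
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    centers = np.asarray(centers, dtype=float)
    if centers.ndim == 1:
        centers = centers[:, None]
    labels = np.asarray(assignments, dtype=int)
    if labels.shape[0] != pts.shape[0]:
        raise ClusteringError("assignments length does not match number of points")
    if centers.shape[1] != pts.shape[1]:
        raise ClusteringError(
            f"dimension mismatch: points d={pts.shape[1]}, centers d={centers.shape[1]}"
        )
    diffs = pts - centers[labels]
    return float(np.sum(diffs * diffs))


def _kmeans_pp_init(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers by squared-distance sampling."""
    n = pts.shape[0]
    centers = np.empty((k, pts.shape[1]))
    centers[0] = pts[rng.integers(n)]
    d2 = np.sum((pts - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[j] = pts[rng.integers(n)]
            continue
        probs = d2 / total
        centers[j] = pts[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((pts - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(
    pts: np.ndarray, centers: np.ndarray, max_iters: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    prev = np.inf
    labels = np.zeros(pts.shape[0], dtype=int)
    for _ in range(max_iters):
        d = cdist(pts, centers)
        labels = np.argmin(d, axis=1)
        # repair empty clusters: reseed from the point farthest from its center
        for j in range(centers.shape[0]):
            if not np.any(labels == j):
                far = int(np.argmax(d[np.arange(len(labels)), labels]))
                labels[far] = j
        for j in range(centers.shape[0]):
            centers[j] = pts[labels == j].mean(axis=0)
        cur = wcss(pts, labels, centers)
        if prev - cur <= tol * max(prev, 1e-300):
            prev = cur
            break
        prev = cur
    return labels, centers, float(prev if np.isfinite(prev) else wcss(pts, labels, centers))


def kmeans(points: PointSet | np.ndarray, k: int, config: ClusteringConfig | None = None) -> ClusteringResult:
    """Best-of-restarts Lloyd k-means with k-means++ seeding.

    Deterministic for a fixed config seed; every cluster in the returned
    result is non-empty and the reported WCSS is recomputed from the final
    assignments and centers.
    """
    ps = points if isinstance(points, PointSet) else PointSet(points)
    cfg = config or ClusteringConfig()
    n = len(ps)
    if not (1 <= k < n) and k != n:
        raise ClusteringError(f"need 1 <= k <= n, got k={k}, n={n}")
    pts = ps.points
    if k == n:
        return ClusteringResult(
            k=k, assignments=np.arange(n), centers=pts.copy(), wcss=0.0
        )
    best: ClusteringResult | None = None
    for r in range(cfg.restarts):
        rng = np.random.default_rng((cfg.seed, k, r))
        centers = _kmeans_pp_init(pts, k, rng)
        labels, centers, w = _lloyd(pts, centers.copy(), cfg.max_iters, cfg.tol)
        if best is None or w < best.wcss - 1e-12:
            best = ClusteringResult(k=k, assignments=labels, centers=centers, wcss=w)
    assert best is not None
    return best


def silhouette(points: PointSet | np.ndarray, assignments: Sequence[int]) -> SilhouetteProfile:
    """Per-point silhouette values and the average silhouette width.

    Requires at least two clusters; points in singleton clusters get s = 0.
    """
    ps = points if isinstance(points, PointSet) else PointSet(points)
    labels = np.asarray(assignments, dtype=int)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ClusteringError("silhouette is undefined for a single cluster")
    d = cdist(ps.points, ps.points)
    n = len(ps)
    a = np.zeros(n)
    b = np.full(n, np.inf)
    for lab in uniq:
        mask = labels == lab
        size = int(mask.sum())
        within = d[:, mask]
        for i in range(n):
            if labels[i] == lab:
                a[i] = within[i].sum() / (size - 1) if size > 1 else 0.0
            else:
                b[i] = min(b[i], within[i].mean())
    s = np.zeros(n)
    for i in range(n):
        if np.sum(labels == labels[i]) == 1:
            s[i] = 0.0  # singleton convention
        else:
            denom = max(a[i], b[i])
            s[i] = 0.0 if denom == 0 else (b[i] - a[i]) / denom
    return SilhouetteProfile(a=a, b=b, s=s)


def select_k(
    points: PointSet | np.ndarray, config: ClusteringConfig | None = None
) -> tuple[ClusteringResult, SilhouetteProfile, pd.DataFrame]:
    """Scan k in [k_min, k_max], return the clustering maximising the ASW.

    Also returns a per-k diagnostic table (k, wcss, asw) for reporting.
    Exact ASW ties resolve to the smaller k.
    """
    ps = points if isinstance(points, PointSet) else PointSet(points)
    cfg = config or ClusteringConfig()
    n = len(ps)
    if n < 3:
        raise ClusteringError(f"k selection needs at least 3 points, got {n}")
    rows = []
    best: tuple[ClusteringResult, SilhouetteProfile] | None = None
    for k in cfg.k_range(n):
        res = kmeans(ps, k, cfg)
        prof = silhouette(ps, res.assignments)
        rows.append({"k": k, "wcss": res.wcss, "asw": prof.asw})
        if best is None or prof.asw > best[1].asw + 1e-12:
            best = (res, prof)
    assert best is not None
    return best[0], best[1], pd.DataFrame(rows)


def canonical_order(ids: Sequence, points: np.ndarray) -> PointSet:
    """Sort points by id so that clustering is invariant to input shuffling."""
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    return PointSet(points=np.asarray(points, dtype=float)[order], ids=[ids[i] for i in order])
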