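"""Density-based temporal segmentation of a smoothed curve sample.

Each time point t is mapped to a feature vector concatenating, across all N
curves, the fitted value and scaled first/second derivatives
[f_i(t), theta1*f_i'(t), theta2*f_i''(t)].  Features are standardized across
time, reduced by PCA, and clustered with DBSCAN; the (eps, minPts) pair is
chosen by a silhouette grid search with eps candidates taken from quantiles
of the k-nearest-neighbour distance distribution.  Noise labels are repaired
by nearest-neighbour propagation along the time axis, and contiguous label
runs become the segments that the ranking stage weighs and integrates over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances, silhouette_score as _sk_silhouette
from sklearn.neighbors import NearestNeighbors

from .curves import SmoothedCurveSet, TimeGrid, evaluate
from .exceptions import (
    AllNoiseError,
    DegenerateFeaturesError,
    DegenerateGridError,
    InvalidArgumentError,
    UndefinedSilhouetteError,
)

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "DbscanParams",
    "SegmentationResult",
    "build_time_features",
    "pca_reduce",
    "eps_grid",
    "run_dbscan",
    "silhouette_score",
    "select_params",
    "repair_noise_labels",
    "extract_segments",
    "single_segment_result",
]

_ZERO_VAR_TOL = 1e-12


@dataclass
class FeatureConfig:
    """Tuning constants of the feature construction and parameter search."""

    theta1: float = 1.0  # first-derivative scale
    theta2: float = 1.0  # second-derivative scale
    var_threshold: float = 0.95  # PCA retained cumulative variance
    q_max: int = 10  # cap on retained components
    knn_k: int = 4  # k for the k-NN eps search range
    n_eps: int = 20  # eps candidates between the 10% and 95% quantiles
    min_segment_len: int = 2  # runs shorter than this are merged

    def __post_init__(self):
        if self.theta1 < 0 or self.theta2 < 0:
            raise InvalidArgumentError("derivative scales must be nonnegative")
        if not (0 < self.var_threshold <= 1):
            raise InvalidArgumentError("var_threshold must lie in (0, 1]")
        if self.q_max < 1 or self.n_eps < 1 or self.knn_k < 1:
            raise InvalidArgumentError("q_max, n_eps and knn_k must be positive")


@dataclass
class FeatureMatrix:
    """Standardized, PCA-reduced per-time-point features."""

    grid: TimeGrid
    Z: np.ndarray  # (T, q)
    q: int
    explained_variance: float


@dataclass(frozen=True)
class DbscanParams:
    eps: float
    min_pts: int

    def __post_init__(self):
        if self.eps <= 0:
            raise InvalidArgumentError("eps must be positive")
        if self.min_pts < 2:
            raise InvalidArgumentError("min_pts must be at least 2")


@dataclass
class SegmentationResult:
    """Contiguous time segments with the parameters that produced them.

    ``segments`` holds inclusive index ranges (i0, i1) into the grid;
    ``time_bounds`` holds the matching contiguous [a, b] intervals (internal
    boundaries at midpoints between adjacent grid times), which exactly cover
    the grid range.  ``silhouette`` is None when the search fell back to a
    single segment.
    """

    labels: np.ndarray
    breakpoints: np.ndarray
    segments: list[tuple[int, int]]
    time_bounds: list[tuple[float, float]]
    params: DbscanParams | None
    silhouette: float | None
    fallback: bool = False

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def to_dict(self) -> dict:
        return {
            "labels": [int(x) for x in self.labels],
            "breakpoints": [float(x) for x in self.breakpoints],
            "segments": [[int(a), int(b)] for a, b in self.segments],
            "time_bounds": [[float(a), float(b)] for a, b in self.time_bounds],
            "eps": None if self.params is None else self.params.eps,
            "min_pts": None if self.params is None else self.params.min_pts,
            "silhouette": self.silhouette,
            "fallback": self.fallback,
            "n_segments": self.n_segments,
        }


def build_time_features(smoothed: SmoothedCurveSet, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Per-time features [f_i, theta1*f_i', theta2*f_i''] over all curves,
    standardized column-wise across time (zero-variance columns dropped)."""
    cfg = cfg or FeatureConfig()
    pts = smoothed.grid.points
    f0 = evaluate(smoothed, pts, 0)
    blocks = [f0.T]
    if cfg.theta1 > 0:
        blocks.append(cfg.theta1 * evaluate(smoothed, pts, 1).T)
    if cfg.theta2 > 0:
        blocks.append(cfg.theta2 * evaluate(smoothed, pts, 2).T)
    X = np.hstack(blocks)  # (T, up to 3N)
    sd = X.std(axis=0)
    scale = max(1.0, np.abs(X).max())
    keep = sd > _ZERO_VAR_TOL * scale
    if not keep.any():
        raise DegenerateFeaturesError("all feature columns are constant across time")
    X = X[:, keep]
    return (X - X.mean(axis=0)) / X.std(axis=0)


def pca_reduce(features: np.ndarray, cfg: FeatureConfig | None = None,
               grid: TimeGrid | None = None) -> FeatureMatrix:
    """Retain the smallest q components reaching ``var_threshold`` cumulative
    variance, capped at ``q_max``."""
    cfg = cfg or FeatureConfig()
    T, p = features.shape
    if p < 1:
        raise DegenerateFeaturesError("empty feature matrix")
    n_comp = min(T, p)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(features)
    ratios = pca.explained_variance_ratio_
    if ratios.size == 0 or ratios[0] <= 0:
        raise DegenerateFeaturesError("no nonzero singular value in the features")
    cum = np.cumsum(ratios)
    q = int(np.searchsorted(cum, cfg.var_threshold - 1e-12) + 1)
    q = min(q, cfg.q_max, n_comp)
    return FeatureMatrix(grid=grid, Z=scores[:, :q], q=q, explained_variance=float(cum[q - 1]))


def eps_grid(features: FeatureMatrix | np.ndarray, k: int = 4, n_eps: int = 20) -> np.ndarray:
    """eps candidates at evenly spaced quantiles (10%..95%) of the k-NN distances."""
    Z = features.Z if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    T = Z.shape[0]
    if k >= T:
        raise InvalidArgumentError("k must be smaller than the number of time points")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    dists, _ = nn.kneighbors(Z)
    kdist = dists[:, k]  # distance to the k-th neighbour, self excluded
    if np.all(kdist <= 0):
        raise DegenerateGridError("all k-NN distances are zero (duplicated features)")
    qs = np.linspace(0.10, 0.95, n_eps) if n_eps > 1 else np.array([0.10])
    grid = np.quantile(kdist, qs)
    grid = np.unique(grid[grid > 0])
    if grid.size == 0:
        raise DegenerateGridError("eps quantile range collapsed to zero")
    return grid


def run_dbscan(features: FeatureMatrix | np.ndarray, params: DbscanParams,
               distances: np.ndarray | None = None) -> np.ndarray:
    """Standard DBSCAN labels with noise relabelled 0 and clusters 1..k."""
    if distances is not None:
        labels = DBSCAN(eps=params.eps, min_samples=params.min_pts,
                        metric="precomputed").fit_predict(distances)
    else:
        Z = features.Z if isinstance(features, FeatureMatrix) else np.asarray(features, float)
        labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(Z)
    return np.where(labels < 0, 0, labels + 1)


def silhouette_score(features: FeatureMatrix | np.ndarray, labels: np.ndarray,
                     distances: np.ndarray | None = None) -> float:
    """Mean silhouette (b - a)/max(a, b) over all points; noise (label 0)
    excluded; singleton clusters contribute 0."""
    labels = np.asarray(labels)
    mask = labels != 0
    kept = labels[mask]
    if np.unique(kept).size < 2:
        raise UndefinedSilhouetteError("silhouette needs at least two clusters")
    if distances is None:
        Z = features.Z if isinstance(features, FeatureMatrix) else np.asarray(features, float)
        distances = pairwise_distances(Z)
    D = distances[np.ix_(mask, mask)]
    return float(_sk_silhouette(D, kept, metric="precomputed"))


def repair_noise_labels(labels: np.ndarray) -> np.ndarray:
    """Replace noise labels (0) by the nearest non-noise label along the time
    axis; equidistant ties take the earlier (left) neighbour."""
    labels = np.asarray(labels).copy()
    nz = np.flatnonzero(labels != 0)
    if nz.size == 0:
        raise AllNoiseError("every time point was labelled noise")
    for j in np.flatnonzero(labels == 0):
        pos = np.searchsorted(nz, j)
        left = nz[pos - 1] if pos > 0 else None
        right = nz[pos] if pos < nz.size else None
        if left is None:
            labels[j] = labels[right]
        elif right is None:
            labels[j] = labels[left]
        else:
            labels[j] = labels[left] if (j - left) <= (right - j) else labels[right]
    return labels


def _runs(labels: np.ndarray) -> list[list]:
    runs = []
    start = 0
    for j in range(1, labels.size + 1):
        if j == labels.size or labels[j] != labels[start]:
            runs.append([start, j - 1, labels[start]])
            start = j
    return runs


def _merge_adjacent_same(runs: list[list]) -> list[list]:
    out = [runs[0]]
    for r in runs[1:]:
        if r[2] == out[-1][2]:
            out[-1][1] = r[1]
        else:
            out.append(r)
    return out


def extract_segments(labels: np.ndarray, grid: TimeGrid,
                     min_segment_len: int = 2,
                     params: DbscanParams | None = None,
                     silhouette: float | None = None,
                     fallback: bool = False) -> SegmentationResult:
    """Contiguous segments from repaired labels; runs shorter than
    ``min_segment_len`` are merged into the longer adjacent run (ties left)."""
    labels = np.asarray(labels)
    if labels.size != grid.n_times:
        raise InvalidArgumentError("labels length must match the grid")
    runs = _merge_adjacent_same(_runs(labels))
    while len(runs) > 1:
        lens = [r[1] - r[0] + 1 for r in runs]
        short = [i for i, L in enumerate(lens) if L < min_segment_len]
        if not short:
            break
        i = short[0]
        if i == 0:
            target = 1
        elif i == len(runs) - 1:
            target = i - 1
        else:
            target = i - 1 if lens[i - 1] >= lens[i + 1] else i + 1
        runs[i][2] = runs[target][2]
        runs = _merge_adjacent_same(runs)

    final_labels = np.empty(labels.size, dtype=int)
    segments, time_bounds, breakpoints = [], [], []
    pts = grid.points
    for idx, (i0, i1, lab) in enumerate(runs):
        final_labels[i0 : i1 + 1] = lab
        segments.append((i0, i1))
        a = grid.lo if idx == 0 else 0.5 * (pts[i0 - 1] + pts[i0])
        b = grid.hi if idx == len(runs) - 1 else 0.5 * (pts[i1] + pts[i1 + 1])
        time_bounds.append((a, b))
        if idx > 0:
            breakpoints.append(a)
    return SegmentationResult(
        labels=final_labels,
        breakpoints=np.asarray(breakpoints),
        segments=segments,
        time_bounds=time_bounds,
        params=params,
        silhouette=silhouette,
        fallback=fallback,
    )


def single_segment_result(grid: TimeGrid) -> SegmentationResult:
    """Degenerate single-segment cover used when no valid clustering exists."""
    return SegmentationResult(
        labels=np.ones(grid.n_times, dtype=int),
        breakpoints=np.asarray([]),
        segments=[(0, grid.n_times - 1)],
        time_bounds=[(grid.lo, grid.hi)],
        params=None,
        silhouette=None,
        fallback=True,
    )


def select_params(features: FeatureMatrix, cfg: FeatureConfig | None = None
                  ) -> tuple[DbscanParams | None, SegmentationResult]:
    """Silhouette grid search over eps (k-NN quantiles) x minPts.

    minPts spans 2q .. min(40, T // 5); when the lower bound exceeds the
    upper the grid collapses to the single value max(2, upper).  Ties favour
    smaller minPts, then smaller eps.  With no pair yielding two or more
    clusters the search falls back to a single segment (never an error).
    """
    cfg = cfg or FeatureConfig()
    Z = features.Z
    T = Z.shape[0]
    grid = features.grid
    D = pairwise_distances(Z)
    try:
        eps_vals = eps_grid(features, k=min(cfg.knn_k, T - 1), n_eps=cfg.n_eps)
    except DegenerateGridError:
        return None, single_segment_result(grid)

    lo = max(2, 2 * features.q)
    hi = min(40, T // 5)
    if hi < lo:
        # the twice-the-retained-dimension heuristic overshoots the stable
        # upper end at small T; keep the search over the small-minPts range
        # the silhouette optimum actually lives in
        lo = 2
        hi = max(2, hi)
    step = max(1, (hi - lo) // 8)
    minpts_vals = list(range(lo, hi + 1, step))

    best = None  # (sc, min_pts, eps, repaired_labels)
    for mp in minpts_vals:
        for eps in eps_vals:
            params = DbscanParams(eps=float(eps), min_pts=int(mp))
            labels = run_dbscan(features, params, distances=D)
            if not np.any(labels != 0):
                continue
            repaired = repair_noise_labels(labels)
            if np.unique(repaired).size < 2:
                continue
            try:
                sc = silhouette_score(features, repaired, distances=D)
            except UndefinedSilhouetteError:
                continue
            if best is None or sc > best[0]:
                best = (sc, mp, float(eps), repaired)
    if best is None:
        return None, single_segment_result(grid)
    sc, mp, eps, repaired = best
    params = DbscanParams(eps=eps, min_pts=mp)
    seg = extract_segments(repaired, grid, cfg.min_segment_len,
                           params=params, silhouette=sc)
    return params, seg
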