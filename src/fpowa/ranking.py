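"""Curve-ranking methods: the FP-OWA pipeline and four baselines.

FP-OWA (functional piecewise ordered weighted averaging):
impute -> GCV spline smoothing -> derivative features -> DBSCAN temporal
segmentation -> per-segment modified-band-depth weights w_i (Eqs: mean MBD
normalized across segments) -> per-segment curve integrals ranked ascending
(average ties) -> Score_j = sum_i w_i R_ij, ranked descending.

Baselines share one call signature (raw curves + config -> RankingResult):

* fpca_rank   — explained-variance-weighted composite of functional-PCA scores;
* wlr_rank    — piecewise-linear interpolants segmented at pairwise crossing
                times, length-proportional weights, within-segment mean ranks;
* depth_rank  — global h-mode depth or random Tukey depth, ranked descending.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import curves as _c
from . import depth as _d
from . import segmentation as _s
from .exceptions import (
    DegenerateFeaturesError,
    InsufficientSupportError,
    InvalidArgumentError,
)

__all__ = [
    "FpowaConfig",
    "SegmentWeights",
    "RankMatrix",
    "RankingResult",
    "segment_weights",
    "segment_rank_matrix",
    "aggregate_scores",
    "fp_owa",
    "fpca_rank",
    "wlr_rank",
    "depth_rank",
    "get_ranker",
    "RANKERS",
]


@dataclass
class FpowaConfig:
    """Shared configuration for all rankers.

    n_basis / lambda_grid control the spline smoother (None = defaults:
    min(T-2, 25) basis functions, 25 log-spaced penalties in [1e-6, 1e2]);
    ``prefilter`` optionally applies a robust filter before smoothing.
    """

    n_basis: int | None = None
    lambda_grid: np.ndarray | None = None
    shared_lambda: bool = False
    features: _s.FeatureConfig = field(default_factory=_s.FeatureConfig)
    prefilter: str = "none"  # none | huber | hampel
    filter_window: int = 7
    hampel_k: float = 3.0
    huber_c: float = 1.5
    ascending: bool = False  # invert the final ordering
    fpca_var_threshold: float = 0.90
    fpca_first_pc: bool = False
    hmode_bandwidth: object = "auto"
    rtd_projections: int = 50
    seed: int = 0  # randomness used by RTD projections only

    def with_(self, **kw) -> "FpowaConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SegmentWeights:
    mean_depths: np.ndarray  # (m,)
    weights: np.ndarray  # (m,), nonnegative, sum 1


@dataclass
class RankMatrix:
    ranks: np.ndarray  # (m, N) average-tie ranks, ascending in the integral
    integrals: np.ndarray  # (m, N)


@dataclass
class RankingResult:
    scores: np.ndarray  # (N,)
    ranking: np.ndarray  # (N,) 1 = largest score (average ties)
    method: str
    unit_names: list[str] | None = None
    diagnostics: dict = field(default_factory=dict)


def _final_ranking(scores: np.ndarray, ascending: bool = False) -> np.ndarray:
    s = scores if ascending else -scores
    return rankdata(s, method="average")


def _prefilter(raw: _c.RawCurveSet, cfg: FpowaConfig) -> _c.RawCurveSet:
    if cfg.prefilter == "none":
        return raw
    if cfg.prefilter == "hampel":
        return _c.hampel_filter(raw, cfg.filter_window, cfg.hampel_k)
    if cfg.prefilter == "huber":
        return _c.huber_filter(raw, cfg.filter_window, cfg.huber_c)
    raise InvalidArgumentError(f"unknown prefilter {cfg.prefilter!r}")


def _smooth(raw: _c.RawCurveSet, cfg: FpowaConfig) -> _c.SmoothedCurveSet:
    basis = _c.build_basis(raw.grid, cfg.n_basis)
    if not raw.fully_observed:
        raw = _c.impute_missing(raw, basis, cfg.lambda_grid)
    return _c.select_lambda_gcv(raw, basis, cfg.lambda_grid, shared=cfg.shared_lambda)


def segment_weights(smoothed: _c.SmoothedCurveSet, seg: _s.SegmentationResult) -> SegmentWeights:
    """Mean MBD per segment, normalized across segments."""
    fitted = smoothed.fitted_values()
    means = np.empty(seg.n_segments)
    for i, (i0, i1) in enumerate(seg.segments):
        d = _d.mbd_fast(fitted[:, i0 : i1 + 1])
        means[i] = d.values.mean()
    total = means.sum()
    weights = means / total if total > 0 else np.full(seg.n_segments, 1.0 / seg.n_segments)
    return SegmentWeights(mean_depths=means, weights=weights)


def segment_rank_matrix(smoothed: _c.SmoothedCurveSet, seg: _s.SegmentationResult) -> RankMatrix:
    """Per-segment exact curve integrals, ranked ascending with average ties."""
    m = seg.n_segments
    N = smoothed.n_curves
    integrals = np.empty((m, N))
    for i, (a, b) in enumerate(seg.time_bounds):
        integrals[i] = _c.integrate_segment(smoothed, a, b)
    ranks = rankdata(integrals, method="average", axis=1)
    return RankMatrix(ranks=ranks, integrals=integrals)


def aggregate_scores(weights: SegmentWeights, ranks: RankMatrix,
                     method: str = "fpowa", ascending: bool = False) -> RankingResult:
    """Score_j = sum_i w_i R_ij; final ranking descending in the score."""
    if weights.weights.size != ranks.ranks.shape[0]:
        raise InvalidArgumentError("weights and rank matrix disagree on m")
    scores = weights.weights @ ranks.ranks
    return RankingResult(
        scores=scores,
        ranking=_final_ranking(scores, ascending),
        method=method,
    )


def fp_owa(raw: _c.RawCurveSet, config: FpowaConfig | None = None) -> RankingResult:
    """The full adaptive piecewise ordered-weighted-averaging ranking."""
    cfg = config or FpowaConfig()
    filtered = _prefilter(raw, cfg)
    smoothed = _smooth(filtered, cfg)
    try:
        X = _s.build_time_features(smoothed, cfg.features)
        fm = _s.pca_reduce(X, cfg.features, grid=raw.grid)
        params, seg = _s.select_params(fm, cfg.features)
    except DegenerateFeaturesError:
        seg = _s.single_segment_result(raw.grid)
    w = segment_weights(smoothed, seg)
    R = segment_rank_matrix(smoothed, seg)
    res = aggregate_scores(w, R, method="fpowa", ascending=cfg.ascending)
    res.unit_names = list(raw.unit_names)
    res.diagnostics = {
        "segmentation": seg,
        "segment_weights": w,
        "rank_matrix": R,
        "smoothed": smoothed,
    }
    return res


def _trapezoid_weights(pts: np.ndarray) -> np.ndarray:
    w = np.zeros(pts.size)
    dt = np.diff(pts)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    return w


def fpca_rank(raw: _c.RawCurveSet, config: FpowaConfig | None = None) -> RankingResult:
    """Composite functional-PCA score ranking.

    Curves are smoothed with the shared GCV pipeline; the sample covariance
    on the grid is eigen-decomposed (trapezoid quadrature); components are
    retained to 90% cumulative variance; each eigenfunction's sign is fixed
    so its inner product with the constant function is nonnegative;
    Score_i = sum_k (lambda_k / sum lambda) xi_ik, ranked descending.
    """
    cfg = config or FpowaConfig()
    if raw.n_curves < 2:
        raise InsufficientSupportError("FPCA ranking needs at least 2 curves")
    smoothed = _smooth(_prefilter(raw, cfg), cfg)
    F = smoothed.fitted_values()  # (N, T)
    pts = raw.grid.points
    w = _trapezoid_weights(pts)
    Xc = F - F.mean(axis=0)
    N = F.shape[0]
    sw = np.sqrt(w)
    M = (Xc * sw).T @ (Xc * sw) / (N - 1)  # W^{1/2} C W^{1/2}
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 1e-300:
        scores = np.zeros(N)
    else:
        cum = np.cumsum(evals) / total
        K = 1 if cfg.fpca_first_pc else int(np.searchsorted(cum, cfg.fpca_var_threshold - 1e-12) + 1)
        K = min(K, evals.size)
        phis = evecs[:, :K] / sw[:, None]  # eigenfunctions, L2(w)-orthonormal
        sign = np.sign(w @ phis)
        for k in np.flatnonzero(sign == 0):  # fallback: first nonzero loading positive
            col = phis[:, k]
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            sign[k] = 1.0 if nz.size == 0 or col[nz[0]] >= 0 else -1.0
        phis = phis * sign
        xi = (Xc * w) @ phis  # (N, K)
        wk = evals[:K] / evals[:K].sum()
        scores = xi @ wk
    res = RankingResult(scores=scores, ranking=_final_ranking(scores, cfg.ascending),
                        method="fpca", unit_names=list(raw.unit_names))
    return res


def _interp_on_grid(raw: _c.RawCurveSet, cfg: FpowaConfig) -> np.ndarray:
    """Piecewise-linear interpolant values at all grid times.

    Interior gaps join the neighbouring observed points directly; missing
    endpoints are filled from the spline-imputation pipeline first.
    """
    pts = raw.grid.points
    vals = raw.values.copy()
    mask = raw.observed_mask.copy()
    end_missing = ~mask[:, 0] | ~mask[:, -1]
    if end_missing.any():
        imputed = _c.impute_missing(raw, _c.build_basis(raw.grid, cfg.n_basis), cfg.lambda_grid)
        for j in (0, raw.n_times - 1):
            fill = ~mask[:, j]
            vals[fill, j] = imputed.values[fill, j]
            mask[fill, j] = True
    V = np.empty_like(vals)
    for i in range(raw.n_curves):
        obs = mask[i]
        V[i] = np.interp(pts, pts[obs], vals[i, obs])
    return V


def _crossing_times(V: np.ndarray, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    n = V.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = V[iu] - V[ju]  # (pairs, T)
    d0, d1 = d[:, :-1], d[:, 1:]
    cross = d0 * d1 < 0  # strict sign change; tangential touching excluded
    pi, ki = np.nonzero(cross)
    t0 = pts[ki]
    dt = pts[ki + 1] - pts[ki]
    tc = t0 + d0[pi, ki] / (d0[pi, ki] - d1[pi, ki]) * dt
    # a curve pair meeting exactly at one grid point crosses there when the
    # neighbouring differences have opposite signs
    zero = d[:, 1:-1] == 0
    if zero.any():
        pz, kz = np.nonzero(zero)
        genuine = d[pz, kz] * d[pz, kz + 2] < 0
        tc = np.concatenate([tc, pts[kz[genuine] + 1]])
    if tc.size == 0:
        return np.asarray([])
    tc = np.sort(tc)
    keep = np.concatenate([[True], np.diff(tc) > tol])
    return tc[keep]


def _pl_values_at(V: np.ndarray, pts: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate every curve's piecewise-linear interpolant at points x: (N, len(x))."""
    idx = np.clip(np.searchsorted(pts, x, side="right") - 1, 0, pts.size - 2)
    t0, t1 = pts[idx], pts[idx + 1]
    frac = np.where(t1 > t0, (x - t0) / (t1 - t0), 0.0)
    return V[:, idx] * (1 - frac) + V[:, idx + 1] * frac


def wlr_rank(raw: _c.RawCurveSet, config: FpowaConfig | None = None) -> RankingResult:
    """Weighted piecewise-linear ranking segmented at curve crossings.

    Breakpoints are the deduplicated crossing times of all curve pairs;
    segment weights are proportional to segment length; within each segment
    curves are ranked ascending by their segment mean value (average ties).
    """
    cfg = config or FpowaConfig()
    if raw.n_curves < 2:
        raise InsufficientSupportError("WLR needs at least 2 curves")
    pts = raw.grid.points
    V = _interp_on_grid(raw, cfg)
    crossings = _crossing_times(V, pts)
    crossings = crossings[(crossings > pts[0] + 1e-12) & (crossings < pts[-1] - 1e-12)]
    bounds = np.concatenate([[pts[0]], crossings, [pts[-1]]])
    # exact integral of the piecewise-linear interpolant up to each boundary
    from scipy.integrate import cumulative_trapezoid

    cum = np.concatenate(
        [np.zeros((V.shape[0], 1)), cumulative_trapezoid(V, pts, axis=1)], axis=1
    )
    idx = np.clip(np.searchsorted(pts, bounds, side="right") - 1, 0, pts.size - 2)
    vb = _pl_values_at(V, pts, bounds)
    Ib = cum[:, idx] + 0.5 * (vb + V[:, idx]) * (bounds - pts[idx])
    seg_int = np.diff(Ib, axis=1)  # (N, m)
    seg_len = np.diff(bounds)
    weights = seg_len / seg_len.sum()
    means = seg_int / seg_len
    ranks = rankdata(means.T, method="average", axis=1)  # (m, N)
    scores = weights @ ranks
    res = RankingResult(scores=scores, ranking=_final_ranking(scores, cfg.ascending),
                        method="wlr", unit_names=list(raw.unit_names))
    res.diagnostics = {"breakpoints": crossings, "weights": weights}
    return res


def depth_rank(raw: _c.RawCurveSet, method: str = "hmode",
               config: FpowaConfig | None = None) -> RankingResult:
    """Rank curves by decreasing global depth (h-mode or random Tukey)."""
    cfg = config or FpowaConfig()
    if raw.n_curves < 2:
        raise InsufficientSupportError("depth ranking needs at least 2 curves")
    smoothed = _smooth(_prefilter(raw, cfg), cfg)
    F = smoothed.fitted_values()
    pts = raw.grid.points
    if method == "hmode":
        d = _d.h_mode_depth(F, bandwidth=cfg.hmode_bandwidth, times=pts)
    elif method == "rtd":
        d = _d.random_tukey_depth(F, n_projections=cfg.rtd_projections,
                                  seed=cfg.seed, times=pts)
    else:
        raise InvalidArgumentError("depth method must be 'hmode' or 'rtd'")
    return RankingResult(scores=d.values, ranking=_final_ranking(d.values, cfg.ascending),
                         method=d.method, unit_names=list(raw.unit_names))


RANKERS = {
    "fpowa": fp_owa,
    "fpowa_huber": lambda raw, cfg=None: fp_owa(raw, (cfg or FpowaConfig()).with_(prefilter="huber")),
    "fpowa_hampel": lambda raw, cfg=None: fp_owa(raw, (cfg or FpowaConfig()).with_(prefilter="hampel")),
    "fpca": fpca_rank,
    "wlr": wlr_rank,
    "hmode": lambda raw, cfg=None: depth_rank(raw, "hmode", cfg),
    "rtd": lambda raw, cfg=None: depth_rank(raw, "rtd", cfg),
}


def get_ranker(name: str):
    try:
        return RANKERS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown method {name!r}; choose from {sorted(RANKERS)}"
        ) from None
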