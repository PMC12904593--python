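"""Statistical depth measures for samples of curves on a common grid.

Modified band depth (MBD) of curve j in a sample of N curves is the average,
over all unordered pairs of sample curves and over grid points, of the
proportion of time curve j lies inside the band spanned by the pair; pairs
containing j itself always cover it.  The fast variant replaces explicit pair
enumeration by per-time-point order statistics and is exactly equivalent to
the naive count, ties included.

h-mode depth is a kernel-density-style centrality (mean Gaussian kernel of
L2 distances to the sample); random Tukey depth is the minimum univariate
half-space depth over random one-dimensional projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientSupportError, InvalidArgumentError

__all__ = [
    "DepthVector",
    "mbd_naive",
    "mbd_fast",
    "h_mode_depth",
    "tukey_depth_1d",
    "random_tukey_depth",
]


@dataclass
class DepthVector:
    values: np.ndarray
    method: str
    context: str = "global"


def _as_matrix(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise InvalidArgumentError("values must be an N x L matrix")
    if v.shape[0] < 2:
        raise InsufficientSupportError("depth requires at least 2 curves")
    return v


def mbd_naive(values) -> DepthVector:
    """Reference MBD by explicit enumeration of all unordered curve pairs."""
    v = _as_matrix(values)
    n, L = v.shape
    prop = np.zeros(n)
    for k in range(n):
        for l in range(k + 1, n):
            lo = np.minimum(v[k], v[l])
            hi = np.maximum(v[k], v[l])
            prop += ((v >= lo) & (v <= hi)).mean(axis=1)
    n_pairs = n * (n - 1) / 2
    return DepthVector(prop / n_pairs, method="mbd_naive")


def mbd_fast(values) -> DepthVector:
    """Rank-based MBD, exactly equal to :func:`mbd_naive` (ties included).

    At each grid point, with le/ge/eq the number of sample values <=, >=, ==
    the target value, the number of unordered covering pairs is
    le*ge - eq - eq*(eq-1)/2; tie-free this reduces to the familiar
    (N - r)(r - 1) + (N - 1).
    """
    v = _as_matrix(values)
    n, L = v.shape
    total = np.zeros(n)
    for t in range(L):
        col = v[:, t]
        s = np.sort(col)
        le = np.searchsorted(s, col, side="right")
        lt = np.searchsorted(s, col, side="left")
        ge = n - lt
        eq = le - lt
        total += le * ge - eq - eq * (eq - 1) / 2
    n_pairs = n * (n - 1) / 2
    return DepthVector(total / (L * n_pairs), method="mbd_fast")


def _l2_distance_matrix(v: np.ndarray, times: np.ndarray | None) -> np.ndarray:
    n, L = v.shape
    if times is None:
        w = np.full(L, 1.0 / max(L - 1, 1))
        if L > 1:
            w[0] = w[-1] = 0.5 / (L - 1)
    else:
        times = np.asarray(times, float)
        w = np.zeros(L)
        if L > 1:
            dt = np.diff(times)
            w[:-1] += dt / 2
            w[1:] += dt / 2
        else:
            w[:] = 1.0
    G = (v * w) @ v.T
    sq = np.diag(G)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * G, 0.0)
    return np.sqrt(d2)


def h_mode_depth(values, bandwidth="auto", times=None) -> DepthVector:
    """Gaussian-kernel h-mode depth on trapezoid-rule L2 distances.

    ``bandwidth="auto"`` uses the 15th percentile of the nonzero pairwise
    distances (falling back to h = 1 when all curves coincide).  The output
    is rescaled by its maximum so values lie in (0, 1].
    """
    v = _as_matrix(values)
    D = _l2_distance_matrix(v, times)
    if bandwidth == "auto":
        off = D[np.triu_indices(v.shape[0], k=1)]
        pos = off[off > 0]
        h = float(np.percentile(pos, 15)) if pos.size else 1.0
    else:
        h = float(bandwidth)
        if h <= 0:
            raise InvalidArgumentError("bandwidth must be positive")
    depth = np.exp(-((D / h) ** 2) / 2).mean(axis=1)
    return DepthVector(depth / depth.max(), method="hmode")


def tukey_depth_1d(x: float, sample) -> float:
    """Univariate half-space depth min(#{z <= x}, #{z >= x}) / N."""
    z = np.asarray(sample, dtype=float)
    if z.size == 0:
        raise InvalidArgumentError("sample must be nonempty")
    return min(np.count_nonzero(z <= x), np.count_nonzero(z >= x)) / z.size


def random_tukey_depth(values, n_projections: int = 50, seed: int = 0,
                       times=None) -> DepthVector:
    """Minimum univariate Tukey depth over random unit Gaussian directions,
    projecting each curve by the trapezoid-weighted grid inner product."""
    if n_projections < 1:
        raise InvalidArgumentError("n_projections must be positive")
    v = _as_matrix(values)
    n, L = v.shape
    if times is None:
        w = np.full(L, 1.0 / max(L - 1, 1))
        if L > 1:
            w[0] = w[-1] = 0.5 / (L - 1)
    else:
        times = np.asarray(times, float)
        w = np.zeros(L)
        dt = np.diff(times)
        w[:-1] += dt / 2
        w[1:] += dt / 2
    rng = np.random.default_rng(seed)
    U = rng.standard_normal((n_projections, L))
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    proj = (v * w) @ U.T  # (n, P)
    depths = np.full(n, np.inf)
    for p in range(n_projections):
        col = proj[:, p]
        s = np.sort(col)
        le = np.searchsorted(s, col, side="right")
        ge = n - np.searchsorted(s, col, side="left")
        depths = np.minimum(depths, np.minimum(le, ge) / n)
    return DepthVector(depths, method="rtd")
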