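"""Discrete functional observations and penalized spline smoothing.

A sample of N curves observed on a shared time grid is held in a
:class:`RawCurveSet`.  Smoothing fits each curve with a cubic B-spline basis
under a second-derivative roughness penalty,

    J(beta) = sum_j [y(t_j) - sum_k beta_k phi_k(t_j)]^2
              + lambda * int (f'')^2 dt,

with the penalty weight ``lambda`` chosen per curve by generalized
cross-validation GCV(lambda) = SSE(lambda) / (n - df(lambda))^2, where
df is the trace of the smoother operator.  The fitted representation
(:class:`SmoothedCurveSet`) supports exact evaluation, derivatives and
segment integrals, which the segmentation and ranking stages build on.

The module also provides spline-based imputation of missing entries and
the Hampel / Huber sliding-window robust pre-filters used by the
outlier-hardened ranking variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from numpy.polynomial.legendre import leggauss

from .exceptions import (
    DegenerateGCVError,
    IllPosedFitError,
    InsufficientSupportError,
    InvalidArgumentError,
)

__all__ = [
    "TimeGrid",
    "RawCurveSet",
    "SplineBasis",
    "SmoothedCurveSet",
    "build_basis",
    "fit_penalized",
    "select_lambda_gcv",
    "impute_missing",
    "evaluate",
    "integrate_segment",
    "hampel_filter",
    "huber_filter",
    "default_lambda_grid",
]

#: consistency factor making the MAD an unbiased sigma estimate under normality
MAD_SCALE = 1.4826

_SPLINE_DEGREE = 3  # cubic, order 4


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing observation times t_1 < ... < t_T.

    ``dates`` optionally carries the calendar dates the points were mapped
    from (used by the monthly-weight summaries); it plays no role in any
    numerical computation.
    """

    points: np.ndarray
    dates: tuple | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 4:
            raise InvalidArgumentError("time grid needs at least 4 ordered points")
        if not np.all(np.diff(pts) > 0):
            raise InvalidArgumentError("time grid must be strictly increasing")

    @property
    def n_times(self) -> int:
        return self.points.size

    @property
    def lo(self) -> float:
        return float(self.points[0])

    @property
    def hi(self) -> float:
        return float(self.points[-1])


@dataclass
class RawCurveSet:
    """N curves observed (possibly with gaps) on a common :class:`TimeGrid`."""

    grid: TimeGrid
    values: np.ndarray
    observed_mask: np.ndarray | None = None
    unit_names: Sequence[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be an N x T matrix")
        n, t = self.values.shape
        if t != self.grid.n_times:
            raise InvalidArgumentError("values width must match the time grid")
        if self.observed_mask is None:
            self.observed_mask = ~np.isnan(self.values)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != self.values.shape:
            raise InvalidArgumentError("observed_mask must match values' shape")
        if self.unit_names is None:
            self.unit_names = [f"unit_{i + 1}" for i in range(n)]
        self.unit_names = list(self.unit_names)
        if len(self.unit_names) != n:
            raise InvalidArgumentError("one unit name per curve required")
        counts = self.observed_mask.sum(axis=1)
        if np.any(counts < 4):
            bad = self.unit_names[int(np.argmin(counts))]
            raise InsufficientSupportError(
                f"curve {bad!r} has fewer than 4 observed points"
            )

    @property
    def n_curves(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def fully_observed(self) -> bool:
        return bool(self.observed_mask.all())

    def with_values(self, values: np.ndarray, observed_mask=None) -> "RawCurveSet":
        return RawCurveSet(
            grid=self.grid,
            values=values,
            observed_mask=self.observed_mask.copy() if observed_mask is None else observed_mask,
            unit_names=list(self.unit_names),
        )


class SplineBasis:
    """Cubic B-spline basis with an exact second-derivative penalty matrix."""

    def __init__(self, grid: TimeGrid, n_basis: int):
        t_lo, t_hi = grid.lo, grid.hi
        n_interior = n_basis - (_SPLINE_DEGREE + 1)
        interior = np.linspace(t_lo, t_hi, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [np.full(_SPLINE_DEGREE + 1, t_lo), interior, np.full(_SPLINE_DEGREE + 1, t_hi)]
        )
        self.n_basis = n_basis
        self.order = _SPLINE_DEGREE + 1
        self.grid = grid
        self._identity_spline = BSpline(
            self.knots, np.eye(n_basis), _SPLINE_DEGREE, extrapolate=False
        )
        self.penalty_matrix = self._assemble_penalty()

    def _assemble_penalty(self) -> np.ndarray:
        # products of second derivatives of cubics are piecewise quadratics:
        # 2-point Gauss-Legendre per knot span integrates them exactly
        spans = np.unique(self.knots)
        xg, wg = leggauss(3)
        P = np.zeros((self.n_basis, self.n_basis))
        d2 = self._identity_spline.derivative(2)
        for a, b in zip(spans[:-1], spans[1:]):
            half = 0.5 * (b - a)
            mid = 0.5 * (a + b)
            pts = mid + half * xg
            D = d2(pts)  # (3, K)
            P += half * (D * wg[:, None]).T @ D
        return 0.5 * (P + P.T)

    def design_matrix(self, times, deriv: int = 0) -> np.ndarray:
        """Evaluate all basis functions (or a derivative) at ``times``: (len, K)."""
        times = np.asarray(times, dtype=float)
        self._check_range(times)
        if deriv == 0:
            B = self._identity_spline(times)
        else:
            B = self._identity_spline.derivative(deriv)(times)
        return np.nan_to_num(B, nan=0.0)

    def integrals(self, a: float, b: float) -> np.ndarray:
        """Exact integral of every basis function over [a, b]."""
        if a >= b:
            raise InvalidArgumentError("integration interval requires a < b")
        self._check_range(np.array([a, b]))
        anti = self._identity_spline.antiderivative()
        return np.asarray(anti(b) - anti(a))

    def _check_range(self, times: np.ndarray):
        if times.size and (times.min() < self.grid.lo - 1e-12 or times.max() > self.grid.hi + 1e-12):
            raise InvalidArgumentError(
                f"times outside the fitted range [{self.grid.lo}, {self.grid.hi}]; "
                "no extrapolation is performed"
            )


@dataclass
class SmoothedCurveSet:
    """Per-curve spline coefficients on a shared basis, with fit diagnostics."""

    basis: SplineBasis
    coefficients: np.ndarray  # (N, K)
    lambdas: np.ndarray  # (N,)
    gcv_values: np.ndarray  # (N,)
    residuals: np.ndarray  # (N, T), NaN where unobserved
    dfs: np.ndarray = field(default=None)  # effective degrees of freedom per curve

    @property
    def grid(self) -> TimeGrid:
        return self.basis.grid

    @property
    def n_curves(self) -> int:
        return self.coefficients.shape[0]

    def fitted_values(self) -> np.ndarray:
        return evaluate(self, self.grid.points)


def build_basis(grid: TimeGrid, n_basis: int | None = None) -> SplineBasis:
    """Cubic basis with equally spaced interior knots over the grid range.

    The default size min(T - 2, 25) gives ample flexibility at typical
    sample sizes without ill-conditioning.
    """
    T = grid.n_times
    if n_basis is None:
        n_basis = min(T - 2, 25)
        n_basis = max(n_basis, 4)
    if not (4 <= n_basis <= T):
        raise InvalidArgumentError(
            f"n_basis must lie in [4, {T}] for a grid of {T} points, got {n_basis}"
        )
    return SplineBasis(grid, n_basis)


def default_lambda_grid() -> np.ndarray:
    """25 log-spaced penalty values spanning interpolation to near-linear fits."""
    return np.logspace(-6, 2, 25)


def _solve_penalized(BtB, Bty, P, lam):
    A = BtB + lam * P
    try:
        c, low = cho_factor(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise IllPosedFitError(
            "penalized system is singular; use a smaller basis or lambda > 0"
        ) from exc
    except Exception as exc:
        raise IllPosedFitError(
            "penalized system is singular; use a smaller basis or lambda > 0"
        ) from exc
    coef = cho_solve((c, low), Bty)
    df = float(np.trace(cho_solve((c, low), BtB)))
    return coef, df


def fit_penalized(raw: RawCurveSet, basis: SplineBasis, lam: float) -> SmoothedCurveSet:
    """Fit every curve with a single fixed penalty weight ``lam >= 0``."""
    if lam < 0:
        raise InvalidArgumentError("lambda must be nonnegative")
    return _fit(raw, basis, lambda_grid=np.array([float(lam)]), select=False)


def select_lambda_gcv(
    raw: RawCurveSet,
    basis: SplineBasis,
    lambda_grid: Sequence[float] | None = None,
    shared: bool = False,
) -> SmoothedCurveSet:
    """Per-curve GCV selection of the penalty over ``lambda_grid``.

    Ties are broken toward the larger (smoother) lambda.  With
    ``shared=True`` a single lambda — the median of the per-curve optima —
    is refitted to all curves.
    """
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0 or np.any(grid < 0):
        raise InvalidArgumentError("lambda_grid must be nonempty with nonnegative entries")
    grid = np.sort(grid)
    out = _fit(raw, basis, lambda_grid=grid, select=True)
    if shared:
        lam = float(np.median(out.lambdas))
        shared_fit = _fit(raw, basis, lambda_grid=np.array([lam]), select=False)
        return shared_fit
    return out


def _fit(raw: RawCurveSet, basis: SplineBasis, lambda_grid: np.ndarray, select: bool) -> SmoothedCurveSet:
    P = basis.penalty_matrix
    N, T = raw.values.shape
    K = basis.n_basis
    pts = raw.grid.points

    if raw.fully_observed:
        B = basis.design_matrix(pts)
        BtB = B.T @ B
        BtY = B.T @ raw.values.T  # (K, N)
        n_obs = T
        coefs_per_lam = []
        sses = np.empty((lambda_grid.size, N))
        dfs = np.empty(lambda_grid.size)
        for li, lam in enumerate(lambda_grid):
            C, df = _solve_penalized(BtB, BtY, P, lam)  # (K, N)
            fit = B @ C  # (T, N)
            sses[li] = ((raw.values.T - fit) ** 2).sum(axis=0)
            dfs[li] = df
            coefs_per_lam.append(C)
        denom = n_obs - dfs
        if select:
            if np.all(denom <= 0):
                raise DegenerateGCVError(
                    "df(lambda) >= n for every grid value; enlarge the lambda grid"
                )
            gcv = np.where(denom[:, None] > 0, sses / denom[:, None] ** 2, np.inf)
            # ties toward larger lambda: scan ascending, accept <=
            best_idx = np.zeros(N, dtype=int)
            best_val = np.full(N, np.inf)
            for li in range(lambda_grid.size):
                take = gcv[li] <= best_val
                best_idx[take] = li
                best_val[take] = gcv[li][take]
        else:
            best_idx = np.zeros(N, dtype=int)
            best_val = sses[0] / denom[0] ** 2 if denom[0] > 0 else np.full(N, np.inf)
        coefficients = np.empty((N, K))
        for li in np.unique(best_idx):
            sel = best_idx == li
            coefficients[sel] = coefs_per_lam[li][:, sel].T
        lambdas = lambda_grid[best_idx]
        df_out = dfs[best_idx]
        residuals = raw.values - (B @ coefficients.T).T
        return SmoothedCurveSet(basis, coefficients, lambdas, best_val, residuals, df_out)

    # gappy data: per-curve design matrices
    coefficients = np.empty((N, K))
    lambdas = np.empty(N)
    gcvs = np.empty(N)
    dfs_out = np.empty(N)
    residuals = np.full((N, T), np.nan)
    B_full = basis.design_matrix(pts)
    for i in range(N):
        obs = raw.observed_mask[i]
        Bi = B_full[obs]
        yi = raw.values[i, obs]
        n_i = int(obs.sum())
        BtB = Bi.T @ Bi
        Bty = Bi.T @ yi
        best = (np.inf, None, None, None)  # gcv, lam, coef, df
        any_valid = False
        for lam in lambda_grid:
            coef, df = _solve_penalized(BtB, Bty, P, lam)
            sse = float(((yi - Bi @ coef) ** 2).sum())
            denom = n_i - df
            if select and denom <= 0:
                continue
            any_valid = True
            gcv = sse / denom**2 if denom > 0 else np.inf
            if gcv <= best[0]:
                best = (gcv, lam, coef, df)
        if select and not any_valid:
            raise DegenerateGCVError(
                f"df(lambda) >= n for curve {raw.unit_names[i]!r} on the whole grid"
            )
        gcvs[i], lambdas[i], dfs_out[i] = best[0], best[1], best[3]
        coefficients[i] = best[2]
        residuals[i, obs] = yi - Bi @ best[2]
    return SmoothedCurveSet(basis, coefficients, lambdas, gcvs, residuals, dfs_out)


def impute_missing(
    raw: RawCurveSet,
    basis: SplineBasis | None = None,
    lambda_grid: Sequence[float] | None = None,
) -> RawCurveSet:
    """Replace masked entries by the GCV-smoothed fit at those times.

    Observed entries are left untouched; boundary gaps are filled by spline
    evaluation at the boundary (inside the fitted range — no extrapolation).
    """
    if raw.fully_observed:
        return raw.with_values(raw.values.copy())
    if basis is None:
        basis = build_basis(raw.grid)
    smoothed = select_lambda_gcv(raw, basis, lambda_grid)
    fitted = smoothed.fitted_values()
    values = np.where(raw.observed_mask, raw.values, fitted)
    return RawCurveSet(
        grid=raw.grid,
        values=values,
        observed_mask=np.ones_like(raw.observed_mask),
        unit_names=list(raw.unit_names),
    )


def evaluate(smoothed: SmoothedCurveSet, times, deriv: int = 0) -> np.ndarray:
    """Exact piecewise-polynomial evaluation of the fits: (N, len(times))."""
    if deriv not in (0, 1, 2):
        raise InvalidArgumentError("deriv must be 0, 1 or 2")
    B = smoothed.basis.design_matrix(times, deriv=deriv)
    return smoothed.coefficients @ B.T


def integrate_segment(smoothed: SmoothedCurveSet, a: float, b: float) -> np.ndarray:
    """Exact integral of every fitted curve over [a, b] via basis antiderivatives."""
    ints = smoothed.basis.integrals(a, b)
    return smoothed.coefficients @ ints


def _window_stats(values: np.ndarray, window: int):
    """Sliding-window median and MAD along time (windows truncated at the edges)."""
    N, T = values.shape
    h = window // 2
    med = np.empty((N, T))
    mad = np.empty((N, T))
    for j in range(T):
        win = values[:, max(0, j - h) : j + h + 1]
        m = np.nanmedian(win, axis=1)
        med[:, j] = m
        mad[:, j] = np.nanmedian(np.abs(win - m[:, None]), axis=1)
    return med, mad


def _check_filter_args(raw: RawCurveSet, window: int, k: float):
    if window < 3 or window % 2 == 0:
        raise InvalidArgumentError("window must be an odd integer >= 3")
    if window > raw.n_times:
        raise InvalidArgumentError("window exceeds the number of time points")
    if k <= 0:
        raise InvalidArgumentError("threshold multiplier must be positive")


def hampel_filter(raw: RawCurveSet, window: int = 7, k: float = 3.0) -> RawCurveSet:
    """Hard outlier replacement: points beyond k * 1.4826 * MAD of the window
    median are replaced by that median."""
    _check_filter_args(raw, window, k)
    vals = np.where(raw.observed_mask, raw.values, np.nan)
    med, mad = _window_stats(vals, window)
    thr = k * MAD_SCALE * mad
    out = np.where(np.abs(vals - med) > thr, med, vals)
    out = np.where(raw.observed_mask, out, raw.values)
    return raw.with_values(out)


def huber_filter(raw: RawCurveSet, window: int = 7, c: float = 1.5) -> RawCurveSet:
    """Soft (winsorizing) variant: deviations beyond c * 1.4826 * MAD are shrunk
    to exactly that threshold, preserving sign."""
    _check_filter_args(raw, window, c)
    vals = np.where(raw.observed_mask, raw.values, np.nan)
    med, mad = _window_stats(vals, window)
    thr = c * MAD_SCALE * mad
    out = np.clip(vals, med - thr, med + thr)
    out = np.where(raw.observed_mask, out, raw.values)
    return raw.with_values(out)
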