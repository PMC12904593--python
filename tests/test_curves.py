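"""Spline basis, penalized fitting, GCV, imputation, integrals, robust filters."""

import numpy as np
import pytest

from fpowa import (
    RawCurveSet,
    TimeGrid,
    build_basis,
    evaluate,
    fit_penalized,
    hampel_filter,
    huber_filter,
    impute_missing,
    integrate_segment,
    select_lambda_gcv,
)
from fpowa.exceptions import (
    InsufficientSupportError,
    InvalidArgumentError,
)

from conftest import smooth_exact, smooth_gcv


class TestBasis:
    def test_partition_of_unity(self, unit_grid):
        basis = build_basis(unit_grid, 10)
        x = np.linspace(0, 1, 57)
        B = basis.design_matrix(x)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_penalty_vanishes_on_affine(self, unit_grid):
        basis = build_basis(unit_grid, 10)
        raw = RawCurveSet(grid=unit_grid, values=np.vstack(
            [unit_grid.points, 2 * unit_grid.points + 1, np.ones(21), np.zeros(21) + 3]))
        sm = fit_penalized(raw, basis, 0.0)
        quad = np.einsum("ik,kl,il->i", sm.coefficients, basis.penalty_matrix, sm.coefficients)
        np.testing.assert_allclose(quad, 0.0, atol=1e-8)

    def test_penalty_quadratic(self, unit_grid):
        # f(t) = t^2 on [0,1]: int (f'')^2 = int 2^2 = 4
        basis = build_basis(unit_grid, 12)
        raw = RawCurveSet(grid=unit_grid, values=np.vstack(
            [unit_grid.points ** 2, unit_grid.points, np.ones(21), unit_grid.points + 1]))
        sm = fit_penalized(raw, basis, 0.0)
        c = sm.coefficients[0]
        quad = c @ basis.penalty_matrix @ c
        assert quad == pytest.approx(4.0, abs=1e-8)

    @pytest.mark.parametrize("n_basis", [3, 25])
    def test_basis_size_validation(self, unit_grid, n_basis):
        with pytest.raises(InvalidArgumentError, match=r"\[4, 21\]"):
            build_basis(unit_grid, n_basis)


class TestPenalizedFit:
    @pytest.mark.parametrize("lam,atol", [(0.0, 1e-8), (1e-3, 1e-8), (1.0, 1e-8),
                                          (1e2, 1e-8), (1e6, 1e-5)])
    def test_affine_reproduction_any_lambda(self, affine_set, lam, atol):
        # the penalty null space contains affine fits; at extreme lambda the
        # attainable accuracy is limited by the conditioning of B'B + lam*P
        basis = build_basis(affine_set.grid, 12)
        sm = fit_penalized(affine_set, basis, lam)
        fitted = evaluate(sm, affine_set.grid.points)
        np.testing.assert_allclose(fitted, affine_set.values, atol=atol)

    def test_huge_lambda_approaches_least_squares_line(self, sine_set):
        basis = build_basis(sine_set.grid, 15)
        sm = fit_penalized(sine_set, basis, 1e9)
        t = sine_set.grid.points
        X = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(X, sine_set.values.T, rcond=None)
        line = (X @ beta).T
        fitted = evaluate(sm, t)
        np.testing.assert_allclose(fitted, line, atol=1e-2)

    def test_zero_lambda_full_basis_interpolates(self, sine_set):
        basis = build_basis(sine_set.grid, sine_set.n_times)
        sm = fit_penalized(sine_set, basis, 0.0)
        np.testing.assert_allclose(sm.residuals, 0.0, atol=1e-7)

    def test_negative_lambda_rejected(self, affine_set):
        basis = build_basis(affine_set.grid, 10)
        with pytest.raises(InvalidArgumentError):
            fit_penalized(affine_set, basis, -1.0)


class TestGCV:
    def test_df_non_increasing_in_lambda(self, sine_set):
        basis = build_basis(sine_set.grid, 15)
        dfs = [fit_penalized(sine_set, basis, lam).dfs[0]
               for lam in np.logspace(-6, 3, 12)]
        assert all(a >= b - 1e-10 for a, b in zip(dfs[:-1], dfs[1:]))

    def test_gcv_denoises_simulated_curves(self):
        """With sigma=0.1 noise, the GCV fit's sup error beats the raw noise."""
        from fpowa import NoiseSpec, SimulationSpec, add_noise, generate_truth

        spec = SimulationSpec(n_curves=25, n_times=40, seed=11)
        clean, *_ = generate_truth(spec)
        noisy = add_noise(clean, NoiseSpec("gaussian", 0.1), seed=12)
        sm = smooth_gcv(noisy)
        fitted = evaluate(sm, clean.grid.points)
        fit_sup = np.abs(fitted - clean.values).max(axis=1)
        noise_sup = np.abs(noisy.values - clean.values).max(axis=1)
        assert fit_sup.mean() < noise_sup.mean()

    def test_noiseless_affine_reproduced_whatever_lambda_wins(self, affine_set):
        sm = smooth_gcv(affine_set)
        fitted = evaluate(sm, affine_set.grid.points)
        np.testing.assert_allclose(fitted, affine_set.values, atol=1e-7)


class TestImpute:
    def test_identity_when_fully_observed(self, affine_set):
        out = impute_missing(affine_set)
        np.testing.assert_array_equal(out.values, affine_set.values)

    def test_interior_point_on_affine_curve(self, unit_grid):
        t = unit_grid.points
        vals = np.vstack([3 * t, 2 * t + 1, t, -t])
        mask = np.ones_like(vals, dtype=bool)
        mask[0, 10] = False
        raw = RawCurveSet(grid=unit_grid, values=vals, observed_mask=mask)
        out = impute_missing(raw)
        assert out.values[0, 10] == pytest.approx(3 * t[10], abs=1e-6)
        np.testing.assert_array_equal(out.values[1:], vals[1:])

    def test_boundary_point_is_finite_and_close_to_truth(self, unit_grid):
        t = unit_grid.points
        vals = np.vstack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t),
                          t ** 2, 1 - t])
        mask = np.ones_like(vals, dtype=bool)
        mask[0, -1] = False
        raw = RawCurveSet(grid=unit_grid, values=vals, observed_mask=mask)
        out = impute_missing(raw)
        assert np.isfinite(out.values[0, -1])
        assert out.values[0, -1] == pytest.approx(np.sin(2 * np.pi * 1.0), abs=0.15)

    def test_too_few_observed_points_rejected(self, unit_grid):
        vals = np.ones((2, 21))
        mask = np.ones_like(vals, dtype=bool)
        mask[1, 3:] = False  # 3 observed points only
        with pytest.raises(InsufficientSupportError):
            RawCurveSet(grid=unit_grid, values=vals, observed_mask=mask)


class TestEvaluateAndIntegrate:
    def test_first_derivative_of_affine(self, affine_set):
        sm = smooth_exact(affine_set, 10)
        d1 = evaluate(sm, np.linspace(0, 1, 31), deriv=1)
        np.testing.assert_allclose(d1, [[1.0] * 31, [2.0] * 31, [3.0] * 31], atol=1e-7)

    def test_second_derivative_of_quadratic(self, unit_grid):
        raw = RawCurveSet(grid=unit_grid, values=np.vstack(
            [unit_grid.points ** 2, unit_grid.points, np.ones(21), 2 * unit_grid.points]))
        sm = smooth_exact(raw, 12)
        d2 = evaluate(sm, np.linspace(0.1, 0.9, 17), deriv=2)
        np.testing.assert_allclose(d2[0], 2.0, atol=1e-6)

    def test_evaluation_matches_residual_bookkeeping(self, sine_set):
        sm = smooth_gcv(sine_set)
        fitted = evaluate(sm, sine_set.grid.points)
        np.testing.assert_allclose(sine_set.values - fitted, sm.residuals, atol=1e-10)

    def test_no_extrapolation(self, affine_set):
        sm = smooth_exact(affine_set)
        with pytest.raises(InvalidArgumentError, match="extrapolation"):
            evaluate(sm, [1.5])

    @pytest.mark.parametrize("curve,expected", [
        (lambda t: np.ones_like(t), 1.0),
        (lambda t: t, 0.5),
        (lambda t: np.sin(2 * np.pi * (t + 0.13)), 0.0),
    ])
    def test_closed_form_integrals(self, unit_grid, curve, expected):
        vals = np.vstack([curve(unit_grid.points)] * 4)
        sm = smooth_exact(RawCurveSet(grid=unit_grid, values=vals), 21)
        I = integrate_segment(sm, 0.0, 1.0)
        np.testing.assert_allclose(I, expected, atol=2e-4)

    def test_integral_additivity(self, sine_set):
        sm = smooth_gcv(sine_set)
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b, c = np.sort(rng.uniform(0, 1, 3))
            if b - a < 1e-3 or c - b < 1e-3:
                continue
            whole = integrate_segment(sm, a, c)
            parts = integrate_segment(sm, a, b) + integrate_segment(sm, b, c)
            np.testing.assert_allclose(whole, parts, atol=1e-10)

    def test_invalid_interval(self, affine_set):
        sm = smooth_exact(affine_set)
        with pytest.raises(InvalidArgumentError):
            integrate_segment(sm, 0.7, 0.2)


class TestRobustFilters:
    def _series(self, grid, y):
        return RawCurveSet(grid=grid, values=np.vstack([y, y + 1, y - 1, 2 * y]))

    def test_constant_series_unchanged(self, unit_grid):
        raw = self._series(unit_grid, np.full(21, 5.0))
        for f in (hampel_filter, huber_filter):
            np.testing.assert_array_equal(f(raw).values, raw.values)

    def test_hampel_replaces_single_spike(self, unit_grid):
        rng = np.random.default_rng(0)
        y = np.sin(2 * np.pi * unit_grid.points) + 0.01 * rng.standard_normal(21)
        spiked = y.copy()
        spiked[10] += 10 * 0.01 * 50  # large spike
        raw = self._series(unit_grid, spiked)
        out = hampel_filter(raw)
        assert abs(out.values[0, 10] - spiked[10]) > 1.0  # replaced
        np.testing.assert_array_equal(np.delete(out.values[0], 10), np.delete(spiked, 10))

    def test_monotone_linear_series_unchanged(self, unit_grid):
        raw = self._series(unit_grid, 3.0 * unit_grid.points)
        out = hampel_filter(raw, window=7, k=3.0)
        np.testing.assert_allclose(out.values, raw.values, atol=1e-12)

    def test_huber_clips_to_threshold(self, unit_grid):
        y = np.zeros(21)
        y[10] = 100.0
        raw = self._series(unit_grid, y)
        out = huber_filter(raw, window=7, c=1.5)
        # window median and MAD are 0 around the flat part -> clipped to median
        assert out.values[0, 10] == pytest.approx(0.0)

    def test_huber_identity_within_threshold(self, unit_grid):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1e-3, 21) + 5
        raw = self._series(unit_grid, y)
        out = huber_filter(raw, window=7, c=20.0)
        np.testing.assert_array_equal(out.values, raw.values)

    def test_filters_idempotent_on_spiky_curve(self, unit_grid):
        rng = np.random.default_rng(2)
        y = np.cos(2 * np.pi * unit_grid.points) + 0.05 * rng.standard_normal(21)
        y[5] += 8.0
        raw = self._series(unit_grid, y)
        for f in (hampel_filter, huber_filter):
            once = f(raw)
            twice = f(once)
            np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_window_validation(self, unit_grid):
        raw = self._series(unit_grid, unit_grid.points)
        with pytest.raises(InvalidArgumentError):
            hampel_filter(raw, window=4)
        with pytest.raises(InvalidArgumentError):
            hampel_filter(raw, window=23)
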