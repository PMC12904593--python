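"""Segment weights, rank aggregation, FP-OWA pipeline and the baselines."""

import numpy as np
import pytest

from fpowa import (
    FpowaConfig,
    NoiseSpec,
    RawCurveSet,
    SimulationSpec,
    TimeGrid,
    add_noise,
    aggregate_scores,
    depth_rank,
    fp_owa,
    fpca_rank,
    generate_truth,
    get_ranker,
    segment_rank_matrix,
    segment_weights,
    wlr_rank,
)
from fpowa.ranking import RankMatrix, SegmentWeights
from fpowa.segmentation import extract_segments, single_segment_result

from conftest import smooth_exact


def _two_segment(grid):
    labels = np.where(grid.points < 0.5, 1, 2)
    return extract_segments(labels, grid)


class TestSegmentWeights:
    def test_single_segment_weight_one(self, affine_set):
        sm = smooth_exact(affine_set, 10)
        w = segment_weights(sm, single_segment_result(affine_set.grid))
        np.testing.assert_allclose(w.weights, [1.0])

    def test_symmetric_segments_split_evenly(self, unit_grid):
        # constant curves: identical configuration in any segment
        vals = np.tile(np.array([[0.0], [1.0], [2.0]]), (1, 21))
        sm = smooth_exact(RawCurveSet(grid=unit_grid, values=vals), 10)
        w = segment_weights(sm, _two_segment(unit_grid))
        np.testing.assert_allclose(w.weights, [0.5, 0.5], atol=1e-10)
        # mean depth per segment from the enumerated MBD values (2/3, 1, 2/3)
        np.testing.assert_allclose(w.mean_depths, 7 / 9, atol=1e-10)

    def test_weights_sum_to_one(self, sine_set):
        from conftest import smooth_gcv

        sm = smooth_gcv(sine_set)
        w = segment_weights(sm, _two_segment(sine_set.grid))
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w.weights >= 0)


class TestRankMatrix:
    def test_affine_slopes_rank_in_order(self, unit_grid):
        vals = np.vstack([s * unit_grid.points for s in (1.0, 2.0, 3.0)])
        sm = smooth_exact(RawCurveSet(grid=unit_grid, values=vals), 10)
        R = segment_rank_matrix(sm, _two_segment(unit_grid))
        np.testing.assert_allclose(R.ranks, [[1, 2, 3], [1, 2, 3]])
        # closed-form integrals s (b^2 - a^2) / 2
        for i, (a, b) in enumerate([(0.0, 0.475), (0.475, 1.0)]):
            np.testing.assert_allclose(
                R.integrals[i], [s * (b * b - a * a) / 2 for s in (1, 2, 3)],
                atol=1e-6,
            )

    def test_average_ties_for_identical_curves(self, unit_grid):
        vals = np.vstack([unit_grid.points, unit_grid.points])
        sm = smooth_exact(RawCurveSet(grid=unit_grid, values=vals), 10)
        R = segment_rank_matrix(sm, single_segment_result(unit_grid))
        np.testing.assert_allclose(R.ranks, [[1.5, 1.5]])

    def test_sign_reversal_reverses_ranks(self, sine_set):
        from conftest import smooth_gcv

        seg = _two_segment(sine_set.grid)
        R1 = segment_rank_matrix(smooth_gcv(sine_set), seg)
        flipped = sine_set.with_values(-sine_set.values)
        R2 = segment_rank_matrix(smooth_gcv(flipped), seg)
        n = sine_set.n_curves
        np.testing.assert_allclose(R1.ranks + R2.ranks, n + 1, atol=1e-9)

    def test_rank_rows_sum_to_triangular_number(self, sine_set):
        from conftest import smooth_gcv

        R = segment_rank_matrix(smooth_gcv(sine_set), _two_segment(sine_set.grid))
        n = sine_set.n_curves
        np.testing.assert_allclose(R.ranks.sum(axis=1), n * (n + 1) / 2)


class TestAggregate:
    def test_single_segment_score_is_rank_vector(self):
        w = SegmentWeights(mean_depths=np.array([0.8]), weights=np.array([1.0]))
        R = RankMatrix(ranks=np.array([[2.0, 3.0, 1.0]]), integrals=np.zeros((1, 3)))
        res = aggregate_scores(w, R)
        np.testing.assert_allclose(res.scores, [2, 3, 1])
        np.testing.assert_allclose(res.ranking, [2, 1, 3])

    def test_half_half_weights(self):
        w = SegmentWeights(mean_depths=np.ones(2), weights=np.array([0.5, 0.5]))
        R = RankMatrix(ranks=np.array([[1.0, 2.0], [3.0, 2.0]]),
                       integrals=np.zeros((2, 2)))
        res = aggregate_scores(w, R)
        assert res.scores[0] == pytest.approx(2.0)

    def test_scores_are_convex_combinations_of_ranks(self, sine_set):
        res = fp_owa(sine_set)
        n = sine_set.n_curves
        assert np.all(res.scores >= 1 - 1e-9) and np.all(res.scores <= n + 1e-9)
        assert res.scores.sum() == pytest.approx(n * (n + 1) / 2, abs=1e-6)


class TestFpowaPipeline:
    def test_duplicated_curve_ties(self, unit_grid):
        rng = np.random.default_rng(31)
        vals = rng.standard_normal((5, 21)).cumsum(axis=1)
        vals = np.vstack([vals, vals[2]])
        res = fp_owa(RawCurveSet(grid=unit_grid, values=vals))
        assert res.scores[2] == pytest.approx(res.scores[5], abs=1e-10)
        assert res.ranking[2] == res.ranking[5]

    def test_constant_shift_leaves_ranking_unchanged(self):
        raw, *_ = generate_truth(SimulationSpec(15, 30, seed=32))
        noisy = add_noise(raw, NoiseSpec("gaussian", 0.05), seed=33)
        res1 = fp_owa(noisy)
        res2 = fp_owa(noisy.with_values(noisy.values + 11.0))
        np.testing.assert_array_equal(res1.ranking, res2.ranking)

    @pytest.mark.parametrize("method", ["fpowa", "wlr", "fpca", "hmode", "rtd"])
    def test_permutation_equivariance(self, method):
        raw, *_ = generate_truth(SimulationSpec(12, 25, seed=34))
        noisy = add_noise(raw, NoiseSpec("gaussian", 0.05), seed=35)
        perm = np.random.default_rng(36).permutation(12)
        ranker = get_ranker(method)
        r1 = ranker(noisy, None)
        r2 = ranker(noisy.with_values(noisy.values[perm]), None)
        np.testing.assert_allclose(r2.scores, r1.scores[perm], atol=1e-9)

    def test_diagnostics_are_attached(self, sine_set):
        res = fp_owa(sine_set)
        assert {"segmentation", "segment_weights", "rank_matrix", "smoothed"} <= set(res.diagnostics)
        seg = res.diagnostics["segmentation"]
        w = res.diagnostics["segment_weights"]
        assert w.weights.size == seg.n_segments

    def test_prefilter_neutral_on_clean_data(self):
        raw, *_ = generate_truth(SimulationSpec(10, 30, seed=37))
        base = fp_owa(raw)
        filt = fp_owa(raw, FpowaConfig(prefilter="huber"))
        np.testing.assert_array_equal(base.ranking, filt.ranking)


class TestWLR:
    def test_non_crossing_curves_single_segment_mean_order(self, unit_grid):
        vals = np.vstack([np.full(21, c) for c in (3.0, 1.0, 2.0)])
        res = wlr_rank(RawCurveSet(grid=unit_grid, values=vals))
        assert res.diagnostics["breakpoints"].size == 0
        np.testing.assert_allclose(res.ranking, [1, 3, 2])

    def test_symmetric_crossing_produces_tie(self, unit_grid):
        t = unit_grid.points
        vals = np.vstack([t, 1 - t])
        res = wlr_rank(RawCurveSet(grid=unit_grid, values=vals))
        np.testing.assert_allclose(res.diagnostics["breakpoints"], [0.5], atol=1e-12)
        np.testing.assert_allclose(res.diagnostics["weights"], [0.5, 0.5])
        np.testing.assert_allclose(res.scores, [1.5, 1.5])

    def test_weights_sum_to_one(self):
        raw, *_ = generate_truth(SimulationSpec(10, 30, seed=38))
        noisy = add_noise(raw, NoiseSpec("gaussian", 0.2), seed=39)
        res = wlr_rank(noisy)
        assert res.diagnostics["weights"].sum() == pytest.approx(1.0, abs=1e-12)


class TestFPCA:
    def test_vertical_shifts_rank_by_mean(self, unit_grid):
        t = unit_grid.points
        shifts = np.array([0.0, 2.0, -1.0, 1.0])
        vals = np.sin(2 * np.pi * t)[None, :] + shifts[:, None]
        res = fpca_rank(RawCurveSet(grid=unit_grid, values=vals))
        np.testing.assert_allclose(res.ranking, [3, 1, 4, 2])

    def test_identical_curves_full_tie(self, unit_grid):
        vals = np.tile(np.cos(unit_grid.points), (4, 1))
        res = fpca_rank(RawCurveSet(grid=unit_grid, values=vals))
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-10)
        assert len(set(res.ranking)) == 1


class TestDepthRank:
    def test_identical_curves_full_tie(self, unit_grid):
        vals = np.tile(np.cos(unit_grid.points), (4, 1))
        for method in ("hmode", "rtd"):
            res = depth_rank(RawCurveSet(grid=unit_grid, values=vals), method)
            assert len(set(res.ranking)) == 1

    def test_symmetric_family_central_curve_first(self, unit_grid):
        t = unit_grid.points
        offsets = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        vals = (3 * t)[None, :] + offsets[:, None]
        raw = RawCurveSet(grid=unit_grid, values=vals)
        assert depth_rank(raw, "hmode").ranking[2] == 1
        assert depth_rank(raw, "rtd", FpowaConfig(seed=7)).ranking[2] == 1

    def test_depth_ranking_ignores_magnitude_order(self):
        """Centrality-based rankers are nearly independent of the slope order."""
        taus = []
        from fpowa import kendall_tau

        for seed in range(10):
            raw, _, tr = generate_truth(SimulationSpec(40, 30, seed=40 + seed))
            res = depth_rank(raw, "hmode")
            taus.append(kendall_tau(res.ranking, tr))
        assert abs(np.mean(taus)) < 0.15
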