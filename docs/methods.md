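# Methods

`fpowa` ranks a sample of N curves observed on a shared time grid by
*magnitude* — which unit accumulates the most of the measured quantity over
the study window — while staying robust to noise, gaps and outliers.  This
note records the model, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Observation model and smoothing

Each unit i is observed as

    y_i(t_j) = f_i(t_j) + eps_i(t_j),      j = 1..T,

with smooth f_i and mean-zero noise.  f_i is estimated in a cubic B-spline
basis {phi_k} with equally spaced interior knots by minimizing

    sum_j [y_i(t_j) - sum_k beta_ik phi_k(t_j)]^2
        + lambda_i * int f_i''(t)^2 dt.

The penalty matrix is assembled by exact Gauss–Legendre quadrature per knot
span (integrands are piecewise polynomials), so affine functions are
penalty-free to machine precision and segment integrals of the fits are
exact basis-antiderivative sums, not quadrature approximations.

* **Basis size** K = min(T − 2, 25): near-interpolation capacity at small T
  without ill-conditioning; exposed as `FpowaConfig.n_basis`.
* **Penalty weight** lambda_i is selected per curve by generalized
  cross-validation, GCV(lambda) = SSE(lambda) / (n_i − df(lambda))², over a
  default grid of 25 log-spaced values in [1e−6, 1e2] (interpolation to
  near-linear regimes at O(1) data scale).  Ties go to the larger lambda.
  `shared_lambda=True` refits one lambda (median of per-curve optima).
* **Missing entries** are filled by evaluating the GCV fit of the observed
  points at the masked times; observed values are never altered, and the
  spline is never extrapolated outside the grid range (boundary gaps use
  the boundary evaluation of the fitted curve).

## Temporal segmentation

Every time point t is mapped to the feature vector concatenating, across
all N curves, [f_i(t), theta1·f_i'(t), theta2·f_i''(t)] (theta1 = theta2 = 1
by default).  Columns are standardized across time; zero-variance columns
are dropped; PCA retains the smallest q components reaching 95% cumulative
variance, capped at q = 10.  DBSCAN then clusters the T feature points:

* eps candidates: 20 evenly spaced quantiles between the 10% and 95%
  quantiles of the 4-nearest-neighbour distance distribution;
* minPts candidates: 2q up to min(40, floor(T/5)).  When 2q exceeds that
  upper end — routine at T ≤ 50 once noise inflates q — the search instead
  spans [2, floor(T/5)]: the silhouette optimum demonstrably lives at small
  minPts there, and collapsing to a single large value hides it;
* each (eps, minPts) pair is scored by the mean silhouette of the
  noise-repaired labels over all T points (noise labels take the nearest
  non-noise label along time, ties to the left); pairs with fewer than two
  clusters are skipped; ties favour smaller minPts, then smaller eps.

Label runs shorter than 2 points are merged into the longer neighbour, and
contiguous runs become segments whose internal boundaries sit at midpoints
between adjacent grid times (so segments exactly cover the domain and
segment integrals are additive).  If no parameter pair yields two clusters
the method degenerates gracefully to a single segment — the ranking then
reduces to the global-integral ranking, never an error.

## Depth weights and rank aggregation

Within segment i the modified band depth of curve j is the average over
unordered curve pairs and over the segment's grid points of the indicator
that f_j lies inside the band of the pair; pairs containing j count as
covering.  The implementation is rank-based: with le/ge/eq the number of
values ≤/≥/= f_j(t) at a grid point, the covering-pair count is
le·ge − eq − eq(eq−1)/2, which equals the explicit pair enumeration exactly,
ties included (property-tested against the naive oracle).  Segment weights
w_i normalize the mean depths; segment scores are ascending average-tie
ranks R_ij of the exact segment integrals; the final score is
Score_j = sum_i w_i R_ij, ranked descending (rank 1 = largest cumulative
magnitude; `ascending=True` inverts).

## Baselines

* **FPCA**: GCV-smoothed curves; trapezoid-quadrature eigendecomposition of
  the sample covariance; components retained to 90% cumulative variance
  (`fpca_first_pc=True` restricts to the first); eigenfunction signs fixed
  by nonnegative inner product with the constant function; composite score
  sum_k (lambda_k / sum lambda) xi_ik.
* **WLR**: piecewise-linear interpolants of the observed points (interior
  gaps joined directly, endpoint gaps spline-imputed); breakpoints at exact
  pairwise crossing times (strict sign changes; a sign change across a
  single exact zero counts; tangential touching does not), deduplicated
  within 1e−9; length-proportional weights; within-segment ascending ranks
  of segment means.
* **h-mode / random Tukey depth**: global centrality rankings.  h-mode uses
  a Gaussian kernel on trapezoid-rule L2 distances with "auto" bandwidth =
  15th percentile of nonzero pairwise distances; RTD takes the minimum
  univariate half-space depth over 50 seeded unit Gaussian directions.
  These rank centre-outward by construction and are included as contrast
  methods: they cannot recover a magnitude ordering, and the studies
  confirm near-zero rank agreement for them.

## Synthetic studies

The generator draws f_i(t) = s_i·t + sin(2π(t + p_i)) on a uniform grid in
[0, 1], s_i ~ U(3.5, 4.5), p_i ~ U(0, 0.2).  The sine integrates to zero
over the unit period, so the true integral is exactly s_i/2 and the ground
truth is the descending slope order.  Disturbances:

* Gaussian / Laplace noise (sd or scale 0.01 / 0.1–0.3 / 0.5) added i.i.d.
  per entry; Poisson perturbations are mean-centred (X − lambda) so the
  noise has mean zero.
* Spike / amplitude noise multiplies the values at ceil(level·T) randomly
  chosen *sampling points* by 5 (spike) or 2 (amplitude); the affected time
  points are drawn once and shared by all curves, so a spiked column scales
  with each curve's own level.  The amplitude factor 2 is a package default.
* MCAR masks entries independently; MAR scales masking probability by the
  within-curve quantile of the previous value (first point never masked);
  MNAR by the quantile of |value − curve median|.  Every curve keeps at
  least 4 observed points.
* Outlier contamination adds i.i.d. Gaussian noise of sd m·delta
  (m ∈ {1,2,3}; delta defaults to the clean sample sd) to every point of
  ceil(proportion·N) whole curves.

Agreement is measured by Kendall's tau-a (tied pairs counted in neither
P nor Q, full n(n−1)/2 denominator; a tau-b switch exists), Spearman's rho
via 1 − 6Σd²/(n(n²−1)) on average-tie ranks, and a score MAE after min–max
normalizing both score vectors to [0, 1] (constant vectors map to 0.5 —
without a common bounded scale, scores of different methods are not
comparable).  Monte-Carlo cells aggregate means with normal-approximation
95% intervals; replicate r of a cell uses seed base + r, so a base seed
reproduces a study bit-for-bit.  The bundled studies use 30–100 replicates
per cell, a size at which the standard error of a mean tau is below 0.01.

### What the studies show — and known gaps

The simulated curves share one periodic component and differ in slope and
a small phase; real data (e.g. annual pollutant series) have seasonal
components of varying amplitude, serial noise correlation, and no known
ground truth.  Passing studies therefore demonstrate internal correctness
and robustness ordering under the stated generator, not field accuracy.

Two findings from these studies are worth flagging:

* **Noise-free rankings are not exact.**  Even without noise, the phase
  term shifts within-segment integrals differently for different curves, so
  any segmented method (FP-OWA, WLR) and the variance-based FPCA score
  deviate from the pure slope order whenever more than one segment (or a
  phase-dominated component) is present.  Exact recovery holds only in the
  single-segment limit.  The package reports what it computes; it does not
  force the degenerate case.
* **Whole-curve Gaussian contamination defeats windowed filters.**  The
  Hampel filter replaces isolated window outliers; when every point of a
  contaminated curve is perturbed, its window MAD grows with the
  contamination and few points are flagged, so Hampel-filtered and plain
  rankings are statistically indistinguishable there.  The Huber
  (winsorizing) variant shrinks large deviations and retains a small edge.
  Both filters help most against sparse, spike-like corruption.

## Applied conveniences

Wide/long CSV ingestion maps ISO dates to day-of-year rescaled to [0, 1]
and keeps the calendar on the grid; `monthly_weights` spreads each
segment's depth weight over calendar months in proportion to day counts
and renormalizes, giving the per-month contribution shares used to
summarize seasonal pollution burden.  All CLI commands log their seed and
write a version + configuration header into every output file.

## Limitations

* The segmentation search is O(|eps grid| · |minPts grid|) DBSCAN runs per
  dataset; fine for T ≤ a few hundred, unindexed beyond that.
* MBD weighting is O(N·T·log N) via the rank formula, but WLR's crossing
  detection is O(N²T) and dominates at large N.
* No curve registration: phase misalignment is treated as signal, not
  warped away.
* Uniform-grid simulation only; the estimators themselves accept any
  strictly increasing grid.
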