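# fpowa — functional piecewise ordered weighted averaging

`fpowa` ranks a collection of curves by *magnitude*: given N units observed
over time on a common grid (daily pollutant concentrations for a set of
cities, expression trajectories, sensor channels, …), it answers "which
unit accumulates the most of the quantity over the window, and how sure are
we of that order?" — robustly, in the presence of noise, missing entries
and contaminated units.

Plain integral comparison answers that question only for clean data.  The
FP-OWA procedure implemented here hardens it in three steps:

1. **Smooth** — each curve y_i(t_j) = f_i(t_j) + ε_i(t_j) is fitted with a
   cubic B-spline under a curvature penalty λ∫(f″)², λ chosen per curve by
   GCV(λ) = SSE(λ)/(n − df(λ))²; missing values are imputed from the fit.
2. **Segment** — every time point is mapped to the feature vector
   [f_i(t), f_i′(t), f_i″(t)] over all curves (standardized, PCA-reduced),
   and DBSCAN — with (eps, minPts) chosen by a silhouette grid search —
   splits the time axis into m contiguous regimes.
3. **Weight and aggregate** — within segment i each curve's exact integral
   I_ij gets an ascending average-tie rank R_ij; segments are weighted by
   their mean modified band depth (w_i ∝ mean_j MBD_ij, Σw_i = 1); the
   final score is Score_j = Σ_i w_i·R_ij, ranked descending.

The package also ships four classical functional rankers behind the same
call signature (FPCA composite scores, crossing-segmented weighted ranks
(WLR), h-mode depth, random Tukey depth), Huber/Hampel robust pre-filters,
a seedable synthetic-data generator with five noise schemes, three
missingness mechanisms and outlier contamination, a Monte-Carlo evaluation
harness (Kendall τ, Spearman ρ, normalized-score MAE), and a residual
bootstrap for rank uncertainty.  See `docs/methods.md` for the numerical
details and design choices.

## Worked example

```python
from fpowa import (NoiseSpec, SimulationSpec, add_noise, fp_owa,
                   generate_truth, kendall_tau)

raw, true_integrals, true_ranking = generate_truth(
    SimulationSpec(n_curves=20, n_times=40, seed=7))
noisy = add_noise(raw, NoiseSpec("gaussian", 0.1), seed=8)

res = fp_owa(noisy)
print(kendall_tau(res.ranking, true_ranking))
```

Running `python examples/rank_simulated_curves.py` (which adds the
diagnostics) prints:

```
segments: 1  breakpoints: []
depth weights: [1.]  (larger = more central segment)
Kendall tau vs true integral ranking: 0.9368

rank  unit      score   true integral
   1  unit_17    20.00   2.2478
   2  unit_20    19.00   2.2445
   3  unit_2     18.00   2.1986
...
```

The generator's ground truth is the descending order of the exact curve
integrals (slope/2 for this family); τ = 0.94 says the noisy ranking agrees
with it on 97% of curve pairs.  On this draw the silhouette search found no
stable multi-regime structure and fell back to a single segment, so the
score reduces to the global-integral rank — with seasonal or regime-switching
data (see `examples/seasonal_segments_and_monthly_weights.py`) the
segmentation becomes non-trivial and each regime contributes by its depth
weight.

Each `examples/*.py` script is a self-contained narrative for one
capability: ranking with diagnostics, the Monte-Carlo method comparison,
robust pre-filters under contamination, bootstrap rank uncertainty, and
calendar segmentation with monthly contribution weights.

## Command line

```sh
fpowa simulate data.csv --n-curves 50 --noise gaussian --level 0.1 --seed 1
fpowa rank data.csv ranks.csv --method fpowa --diagnostics diag.json
fpowa benchmark bench.csv --noise-kind laplace --replicates 100 --seed 1
fpowa bootstrap data.csv stability.csv --resamples 200 --seed 1
fpowa segments data.csv segments.json
```

Wide CSV (time column + one column per unit; ISO dates or reals) is the
primary format; `--long-format` accepts (unit, time, value) tables.  Empty
cells, `NA` and `NaN` are treated as missing.

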