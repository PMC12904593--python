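"""Effect of Huber/Hampel pre-filters under whole-curve contamination.

Contaminates 30% of the curves with Gaussian noise of 3x the sample sd and
compares plain FP-OWA with its filtered variants (15 replicates).
"""

from fpowa import OutlierSpec, StudyConfig, run_study

cfg = StudyConfig(
    methods=("fpowa", "fpowa_huber", "fpowa_hampel"),
    n_curves=60, n_times=30,
    outlier=OutlierSpec(proportion=0.3, magnitude_mult=3),
    n_replicates=15, base_seed=21,
)
print("30% contaminated curves, amplitude 3*delta (15 replicates, n=60, t=30)")
for rep in run_study(cfg):
    print(f"{rep.method:14s} mean tau = {rep.kendall:.4f}  "
          f"95% CI ({rep.kendall_ci[0]:.4f}, {rep.kendall_ci[1]:.4f})")
print("""
Whole-curve Gaussian contamination leaves nothing isolated for a windowed
filter to flag, so all three variants land within each other's confidence
intervals here; the filters earn their keep against sparse, spike-like
corruption (rerun with NoiseSpec('spike', ...) to see the gap open).""")
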