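"""Residual-bootstrap uncertainty of a 13-unit ranking.

Mirrors the applied workflow: fit FP-OWA once, resample the spline
residuals within each curve 200 times, re-rank, and report per-unit rank
quantiles.  Units at the extremes of the ranking are expected to be stable
(narrow intervals); mid-field units compete and overlap.
"""

import numpy as np

from fpowa import NoiseSpec, SimulationSpec, add_noise, bootstrap_stability, generate_truth

raw, *_ = generate_truth(SimulationSpec(n_curves=13, n_times=50, seed=42))
noisy = add_noise(raw, NoiseSpec("gaussian", 0.1), seed=43)

rep = bootstrap_stability(noisy, B=200, seed=44)

print("unit      rank   [2.5%  25%  50%  75%  97.5%]   IQR")
for idx in np.argsort(rep.original_ranking):
    q = rep.quantiles[idx]
    print(f"{rep.unit_names[idx]:9s}{rep.original_ranking[idx]:4.0f}   "
          f"[{q[0]:5.1f}{q[1]:5.1f}{q[2]:5.1f}{q[3]:5.1f}{q[4]:6.1f}]  {rep.iqr[idx]:5.2f}")
print()
print("Narrow intervals at the top/bottom mean those positions are robust to")
print("the fitted noise level; wide middle intervals flag statistically")
print("indistinguishable units.")
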