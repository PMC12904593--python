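"""Rank a simulated sample of curves with FP-OWA and inspect the pipeline.

Generates 20 curves f_i(t) = s_i t + sin(2*pi*(t + p_i)) with Gaussian
noise, runs the full pipeline, and prints the detected segments, their
depth weights, and the top of the ranking next to the ground truth.
"""

import numpy as np

from fpowa import NoiseSpec, SimulationSpec, add_noise, fp_owa, generate_truth, kendall_tau

raw, true_integrals, true_ranking = generate_truth(SimulationSpec(n_curves=20, n_times=40, seed=7))
noisy = add_noise(raw, NoiseSpec("gaussian", 0.1), seed=8)

res = fp_owa(noisy)
seg = res.diagnostics["segmentation"]
w = res.diagnostics["segment_weights"]

print(f"segments: {seg.n_segments}  breakpoints: {np.round(seg.breakpoints, 3)}")
print(f"depth weights: {np.round(w.weights, 3)}  (larger = more central segment)")
print(f"Kendall tau vs true integral ranking: {kendall_tau(res.ranking, true_ranking):.4f}")
print()
print("rank  unit      score   true integral")
for idx in np.argsort(res.ranking)[:8]:
    print(f"{res.ranking[idx]:4.0f}  {res.unit_names[idx]:8s}{res.scores[idx]:8.2f}   {true_integrals[idx]:.4f}")
print()
print("The score is a depth-weighted average of within-segment integral ranks;")
print("rank 1 is the curve with the largest cumulative magnitude.")
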