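"""A miniature end-to-end experiment: simulate, mix, separate, evaluate.

Runs a reduced version of the full pipeline (small bundle, short recording)
twice with paired seeds and reports matching accuracy with and without
source separation, plus the random-trace negative control.
"""

import numpy as np

from fibermix import pipeline

config = pipeline.ScenarioConfig(
    n_packets=100_000, grid_dims=(120, 120, 120),
    n_fibers=20, density=100_000.0,
    box=((-0.3, 0.3), (-0.3, 0.3), (-0.3, 0.3)),
    duration=300.0, n_iterations=3, master_seed=1)

print("running", config.n_iterations, "iterations of a",
      config.n_fibers, "fiber scenario...")
result = pipeline.run_scenario(config)

print(result.summary().to_string(index=False))
sep, raw = result.accuracy_pairs()
print(f"\nseparated accuracy {np.mean(sep):.1f}% vs raw fiber accuracy "
      f"{np.mean(raw):.1f}% (paired t = {result.t_stat:.2f}, "
      f"p = {result.p_value:.3f})")
ctrl = np.mean([it.control_auc for it in result.iterations])
print(f"negative-control spike-detection AUC: {ctrl:.3f} (chance = 0.5)")
print("\nAccuracy = % of extracted traces matching a true neuron at")
print("r^2 >= 0.6; the control confirms matches are not coincidental.")
print("At small bundle sizes fibers barely overlap, so raw traces and")
print("separated components match about equally well; the separation")
print("advantage appears for denser bundles (see docs/methods.md).")
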