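"""Demixing a three-fiber toy recording with non-negative ICA.

Three fibers record overlapping mixtures of three nearby neurons plus a
distant background cloud. The pipeline inverse-filters the GCaMP6f
waveform, runs non-negative ICA, and matches the separated traces back to
the true neurons by squared correlation.
"""

from fibermix import pipeline

result, match, truth = pipeline.run_toy(duration=120.0, seed=0)

print(f"ICA converged: {result.converged} "
      f"(objective {result.objective[-1]:.3e} after {result.n_iter} steps)")
for i in range(match.r2.size):
    status = "accurate match" if match.matched[i] else "no match"
    print(f"separated trace {i} -> neuron {match.best_index[i]} "
          f"(r^2 = {match.r2[i]:.3f}, {status})")
print("\nEach separated trace should recover a distinct neuron with r^2")
print("well above the 0.6 accuracy bar, despite the background fluorescence.")
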