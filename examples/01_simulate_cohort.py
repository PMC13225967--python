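"""Generate a synthetic wheat-flour cohort and look at what it contains.

183 pellets from three cultivars, ash between 0.36 and 0.71 %, three
replicate THz pulse measurements each, plus one reference pulse.
"""
import numpy as np

from thzash import CohortConfig, generate_cohort

config = CohortConfig(seed=1)
table, traces, reference = generate_cohort(config)

print(table.head())
print(f"\nsamples: {len(table)}, traces: {len(traces)} "
      f"({config.replicates} replicates each)")
print(f"ash range: {table.ash_true.min():.3f}-{table.ash_true.max():.3f} % "
      f"(mean {table.ash_true.mean():.4f})")
print(f"pellet thickness: {table.thickness_mm.mean():.2f} "
      f"+/- {np.ptp(table.thickness_mm)/2:.2f} mm")
# The trace is a single-cycle THz pulse: its amplitude integrates to ~0 and
# the sample pulses arrive ~2 ps after the reference (refractive delay).
t0_ref = reference.time_ps[np.argmax(np.abs(reference.amplitude))]
t0_s = traces[0].time_ps[np.argmax(np.abs(traces[0].amplitude))]
print(f"pulse delay through sample 0: {t0_s - t0_ref:.2f} ps")
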