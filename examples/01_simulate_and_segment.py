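"""Simulate a noisy replication-timing profile and segment it.

Builds one synthetic chromosome (3200 probes at 40 kb spacing, S/G1
signal spanning 1-2) with 15%-of-range Gaussian noise, runs the
segmentation, and reports how well the continuous CTR/TTR map recovers
the known clean signal.
"""

import numpy as np

from arto import (SimulationSpec, add_gaussian_noise, rmse_percent,
                  segment_signal, simulate_clean_signal)

spec = SimulationSpec()            # the study conditions
clean, truth = simulate_clean_signal(spec, seed=1)
noisy = add_gaussian_noise(clean, 0.15, seed=2)

result = segment_signal(noisy)

rng = np.ptp(truth.clean_values)
rmse = rmse_percent(result.fitted, truth.clean_values, rng)
acc = np.mean(result.probe_types() == truth.true_type)

print(f"true segments:       {len(truth.true_breakpoints) + 1}")
print(f"recovered segments:  {result.n_segments} "
      f"({np.sum(result.seg_type == 'CTR')} CTR / {np.sum(result.seg_type == 'TTR')} TTR)")
print(f"RMSE:                {rmse:.2f}% of signal range")
print(f"raw type accuracy:   {acc:.3f}")
print()
print("RMSE is the per-probe error of the fitted ToR curve against the")
print("noise-free truth; a few percent of range at 15% noise means the")
print("map is far more accurate than any single measurement.")
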