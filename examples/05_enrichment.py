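"""CTR-residence enrichment of a gene set against matched random sets.

Are genes preferentially located in CTRs?  A naive comparison is
confounded by chromosome, gene length and ToR, so each of the 100
control sets redraws every gene at a random position with the same
chromosome, the same length and a similar ToR, keeping only placements
with a confident activity call.
"""

import numpy as np

from arto import (GenomicRegion, SimulationSpec, add_gaussian_noise,
                  ctr_residence_enrichment, segment_signal, simulate_clean_signal)

clean, truth = simulate_clean_signal(SimulationSpec(), seed=1)
noisy = add_gaussian_noise(clean, 0.10, seed=2)
result = segment_signal(noisy)

# plant 'genes' preferentially inside recovered CTRs
rng = np.random.default_rng(3)
ctr_idx = np.flatnonzero(result.seg_type == "CTR")
genes = []
for i in rng.choice(ctr_idx, 40):
    lo, hi = result.seg_start_x[i], result.seg_end_x[i]
    if hi - lo < 500_000:
        continue
    start = int(rng.uniform(lo + 150_000, hi - 200_000))
    genes.append(GenomicRegion("sim", start, start + 50_000))

enr = ctr_residence_enrichment(genes, result, n_random=100, seed=4)
print(f"genes with a defined call:  {enr.n_regions}")
print(f"observed % in CTRs:         {enr.observed_pct:.1f}%")
print(f"matched-control mean:       {np.mean(enr.null_pcts):.1f}% "
      f"(sd {np.std(enr.null_pcts):.1f})")
print(f"empirical p ((k+1)/(n+1)):  {enr.p_value:.4f}")
print()
print("Matching is deliberately conservative: controls share the genes'")
print("ToR bins, and CTRs dominate those bins, so the null percentage is")
print("itself high - any residual excess is attributable to activity type")
print("rather than to chromosome, length or ToR composition.")
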