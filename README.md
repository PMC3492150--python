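# arto

Segmentation of genome-wide DNA replication-timing (ToR) profiles into
**constant-timing regions (CTRs)** and **temporal transition regions
(TTRs)**, with per-locus time-of-replication estimates and
replication-activity-type calls.

## The problem

Replication timing is measured on tiling arrays as a normalized S/G1
DNA-abundance ratio per probe (~40 kb spacing): early-replicating loci
approach 2, late loci approach 1.  The raw measurements are noisy
(noise sd of 14–22% of the signal range is typical), but the underlying
program is highly structured: large regions replicate at essentially
one time (CTRs, the product of many coordinately firing origins),
separated by regions where timing changes gradually with position
(TTRs, where a replication fork propagates at 0.25–4 kb/min).

`arto` fits this structure directly.  The model is a **continuous
piecewise-linear curve** y(x) over genomic position x, in which every
piece is either

* flat (a CTR, slope 0), or
* sloped with |dy/dx| ∈ [R/(v_max·T_S), R/(v_min·T_S)] (a TTR), where
  R is the S-phase signal span, v the fork rate and T_S the S-phase
  duration — a faster fork gives a shallower slope.

Fitting proceeds per chromosome: robust noise estimation (MAD of first
differences), an optional median-3 prefilter, a Hough transform that
votes for candidate flat/sloped lines in sliding windows, a dynamic
program that assigns probes to candidate lines with breakpoints
restricted to line intersections (so the map is continuous by
construction) under a per-breakpoint penalty, a constrained
least-squares refit, and window restarts at the last committed
breakpoint.  Probes within 120 kb of a CTR boundary or 180 kb of a TTR
boundary are reported as `undefined` — the distances at which simulated
calls reach 80% certainty.

The package also includes the downstream comparative machinery: ToR
similarity between samples (the 30%-of-S-phase rule), activity-type
agreement, ToR-matched CTR/TTR probe pairing with paired tests,
windowed feature densities, and CTR-residence enrichment against
chromosome-, length- and ToR-matched random control sets — plus a full
synthetic-data simulator and benchmark harness.

## Worked example

```python
import numpy as np
from arto import (SimulationSpec, simulate_clean_signal, add_gaussian_noise,
                  segment_signal, rmse_percent)

spec = SimulationSpec()                        # 3200 probes, 40 kb spacing
clean, truth = simulate_clean_signal(spec, seed=1)
noisy = add_gaussian_noise(clean, 0.15, seed=2)   # sd = 15% of range

result = segment_signal(noisy)
rng = np.ptp(truth.clean_values)
print(rmse_percent(result.fitted, truth.clean_values, rng))
print(np.mean(result.probe_types() == truth.true_type))
```

Running this (it is `examples/01_simulate_and_segment.py`) prints

```
true segments:       133
recovered segments:  89 (41 CTR / 48 TTR)
RMSE:                5.51% of signal range
raw type accuracy:   0.892
```

i.e. from measurements whose per-probe noise is 15% of the signal
range, the fitted map recovers the clean profile to ~5% of range, and
~90% of probes get the correct CTR/TTR label even before the undefined
margins are applied.  The other scripts in `examples/` walk through
classification and region assignment, inter-sample comparison, matched
pairing, enrichment, and the benchmark report.

A thin CLI wraps the same functions:

```bash
arto simulate --n-signals 1 --seed 3 --out sim/
arto segment --in sim/signal_000.tsv --out-prefix fit   # BED + bedGraph + TSV
arto benchmark --n-signals 100 --noise 0.15 --seed 1 --out report.json
```

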