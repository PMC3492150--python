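"""Synthetic replication-timing signal generator.

Builds piecewise-linear ToR profiles alternating between constant regions
(CTRs, coordinated origin firing, zero slope) and temporal transition
regions (TTRs, fork propagation, slope bounded by the fork-rate range),
then adds white Gaussian noise at a chosen fraction of the signal range.
The defaults emulate the benchmark regime used throughout this package:
3200 probes at 40 kb spacing, signal spanning 1-2 (S/G1 ratio units),
fork rates 0.25-4 kb/min, noise sd in {2, 5, 10, 15, 20}% of range.

Every stochastic operation takes an explicit seed (int, SeedSequence or
Generator); all randomness flows through numpy's Generator API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ProbeSignal

CTR = "CTR"
TTR = "TTR"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def rate_to_slope(rate_kb_per_min: float, signal_range: float,
                  s_phase_minutes: float) -> float:
    """Convert a replication-fork rate to a ToR-signal slope (units per bp).

    A fork moving at ``v`` kb/min traverses ``v * 1000 * s_phase_minutes``
    bp over a full S phase, during which the signal spans ``signal_range``;
    faster forks therefore give shallower slopes.
    """
    if rate_kb_per_min <= 0 or signal_range <= 0 or s_phase_minutes <= 0:
        raise ValueError("rates, range and S-phase duration must be positive")
    return signal_range / (rate_kb_per_min * 1000.0 * s_phase_minutes)


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic chromosome."""

    n_probes: int = 3200
    probe_spacing: int = 40_000            # bp between probe midpoints
    signal_low: float = 1.0                # S/G1 ratio at the late extreme
    signal_high: float = 2.0               # S/G1 ratio at the early extreme
    ctr_length_range: tuple[int, int] = (10, 100)   # probes, log-uniform
    fork_rate_range: tuple[float, float] = (0.25, 4.0)  # kb/min
    s_phase_minutes: float = 480.0
    noise_sd_frac: float = 0.15            # sd as fraction of signal range

    def __post_init__(self) -> None:
        if self.n_probes < 2:
            raise ValueError("n_probes must be >= 2")
        if not (0 < self.fork_rate_range[0] < self.fork_rate_range[1]):
            raise ValueError("fork_rate_range must be positive and ordered")
        if not 0 <= self.noise_sd_frac < 1:
            raise ValueError("noise_sd_frac must be in [0, 1)")
        if self.signal_low >= self.signal_high:
            raise ValueError("signal_low must be < signal_high")

    @property
    def signal_range(self) -> float:
        return self.signal_high - self.signal_low

    def slope_bounds(self) -> tuple[float, float]:
        """(slope_min, slope_max) magnitudes in signal units per bp."""
        smin = rate_to_slope(self.fork_rate_range[1], self.signal_range, self.s_phase_minutes)
        smax = rate_to_slope(self.fork_rate_range[0], self.signal_range, self.s_phase_minutes)
        return smin, smax


@dataclass
class GroundTruth:
    """Known structure of a simulated signal.

    ``true_breakpoints`` are interior probe indices at segment junctions;
    ``dist_to_segment_end`` is the bp distance of each probe to the nearest
    segment end (chromosome ends included), 0 at breakpoints.
    """

    clean_values: np.ndarray
    true_type: np.ndarray            # "CTR"/"TTR" per probe
    true_breakpoints: np.ndarray     # interior probe indices
    dist_to_segment_end: np.ndarray  # bp per probe


def simulate_clean_signal(spec: SimulationSpec, seed) -> tuple[ProbeSignal, GroundTruth]:
    """Draw one clean piecewise-linear CTR/TTR profile.

    CTR levels are uniform over the signal range and CTR lengths
    log-uniform over ``ctr_length_range``; each TTR runs from the current
    level toward a freshly drawn target level at a log-uniform admissible
    slope, so continuity is exact and every TTR slope magnitude lies in
    the fork-rate-implied bounds.  The signal never leaves
    ``[signal_low, signal_high]`` because each TTR stops at (or before)
    its in-range target.
    """
    rng = _rng(seed)
    n, spacing = spec.n_probes, spec.probe_spacing
    low, high = spec.signal_low, spec.signal_high
    smin, smax = spec.slope_bounds()
    if smin * spacing >= spec.signal_range:
        raise ValueError("fork_rate_range incompatible with probe spacing: "
                         "one probe step would exceed the signal range")

    def draw_ctr_len() -> int:
        lo, hi = spec.ctr_length_range
        return max(1, int(round(np.exp(rng.uniform(np.log(lo), np.log(hi))))))

    node_idx = [0]
    node_val = [float(rng.uniform(low, high))]
    seg_types: list[str] = []
    seg_slopes: list[float] = []
    last = n - 1
    pos = 0
    cur = node_val[0]
    while pos < last:
        # constant region
        end = min(pos + draw_ctr_len(), last)
        node_idx.append(end)
        node_val.append(cur)
        seg_types.append(CTR)
        seg_slopes.append(0.0)
        pos = end
        if pos >= last:
            break
        # transition toward a fresh level, at an admissible slope
        while True:
            target = float(rng.uniform(low, high))
            if abs(target - cur) >= smin * spacing:
                break
        s_hi = min(smax, abs(target - cur) / spacing)
        slope = float(np.exp(rng.uniform(np.log(smin), np.log(s_hi))))
        n_ttr = max(1, int(abs(target - cur) // (slope * spacing)))
        end = min(pos + n_ttr, last)
        sign = 1.0 if target > cur else -1.0
        cur = cur + sign * slope * spacing * (end - pos)
        node_idx.append(end)
        node_val.append(cur)
        seg_types.append(TTR)
        seg_slopes.append(sign * slope)
        pos = end

    nodes = np.asarray(node_idx)
    positions = spacing * np.arange(1, n + 1, dtype=np.int64)
    clean = np.interp(np.arange(n), nodes, np.asarray(node_val))

    # probe at a junction belongs to the left segment
    true_type = np.empty(n, dtype="<U3")
    for k, typ in enumerate(seg_types):
        a, b = node_idx[k], node_idx[k + 1]
        sel = slice(a + 1, b + 1) if k > 0 else slice(a, b + 1)
        true_type[sel] = typ

    dist = np.min(np.abs(np.arange(n)[:, None] - nodes[None, :]), axis=1) * spacing
    truth = GroundTruth(
        clean_values=clean,
        true_type=true_type,
        true_breakpoints=nodes[1:-1].copy(),
        dist_to_segment_end=dist.astype(np.int64),
    )
    signal = ProbeSignal("sim", positions, clean, sample_id="synthetic")
    return signal, truth


def add_gaussian_noise(signal: ProbeSignal, sd_frac: float, seed,
                       value_range: float | None = None) -> ProbeSignal:
    """Add i.i.d. N(0, (sd_frac * range)^2) noise to a signal's values."""
    if sd_frac < 0:
        raise ValueError("sd_frac must be >= 0")
    if sd_frac == 0:
        return ProbeSignal(signal.chromosome, signal.positions.copy(),
                           signal.values.copy(), signal.sample_id)
    rng = _rng(seed)
    rng_range = signal.value_range if value_range is None else value_range
    noisy = signal.values + rng.normal(0.0, sd_frac * rng_range, size=len(signal))
    return ProbeSignal(signal.chromosome, signal.positions.copy(), noisy, signal.sample_id)
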