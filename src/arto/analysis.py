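"""Comparative procedures over annotated ToR maps.

Inter-sample similarity (the 30%-of-S-phase rule), activity-type
agreement, ToR-matched CTR/TTR probe pairing, windowed feature density,
and CTR-residence enrichment against matched random control sets.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import CTR_MARGIN, TTR_MARGIN, UNDEFINED, assign_region
from .io import GenomicRegion
from .segmentation import SegmentationResult

logger = logging.getLogger("arto")


def _merge_on_probes(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    return a.merge(b, on=["chromosome", "position"], suffixes=("_a", "_b"))


def compare_tor_maps(a: pd.DataFrame, b: pd.DataFrame,
                     threshold_frac: float = 0.30) -> float:
    """Fraction of shared probes whose ToR difference is small.

    Two probes agree when |ToR_a - ToR_b| < threshold_frac x S-phase
    length, with S-phase length taken as the mean of the two maps'
    fitted ranges.  Requires >= 100 shared probes.
    """
    m = _merge_on_probes(a, b)
    if len(m) < 100:
        raise ValueError(f"only {len(m)} shared probes; need >= 100")
    range_a = a["fitted_tor"].max() - a["fitted_tor"].min()
    range_b = b["fitted_tor"].max() - b["fitted_tor"].min()
    thresh = threshold_frac * 0.5 * (range_a + range_b)
    return float(np.mean(np.abs(m["fitted_tor_a"] - m["fitted_tor_b"]) < thresh))


def compare_activity_types(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Agreement fraction of CTR/TTR calls over probes defined in both maps."""
    m = _merge_on_probes(a, b)
    both = m[(m["activity_a"] != UNDEFINED) & (m["activity_b"] != UNDEFINED)]
    if len(both) == 0:
        raise ValueError("no probes defined in both maps")
    return float(np.mean(both["activity_a"] == both["activity_b"]))


@dataclass
class PairedProbeSet:
    """ToR-matched CTR/TTR probe pairs.

    ``ctr_index``/``ttr_index`` index into the pools handed to
    :func:`select_matched_pairs`; ``tor_tolerance`` bounds the
    within-pair ToR difference.
    """

    ctr_index: np.ndarray
    ttr_index: np.ndarray
    ctr_tor: np.ndarray
    ttr_tor: np.ndarray
    tor_tolerance: float
    seed: object = None

    def __len__(self) -> int:
        return len(self.ctr_index)


def _nearest_unused(sorted_tor, order, used, target):
    """Index (into original pool) of nearest unused probe to target ToR."""
    n = len(sorted_tor)
    lo = bisect_left(sorted_tor, target) - 1
    hi = lo + 1
    while lo >= 0 and used[order[lo]]:
        lo -= 1
    while hi < n and used[order[hi]]:
        hi += 1
    dl = target - sorted_tor[lo] if lo >= 0 else np.inf
    dr = sorted_tor[hi] - target if hi < n else np.inf
    if not np.isfinite(dl) and not np.isfinite(dr):
        return -1, np.inf
    return (order[lo], dl) if dl <= dr else (order[hi], dr)


def select_matched_pairs(ctr_tor, ttr_tor, n_pairs: int = 1000,
                         tolerance: float | None = None, seed=None) -> PairedProbeSet:
    """Draw ToR-matched CTR/TTR probe pairs without replacement.

    For each of ``n_pairs`` attempts a target ToR is drawn uniformly over
    the pooled ToR span and the unused probe nearest the target is taken
    from each pool; the pair is discarded (neither probe consumed) when
    either distance to the target exceeds ``tolerance`` (default 1% of
    the pooled span).  The two resulting ToR distributions are close to
    uniform and to each other.
    """
    ctr_tor = np.asarray(ctr_tor, dtype=float)
    ttr_tor = np.asarray(ttr_tor, dtype=float)
    if len(ctr_tor) == 0 or len(ttr_tor) == 0:
        raise ValueError("both pools must be non-empty")
    rng = np.random.default_rng(seed)
    lo = min(ctr_tor.min(), ttr_tor.min())
    hi = max(ctr_tor.max(), ttr_tor.max())
    if tolerance is None:
        tolerance = 0.01 * (hi - lo)

    pools = []
    for tor in (ctr_tor, ttr_tor):
        order = np.argsort(tor, kind="stable")
        pools.append((tor[order].tolist(), order, np.zeros(len(tor), dtype=bool)))

    ci, ti = [], []
    for _ in range(n_pairs):
        if pools[0][2].all() or pools[1][2].all():
            logger.warning("probe pools exhausted after %d pairs", len(ci))
            break
        target = rng.uniform(lo, hi)
        c, cd = _nearest_unused(*pools[0], target)
        t, td = _nearest_unused(*pools[1], target)
        if c < 0 or t < 0 or cd > tolerance or td > tolerance:
            continue
        pools[0][2][c] = True
        pools[1][2][t] = True
        ci.append(c)
        ti.append(t)
    ci = np.asarray(ci, dtype=np.int64)
    ti = np.asarray(ti, dtype=np.int64)
    return PairedProbeSet(ci, ti, ctr_tor[ci], ttr_tor[ti],
                          tor_tolerance=2.0 * tolerance, seed=seed)


def _merged_intervals(regions: list[GenomicRegion]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted((r.start, r.end) for r in regions)
    starts, ends = [], []
    for s, e in ivs:
        if ends and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def distance_to_regions(positions, regions: list[GenomicRegion]) -> np.ndarray:
    """bp distance from each position to the nearest interval (0 if inside)."""
    positions = np.asarray(positions)
    if not regions:
        return np.full(len(positions), np.inf)
    starts, ends = _merged_intervals(regions)
    i = np.searchsorted(starts, positions, side="right") - 1
    inside = (i >= 0) & (positions < ends[np.clip(i, 0, None)])
    d_left = np.where(i >= 0, positions - (ends[np.clip(i, 0, None)] - 1), np.inf)
    j = np.clip(i + 1, 0, len(starts) - 1)
    d_right = np.where(i + 1 < len(starts), starts[j] - positions, np.inf)
    dist = np.minimum(np.maximum(d_left, 0), np.maximum(d_right, 0))
    return np.where(inside, 0.0, dist)


def filter_intergenic(probes: pd.DataFrame, genes: list[GenomicRegion],
                      min_dist: int = 20_000) -> pd.DataFrame:
    """Keep probes located more than ``min_dist`` bp from every gene."""
    if not genes:
        return probes.copy()
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    keep = np.ones(len(probes), dtype=bool)
    pos = probes["position"].to_numpy()
    chroms = probes["chromosome"].to_numpy()
    for chrom, gs in by_chrom.items():
        sel = chroms == chrom
        if sel.any():
            keep[sel] = distance_to_regions(pos[sel], gs) > min_dist
    return probes.loc[keep].copy()


def window_feature_density(feature_positions, probe_positions, window_bp: float,
                           weights=None) -> np.ndarray:
    """Feature count (or mean weight) in a window centered on each probe.

    Counts features within ``[pos - window/2, pos + window/2]``
    (inclusive).  With ``weights`` the mean weight in the window is
    returned instead (NaN for empty windows) — e.g. percent methylation
    of calls around each probe.
    """
    f = np.sort(np.asarray(feature_positions, dtype=float))
    if weights is not None:
        w = np.asarray(weights, dtype=float)[np.argsort(np.asarray(feature_positions, dtype=float), kind="stable")]
        cw = np.concatenate([[0.0], np.cumsum(w)])
    pos = np.asarray(probe_positions, dtype=float)
    half = window_bp / 2.0
    lo = np.searchsorted(f, pos - half, side="left")
    hi = np.searchsorted(f, pos + half, side="right")
    counts = hi - lo
    if weights is None:
        return counts.astype(float)
    sums = cw[hi] - cw[lo]
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


@dataclass
class EnrichmentResult:
    """Observed CTR residence vs matched random control sets."""

    observed_pct: float
    null_pcts: np.ndarray
    p_value: float               # (k+1)/(n+1)-corrected empirical p
    n_regions: int
    n_fallback: int              # null draws that dropped the ToR constraint
    region_table: pd.DataFrame | None = None
    null_regions: list[list[GenomicRegion]] | None = None


def ctr_residence_enrichment(regions: list[GenomicRegion],
                             results: dict[str, SegmentationResult] | SegmentationResult,
                             n_random: int = 100, tor_bin_frac: float = 0.10,
                             ctr_margin: int = CTR_MARGIN, ttr_margin: int = TTR_MARGIN,
                             max_tries: int = 1000, seed=None,
                             keep_null_regions: bool = False) -> EnrichmentResult:
    """Is a region set (genes, lincRNA exons, ...) enriched in CTRs?

    Observed statistic: percent of defined regions whose activity is
    CTR.  Each of ``n_random`` null sets redraws every region at a
    random location on the same chromosome, with the same length, a
    defined activity call, and the same ToR bin (width ``tor_bin_frac``
    of the fitted range); regions for which no such placement is found
    within ``max_tries`` are redrawn without the ToR constraint (count
    reported).  Empirical p uses the (k+1)/(n+1) correction.
    """
    if isinstance(results, SegmentationResult):
        results = {results.chromosome: results}
    rng = np.random.default_rng(seed)

    fitted_all = np.concatenate([r.fitted for r in results.values()])
    tor_lo = float(fitted_all.min())
    tor_range = float(fitted_all.max() - tor_lo) or 1.0
    binw = tor_bin_frac * tor_range

    def tor_bin(t: float) -> int:
        return int(np.floor((t - tor_lo) / binw))

    rows = []
    for r in regions:
        res = results.get(r.chromosome)
        if res is None:
            continue
        tor, act = assign_region(res, r, ctr_margin, ttr_margin)
        rows.append((r, tor, act))
    defined = [(r, tor, act) for r, tor, act in rows if act != UNDEFINED]
    n_drop = len(rows) - len(defined)
    if n_drop:
        logger.info("dropped %d regions with undefined activity", n_drop)
    if not defined:
        raise ValueError("no regions with defined activity")
    observed = 100.0 * np.mean([act == "CTR" for _, _, act in defined])

    n_fallback = 0
    null_pcts = np.empty(n_random)
    kept_nulls: list[list[GenomicRegion]] = []
    for k in range(n_random):
        hits = 0
        null_set: list[GenomicRegion] = []
        for r, tor, _ in defined:
            res = results[r.chromosome]
            length = len(r)
            lo_x = int(np.ceil(res.seg_start_x[0]))
            hi_x = int(np.floor(res.seg_end_x[-1])) - length
            if hi_x <= lo_x:
                raise ValueError(f"region longer than segmented territory on {r.chromosome}")
            want = tor_bin(tor)
            placed = None
            for constrain_tor in (True, False):
                for _ in range(max_tries):
                    s = int(rng.integers(lo_x, hi_x + 1))
                    cand = GenomicRegion(r.chromosome, s, s + length, r.name)
                    ctor, cact = assign_region(res, cand, ctr_margin, ttr_margin)
                    if cact == UNDEFINED:
                        continue
                    if constrain_tor and tor_bin(ctor) != want:
                        continue
                    placed = (cand, cact)
                    break
                if placed is not None:
                    break
                if constrain_tor:
                    n_fallback += 1
            if placed is None:
                raise RuntimeError("could not place a defined null region")
            cand, cact = placed
            hits += cact == "CTR"
            if keep_null_regions:
                null_set.append(cand)
        null_pcts[k] = 100.0 * hits / len(defined)
        if keep_null_regions:
            kept_nulls.append(null_set)

    p = (1 + int(np.sum(null_pcts >= observed))) / (n_random + 1)
    table = pd.DataFrame(
        [(r.chromosome, r.start, r.end, r.name, tor, act) for r, tor, act in defined],
        columns=["chromosome", "start", "end", "name", "tor", "activity"])
    return EnrichmentResult(float(observed), null_pcts, float(p), len(defined),
                            n_fallback, table, kept_nulls if keep_null_regions else None)


def paired_difference_test(ctr_values, ttr_values) -> tuple[float, float, float]:
    """Two-sided paired t-test on (TTR value - CTR value) over matched pairs.

    Returns (mean difference, t statistic, p).  Pairs with a missing
    value in either member are dropped; at least 10 complete pairs are
    required.  A zero-variance nonzero difference is degenerate and is
    reported as t = +/-inf, p = 0.
    """
    c = np.asarray(ctr_values, dtype=float)
    t = np.asarray(ttr_values, dtype=float)
    if c.shape != t.shape:
        raise ValueError("value arrays must be aligned per pair")
    ok = np.isfinite(c) & np.isfinite(t)
    c, t = c[ok], t[ok]
    if len(c) < 10:
        raise ValueError(f"only {len(c)} complete pairs; need >= 10")
    d = t - c
    if np.std(d, ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, 0.0, 1.0
        return float(d.mean()), float(np.sign(d.mean()) * np.inf), 0.0
    stat = stats.ttest_rel(t, c)
    return float(d.mean()), float(stat.statistic), float(stat.pvalue)
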