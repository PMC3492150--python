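"""Piecewise-linear CTR/TTR segmentation of replication-timing signals.

The model: a genome-wide ToR profile is a continuous piecewise-linear
curve whose pieces are either constant (CTRs — multiple coordinately
firing origins) or sloped within the range implied by replication-fork
rates of 0.25-4 kb/min (TTRs).  There are no discontinuities (no fork
barriers).

The fitting pipeline per chromosome:

1. estimate the measurement-noise sd with a robust MAD estimator on
   first differences (the piecewise-linear trend cancels);
2. optionally apply a running median-3 prefilter;
3. slide windows of ``window_size`` probes over the signal; in each
   window a Hough transform votes for candidate lines that are either
   flat or admissibly sloped;
4. dynamic programming assigns probes to candidate lines, with segment
   switches allowed only where consecutive lines intersect (continuity)
   and charged a per-breakpoint penalty;
5. a constrained least-squares refit with fixed breakpoints and fixed
   per-segment type (slope 0 vs bounded slope) produces the final
   continuous fit;
6. all segments but the last are committed and the next window restarts
   at the last committed breakpoint, anchored to its value, until the
   final window commits everything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import lsq_linear

from .io import ProbeSignal
from .simulate import rate_to_slope

logger = logging.getLogger("arto")

CTR = "CTR"
TTR = "TTR"

# sd of the middle order statistic of 3 iid N(0,1) draws; used to rescale
# the raw-noise estimate after the median-3 prefilter
_MEDIAN3_SD_FACTOR = 0.670


@dataclass
class FitParameters:
    """All segmentation tunables.

    ``noise_sd`` is the raw measurement-noise sd in signal units; when
    None it is estimated by MAD.  ``breakpoint_penalty`` (signal units
    squared) defaults to ``penalty_multiplier * sd^2 * ln(window_size)``,
    a BIC-flavored per-breakpoint charge.  Hough resolution is tied to
    the measured noise: intercept bins of ``0.5 * sd`` and a vote band of
    ``hough_vote_band * sd``.
    """

    window_size: int = 300
    fork_rate_range: tuple[float, float] = (0.25, 4.0)   # kb/min
    s_phase_minutes: float = 480.0
    noise_sd: float | None = None
    hough_slope_bins: int = 24            # per sign, log-spaced, plus slope 0
    hough_intercept_bin: float | None = None   # default 0.5 * noise_sd
    hough_vote_band: float = 0.75         # multiples of noise_sd
    hough_vote_threshold: int | None = None    # default max(6, n // 30)
    breakpoint_penalty: float | None = None
    penalty_multiplier: float = 4.0
    max_breakpoints_per_window: int | None = None
    max_candidates: int = 48
    prefilter_median: bool = True
    signal_range: float | None = None     # default: robust range of the data
    gap_factor: float = 10.0              # split blocks at gaps > factor * median spacing

    def __post_init__(self) -> None:
        if self.window_size < 8:
            raise ValueError("window_size must be >= 8")
        if self.breakpoint_penalty is not None and self.breakpoint_penalty < 0:
            raise ValueError("breakpoint_penalty must be >= 0")
        if not (0 < self.fork_rate_range[0] < self.fork_rate_range[1]):
            raise ValueError("fork_rate_range must be positive and ordered")


@dataclass
class CandidateLine:
    """A line hypothesis from the Hough accumulator.

    ``slope`` is in signal units per bp (0 for a constant line);
    ``intercept`` is the value at the window's reference x.
    """

    slope: float
    intercept: float
    votes: int


@dataclass
class SegmentationResult:
    """A continuous piecewise-linear ToR map for one chromosome.

    Segments are stored as parallel arrays; within a block (a run of
    probes not split by a large gap) consecutive segments share their
    junction exactly.  ``fitted`` holds the per-probe value on the map.
    """

    chromosome: str
    seg_start_x: np.ndarray   # bp, may be fractional (line intersections)
    seg_end_x: np.ndarray
    seg_start_v: np.ndarray
    seg_end_v: np.ndarray
    seg_type: np.ndarray      # "CTR"/"TTR" per segment
    seg_block: np.ndarray     # block id per segment
    positions: np.ndarray     # probe positions
    fitted: np.ndarray        # per-probe fitted ToR
    objective: float | None = None   # SSE + penalty * breakpoints (windowed fits)

    @property
    def n_segments(self) -> int:
        return len(self.seg_type)

    @property
    def breakpoints(self) -> np.ndarray:
        """All segment-boundary positions, block ends included."""
        return np.unique(np.concatenate([self.seg_start_x, self.seg_end_x]))

    @property
    def segment_slopes(self) -> np.ndarray:
        return (self.seg_end_v - self.seg_start_v) / (self.seg_end_x - self.seg_start_x)

    def probe_segment_index(self) -> np.ndarray:
        """Containing segment per probe; a probe on a junction goes left."""
        idx = np.searchsorted(self.seg_end_x, self.positions, side="left")
        return np.clip(idx, 0, self.n_segments - 1)

    def probe_types(self) -> np.ndarray:
        """Per-probe CTR/TTR call with no undefined margins."""
        return self.seg_type[self.probe_segment_index()]

    def value_at(self, pos) -> np.ndarray:
        """Map value at arbitrary bp positions (within segmented territory)."""
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        idx = np.clip(np.searchsorted(self.seg_end_x, pos, side="left"),
                      0, self.n_segments - 1)
        x0, x1 = self.seg_start_x[idx], self.seg_end_x[idx]
        v0, v1 = self.seg_start_v[idx], self.seg_end_v[idx]
        frac = np.where(x1 > x0, (pos - x0) / np.where(x1 > x0, x1 - x0, 1.0), 0.0)
        return v0 + frac * (v1 - v0)


def slope_bounds(params: FitParameters, signal_range: float) -> tuple[float, float]:
    """Admissible TTR slope magnitudes (signal units per bp).

    The fastest fork gives the shallowest slope and vice versa.
    """
    smin = rate_to_slope(params.fork_rate_range[1], signal_range, params.s_phase_minutes)
    smax = rate_to_slope(params.fork_rate_range[0], signal_range, params.s_phase_minutes)
    return smin, smax


def estimate_noise_mad(values) -> float:
    """Robust noise-sd estimate from first differences.

    Differencing cancels the piecewise-linear trend (slopes contribute
    far less than noise at typical probe spacing) and turns breakpoints
    into sparse outliers, which the MAD resists.  For Gaussian noise,
    sd(diff) = sigma * sqrt(2), hence the 1.4826 / sqrt(2) scaling.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        raise ValueError("need at least 8 values to estimate noise")
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def prefilter(signal: ProbeSignal, params: FitParameters) -> ProbeSignal:
    """Running median-3 noise filter (endpoints copied); no-op when disabled."""
    if not params.prefilter_median or len(signal) < 3:
        return signal
    v = signal.values
    out = v.copy()
    out[1:-1] = np.median(np.stack([v[:-2], v[1:-1], v[2:]]), axis=0)
    return ProbeSignal(signal.chromosome, signal.positions.copy(), out, signal.sample_id)


def _robust_range(values: np.ndarray) -> float:
    lo, hi = np.quantile(values, [0.005, 0.995])
    return float(max(hi - lo, 1e-12))


def _hough_slopes(params: FitParameters, smin: float, smax: float) -> np.ndarray:
    mags = np.logspace(np.log10(smin), np.log10(smax), params.hough_slope_bins)
    return np.concatenate([[0.0], mags, -mags])


def hough_lines(window: ProbeSignal, params: FitParameters,
                noise_sd: float | None = None,
                signal_range: float | None = None) -> list[CandidateLine]:
    """Vote for candidate lines (flat or admissibly sloped) in one window.

    For each slope on the grid the per-probe intercepts at the window's
    first position are histogrammed; a cell's votes count the probes
    within ``hough_vote_band * noise_sd`` of its line.  Local maxima
    above the vote threshold are returned, strongest first, deduplicated
    by non-maximum suppression along the intercept axis.
    """
    x = window.positions.astype(float)
    y = window.values
    n = len(x)
    if n < 4:
        raise ValueError("a Hough window needs at least 4 probes")
    if noise_sd is None:
        noise_sd = params.noise_sd if params.noise_sd is not None else estimate_noise_mad(y)
    rng_ = signal_range if signal_range is not None else (
        params.signal_range if params.signal_range is not None else _robust_range(y))
    # floor keeps the accumulator finite on (near-)noiseless data
    sd = max(noise_sd, 5e-3 * rng_)
    smin, smax = slope_bounds(params, rng_)
    slopes = _hough_slopes(params, smin, smax)
    binw = params.hough_intercept_bin if params.hough_intercept_bin is not None else 0.5 * sd
    band = params.hough_vote_band * sd
    half = max(1, int(round(band / binw)))
    thresh = params.hough_vote_threshold if params.hough_vote_threshold is not None \
        else max(6, n // 30)

    x_ref = x[0]
    dx = x - x_ref
    # a sloped grid line misses a true segment's slope by up to half the
    # log-grid step; over the longest span that slope can sustain
    # (~range/slope) the intercepts drift by ~(sqrt(ratio)-1) * range / 2,
    # so sloped cells vote with a correspondingly widened band
    ratio = (smax / smin) ** (1.0 / max(params.hough_slope_bins - 1, 1))
    slope_allow = 0.5 * (np.sqrt(ratio) - 1.0) * rng_

    flat: list[CandidateLine] = []
    per_slope: list[list[CandidateLine]] = []
    for s in slopes:
        is_flat = s == 0.0
        band_s = band if is_flat else band + slope_allow
        thresh_s = thresh if is_flat else max(4, n // 60)
        cap = 12 if is_flat else 8
        b = y - s * dx
        # greedy peak extraction with point removal: take the
        # best-supported intercept cell, claim its probes, repeat —
        # nearby but distinct levels stay separable
        remaining = np.ones(n, dtype=bool)
        found: list[CandidateLine] = []
        while len(found) < cap:
            bs = np.sort(b[remaining])
            if len(bs) < thresh_s:
                break
            centers = (np.unique(np.floor(bs / binw)) + 0.5) * binw
            counts = (np.searchsorted(bs, centers + band_s, side="right")
                      - np.searchsorted(bs, centers - band_s, side="left"))
            j = int(np.argmax(counts))
            if counts[j] < thresh_s:
                break
            support = remaining & (np.abs(b - centers[j]) <= band_s)
            found.append(CandidateLine(float(s), float(b[support].mean()),
                                       int(support.sum())))
            remaining &= ~support
        if is_flat:
            flat = found
        else:
            per_slope.append(found)

    # all flat lines, then sloped lines round-robin across slope bins so
    # every slope magnitude stays represented under the candidate cap
    cands = list(flat)
    budget = params.max_candidates - len(cands)
    rank = 0
    while budget > 0 and any(len(p) > rank for p in per_slope):
        level = sorted((p[rank] for p in per_slope if len(p) > rank),
                       key=lambda c: -c.votes)
        take = level[:budget]
        cands.extend(take)
        budget -= len(take)
        rank += 1
    cands.sort(key=lambda c: -c.votes)
    if not cands:
        cands = [CandidateLine(0.0, float(np.median(y)), 0)]
    return cands


def _transition_candidates(x, y, smin, smax, halfwin: int = 2,
                           max_new: int | None = None) -> list[CandidateLine]:
    """Locally fitted lines at steep-slope maxima.

    Steep TTRs span only a couple of probes, far too few to win Hough
    votes, yet the DP needs a line through the actual step to move
    between two constant levels (flat lines never intersect).  A short
    sliding least-squares fit recovers exactly those connectors: local
    maxima of |slope| with admissible magnitude, clamped to the bounds.
    """
    n = len(x)
    w = 2 * halfwin + 1
    if n < w:
        return []
    if max_new is None:
        max_new = max(16, n // 10)
    cs = np.cumsum
    pad = lambda a: np.concatenate([[0.0], cs(a)])
    Sx, Sy = pad(x), pad(y)
    Sxx, Sxy = pad(x * x), pad(x * y)

    def roll(S):
        return S[w:] - S[:-w]

    sx, sy, sxx, sxy = roll(Sx), roll(Sy), roll(Sxx), roll(Sxy)
    denom = w * sxx - sx * sx
    slope = np.where(denom > 0, (w * sxy - sx * sy) / np.where(denom > 0, denom, 1.0), 0.0)
    mag = np.abs(slope)
    ok = (mag >= smin) & (mag <= 2.0 * smax)
    order = np.argsort(mag)[::-1]
    x_ref = x[0]
    out: list[CandidateLine] = []
    taken = np.zeros(len(slope), dtype=bool)
    for j in order:
        if len(out) >= max_new or not ok[j]:
            break
        if taken[j]:
            continue
        s = float(np.sign(slope[j]) * min(mag[j], smax))
        xbar, ybar = sx[j] / w, sy[j] / w
        out.append(CandidateLine(s, float(ybar - s * (xbar - x_ref)), w))
        taken[max(0, j - w):j + w + 1] = True

    # two-point connectors through the steepest probe gaps: a one-gap
    # level step is invisible to any vote-based detector but defines its
    # connecting line exactly
    dy = np.diff(y)
    dx = np.diff(x)
    gap_slope = dy / dx
    gmag = np.abs(gap_slope)
    gok = gmag >= smin
    gorder = np.argsort(gmag)[::-1]
    gtaken = np.zeros(len(dy), dtype=bool)
    n_pair = 0
    for j in gorder:
        if n_pair >= max_new or not gok[j]:
            break
        if gtaken[j]:
            continue
        s = float(np.sign(gap_slope[j]) * min(gmag[j], smax))
        xm, ym = 0.5 * (x[j] + x[j + 1]), 0.5 * (y[j] + y[j + 1])
        out.append(CandidateLine(s, float(ym - s * (xm - x_ref)), 2))
        gtaken[max(0, j - 2):j + 3] = True
        n_pair += 1
    return out


def _dp_assign(x, y, lines, penalty, anchor=None, max_bp=None):
    """Assign probes to candidate lines by DP; return run list.

    A switch from line l' to line l is allowed only in the probe gap that
    contains their intersection, which makes the resulting fit continuous
    by construction.  Ties prefer staying on the current line (fewer
    breakpoints).  ``anchor`` = (x, v) adds a pseudo-residual tying the
    first line to the previous window's committed endpoint.
    """
    n = len(x)
    L = len(lines)
    s = np.array([l.slope for l in lines])
    b = np.array([l.intercept for l in lines])
    x_ref = x[0]
    R = (y[:, None] - (s[None, :] * (x[:, None] - x_ref) + b[None, :])) ** 2

    # intersections -> allowed switch gap per ordered line pair
    gap_pairs: dict[int, list[tuple[int, int, float]]] = {}
    for l1 in range(L):
        for l2 in range(L):
            if l1 == l2 or s[l1] == s[l2]:
                continue
            xint = x_ref + (b[l2] - b[l1]) / (s[l1] - s[l2])
            g = int(np.searchsorted(x, xint, side="left"))
            if 1 <= g <= n - 1 and x[g - 1] < xint <= x[g]:
                gap_pairs.setdefault(g, []).append((l1, l2, xint))

    # a segment can contain zero probes (a one-gap step between two
    # constant levels): both of its boundary intersections fall in the
    # same gap, so allow a chained two-switch move through a middle line
    gap_triples: dict[int, list[tuple[int, int, int]]] = {}
    for g, pairs in gap_pairs.items():
        by_from: dict[int, list[tuple[int, float]]] = {}
        for lf, lt, xi in pairs:
            by_from.setdefault(lf, []).append((lt, xi))
        trips = []
        for lf, lt, xi in pairs:
            for lt2, xi2 in by_from.get(lt, ()):
                if lt2 != lf and xi <= xi2:
                    trips.append((lf, lt2, lt))
        if trips:
            gap_triples[g] = trips

    anchor_pen = np.zeros(L)
    if anchor is not None:
        ax, av = anchor
        anchor_pen = (av - (s * (ax - x_ref) + b)) ** 2

    if max_bp is None:
        dp = R[0] + anchor_pen
        back = np.full((n, L), -1, dtype=np.int32)
        via = np.full((n, L), -1, dtype=np.int32)
        for i in range(1, n):
            pairs = gap_pairs.get(i)
            if pairs:
                new = dp.copy()
                for lf, lt, _ in pairs:
                    c = dp[lf] + penalty
                    if c < new[lt] - 1e-12:
                        new[lt] = c
                        back[i, lt] = lf
                        via[i, lt] = -1
                for lf, lt, lv in gap_triples.get(i, ()):
                    c = dp[lf] + 2.0 * penalty
                    if c < new[lt] - 1e-12:
                        new[lt] = c
                        back[i, lt] = lf
                        via[i, lt] = lv
                dp = new + R[i]
            else:
                dp = dp + R[i]
        l = int(np.argmin(dp))
        obj = float(dp[l])
    else:
        K = int(max_bp)
        dp = np.full((K + 1, L), np.inf)
        dp[0] = R[0] + anchor_pen
        back = np.full((n, K + 1, L), -1, dtype=np.int32)
        via = np.full((n, K + 1, L), -1, dtype=np.int32)
        for i in range(1, n):
            new = dp.copy()
            for lf, lt, _ in gap_pairs.get(i, ()):
                c = dp[:-1, lf] + penalty
                view = new[1:, lt]
                imp = c < view - 1e-12
                view[imp] = c[imp]
                back[i, 1:, lt][imp] = lf
                via[i, 1:, lt][imp] = -1
            if K >= 2:
                for lf, lt, lv in gap_triples.get(i, ()):
                    c = dp[:-2, lf] + 2.0 * penalty
                    view = new[2:, lt]
                    imp = c < view - 1e-12
                    view[imp] = c[imp]
                    back[i, 2:, lt][imp] = lf
                    via[i, 2:, lt][imp] = lv
            dp = new + R[i]
        k, l = np.unravel_index(int(np.argmin(dp)), dp.shape)
        obj = float(dp[k, l])

    # backtrack into runs of consecutive probes on one line; a run with
    # first_probe > last_probe is a zero-probe segment
    runs: list[tuple[int, int, int]] = []   # (line, first_probe, last_probe)
    end = n - 1
    cur = l
    if max_bp is None:
        for i in range(n - 1, 0, -1):
            prev = back[i, cur]
            if prev != -1:
                runs.append((cur, i, end))
                if via[i, cur] != -1:
                    runs.append((int(via[i, cur]), i, i - 1))
                end = i - 1
                cur = int(prev)
    else:
        kk = int(k)
        for i in range(n - 1, 0, -1):
            prev = back[i, kk, cur]
            if prev != -1:
                runs.append((cur, i, end))
                if via[i, kk, cur] != -1:
                    runs.append((int(via[i, kk, cur]), i, i - 1))
                    kk -= 1
                end = i - 1
                cur = int(prev)
                kk -= 1
    runs.append((cur, 0, end))
    runs.reverse()
    return runs, obj


def _knots_from_runs(x, runs, lines, anchor=None):
    """Knot positions, segment types and TTR signs implied by DP runs."""
    m = len(runs)
    s = np.array([lines[r[0]].slope for r in runs])
    knots = [anchor[0] if anchor is not None else x[0]]
    for j in range(m - 1):
        l1, l2 = runs[j][0], runs[j + 1][0]
        xint = (lines[l2].intercept - lines[l1].intercept) / (
            lines[l1].slope - lines[l2].slope) + x[0]
        knots.append(xint)
    knots.append(x[-1])
    types = np.where(s == 0.0, CTR, TTR)
    return np.asarray(knots, dtype=float), types, np.sign(s)


def _polish_knots(x, y, knots, types, signs, smin, smax, init_s, init_b, n_iter=2):
    """Sharpen breakpoint positions by alternating line fits and knot moves.

    Starting from the DP-selected lines, each segment's line is refit
    unconstrained on its currently assigned probes (CTR level from >= 1
    probe, TTR slope from >= 3 probes, clamped to the admissible
    magnitude with its sign kept; shorter segments keep their DP line),
    and each interior knot moves to the intersection of its neighbors'
    lines.  Continuity is restored by the constrained refit that follows.
    """
    m = len(types)
    if m < 2:
        return knots
    knots = knots.copy()
    line_s = np.asarray(init_s, dtype=float).copy()
    line_b = np.asarray(init_b, dtype=float).copy()
    for _ in range(n_iter):
        seg = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, m - 1)
        for j in range(m):
            sel = seg == j
            nsel = int(sel.sum())
            xs, ys = x[sel], y[sel]
            if types[j] == CTR and nsel >= 1:
                line_s[j], line_b[j] = 0.0, float(ys.mean())
            elif types[j] == TTR and nsel >= 3:
                xm = xs.mean()
                denom = float(np.sum((xs - xm) ** 2))
                sl = float(np.sum((xs - xm) * (ys - ys.mean())) / denom) if denom > 0 else 0.0
                mag = np.clip(abs(sl), smin, smax)
                sl = (signs[j] if sl * signs[j] <= 0 else np.sign(sl)) * mag
                line_s[j] = sl
                line_b[j] = float(np.mean(ys - sl * xs))
        new = knots.copy()
        for k in range(1, m):
            s1, s2 = line_s[k - 1], line_s[k]
            if s1 == s2:
                continue
            xint = (line_b[k] - line_b[k - 1]) / (s1 - s2)
            lo = new[k - 1] + 1.0
            hi = knots[k + 1] - 1.0
            if lo < hi:
                new[k] = float(np.clip(xint, lo, hi))
        knots = new
    return knots


def _refit_knots(x, y, knots, types, signs, smin, smax, anchor=None):
    """Constrained LS refit with fixed knots and fixed segment types.

    Parametrized by the value at the first knot (fixed to the anchor if
    given) plus one slope per TTR segment, box-bounded to the admissible
    magnitude range with its DP-chosen sign.  CTR slopes are fixed to 0,
    so continuity and admissibility hold exactly.
    """
    m = len(types)
    ttr_idx = np.flatnonzero(types == TTR)
    free_v0 = anchor is None
    ncol = int(free_v0) + len(ttr_idx)
    if ncol == 0:
        base = float(anchor[1])
        return np.full(m + 1, base), types, np.full(len(x), base)

    target = y - (0.0 if free_v0 else anchor[1])
    A = np.zeros((len(x), ncol))
    lb = np.full(ncol, -np.inf)
    ub = np.full(ncol, np.inf)
    col = 0
    if free_v0:
        A[:, 0] = 1.0
        col = 1
    for j in ttr_idx:
        A[:, col] = np.clip(x - knots[j], 0.0, knots[j + 1] - knots[j])
        if signs[j] > 0:
            lb[col], ub[col] = smin, smax
        else:
            lb[col], ub[col] = -smax, -smin
        col += 1
    res = lsq_linear(A, target, bounds=(lb, ub), method="bvls")
    coef = res.x
    base = coef[0] if free_v0 else float(anchor[1])
    slopes_fit = np.zeros(m)
    slopes_fit[ttr_idx] = coef[int(free_v0):]
    node_v = base + np.concatenate([[0.0], np.cumsum(slopes_fit * np.diff(knots))])
    fitted = (A @ coef) + (0.0 if free_v0 else float(anchor[1]))
    return node_v, types, fitted


def dp_segment_window(window: ProbeSignal, candidates: list[CandidateLine] | None,
                      params: FitParameters, noise_sd: float | None = None,
                      signal_range: float | None = None,
                      anchor: tuple[float, float] | None = None,
                      refit_values: np.ndarray | None = None) -> SegmentationResult:
    """Fit one window: DP line assignment + constrained continuous refit.

    Minimizes sum of squared residuals plus ``breakpoint_penalty`` per
    breakpoint over assignments of probes to candidate lines, with
    breakpoints restricted to consecutive-line intersections.  The
    returned result carries the achieved objective (refit SSE + penalty
    times the number of breakpoints).  ``refit_values`` lets the caller
    detect on filtered values but estimate levels/slopes on raw ones
    (the median prefilter biases values at sharp corners).
    """
    x = window.positions.astype(float)
    y = window.values
    y_fit = y if refit_values is None else np.asarray(refit_values, dtype=float)
    if noise_sd is None:
        noise_sd = params.noise_sd if params.noise_sd is not None else estimate_noise_mad(y)
    rng_ = signal_range if signal_range is not None else (
        params.signal_range if params.signal_range is not None else _robust_range(y))
    sd = max(noise_sd, 5e-3 * rng_)
    smin, smax = slope_bounds(params, rng_)
    if candidates is None or not candidates:
        candidates = hough_lines(window, params, noise_sd=noise_sd, signal_range=rng_)
        candidates = candidates + _transition_candidates(x, y, smin, smax)
    penalty = params.breakpoint_penalty if params.breakpoint_penalty is not None \
        else params.penalty_multiplier * sd * sd * np.log(max(len(x), 2))

    runs, _ = _dp_assign(x, y, candidates, penalty, anchor=anchor,
                         max_bp=params.max_breakpoints_per_window)
    knots, types, signs = _knots_from_runs(x, runs, candidates, anchor=anchor)
    init_s = np.array([candidates[r[0]].slope for r in runs])
    init_b = np.array([candidates[r[0]].intercept - candidates[r[0]].slope * x[0]
                       for r in runs])
    knots = _polish_knots(x, y_fit, knots, types, signs, smin, smax, init_s, init_b)
    node_v, types, fitted = _refit_knots(x, y_fit, knots, types, signs, smin, smax,
                                         anchor=anchor)
    knots, node_v, types = _merge_segments(knots, node_v, types)
    fitted = np.interp(x, knots, node_v)
    sse = float(np.sum((y_fit - fitted) ** 2))
    obj = sse + penalty * (len(types) - 1)
    m = len(types)
    return SegmentationResult(
        chromosome=window.chromosome,
        seg_start_x=knots[:-1].copy(), seg_end_x=knots[1:].copy(),
        seg_start_v=node_v[:-1].copy(), seg_end_v=node_v[1:].copy(),
        seg_type=np.asarray(types, dtype="<U3"), seg_block=np.zeros(m, dtype=np.int64),
        positions=window.positions.copy(), fitted=fitted, objective=obj,
    )


def _merge_segments(knots, node_v, types):
    """Merge adjacent segments that collapsed to one line after refit."""
    keep_t, keep_k, keep_v = [types[0]], [knots[0], knots[1]], [node_v[0], node_v[1]]
    for j in range(1, len(types)):
        dx = knots[j + 1] - knots[j]
        slope_j = (node_v[j + 1] - node_v[j]) / dx if dx > 0 else 0.0
        dx_p = keep_k[-1] - keep_k[-2]
        slope_p = (keep_v[-1] - keep_v[-2]) / dx_p if dx_p > 0 else 0.0
        same = types[j] == keep_t[-1] and (
            types[j] == CTR or abs(slope_j - slope_p) <= 1e-12 * max(abs(slope_p), 1e-30))
        if same:
            keep_k[-1] = knots[j + 1]
            keep_v[-1] = node_v[j + 1]
        else:
            keep_t.append(types[j])
            keep_k.append(knots[j + 1])
            keep_v.append(node_v[j + 1])
    return (np.asarray(keep_k), np.asarray(keep_v), np.asarray(keep_t, dtype="<U3"))


def _segment_block(x, y, y_raw, chromosome, params, noise_sd, signal_range):
    """Windowed segmentation of one contiguous probe block."""
    n = len(x)
    W = params.window_size
    seg_sx, seg_ex, seg_sv, seg_ev, seg_t = [], [], [], [], []

    def commit(knots, node_v, types, upto):
        for j in range(upto):
            seg_sx.append(knots[j]); seg_ex.append(knots[j + 1])
            seg_sv.append(node_v[j]); seg_ev.append(node_v[j + 1])
            seg_t.append(types[j])

    idx = 0
    anchor = None
    min_tail = max(16, W // 10)
    while idx < n:
        end = idx + W
        if end >= n - min_tail:
            end = n
        win = ProbeSignal(chromosome, x[idx:end].astype(np.int64), y[idx:end])
        fit = dp_segment_window(win, None, params, noise_sd=noise_sd,
                                signal_range=signal_range, anchor=anchor,
                                refit_values=y_raw[idx:end])
        knots = np.concatenate([fit.seg_start_x, fit.seg_end_x[-1:]])
        node_v = np.concatenate([fit.seg_start_v, fit.seg_end_v[-1:]])
        types = fit.seg_type
        m = len(types)
        if end == n or m == 1:
            commit(knots, node_v, types, m)
            anchor = (knots[-1], node_v[-1])
            idx = end
        else:
            # breakpoints in the window's tail are poorly estimated (the
            # data that localizes them is truncated) and the restart
            # anchor locks their value, so only commit up to the last
            # knot that clears a tail buffer
            buffer = max(8, W // 15)
            cutoff = x[end - 1 - buffer] if end - 1 - buffer >= idx else x[idx]
            good = [j for j in range(1, m) if knots[j] <= cutoff]
            upto = good[-1] if good else m - 1
            commit(knots, node_v, types, upto)
            anchor = (knots[upto], node_v[upto])
            nxt = int(np.searchsorted(x, knots[upto], side="right"))
            idx = max(nxt, idx + 1)

    # merge segments that continue one line across a window junction,
    # so stitching never manufactures a breakpoint
    nodes = np.append(np.asarray(seg_sx), seg_ex[-1])
    vals = np.append(np.asarray(seg_sv), seg_ev[-1])
    knots2, node_v2, types2 = _merge_segments(nodes, vals, np.asarray(seg_t, dtype="<U3"))

    # whole-block refinement: the committed map inherited values locked
    # by the window-restart anchors; with the architecture fixed, a final
    # polish + unanchored constrained refit over all probes is the
    # maximum-likelihood continuous fit
    dk = np.diff(knots2)
    slopes = np.where(dk > 0, np.diff(node_v2) / np.where(dk > 0, dk, 1.0), 0.0)
    signs = np.sign(slopes)
    smin, smax = slope_bounds(params, signal_range)
    intercepts = node_v2[:-1] - slopes * knots2[:-1]
    knots2 = _polish_knots(x, y_raw, knots2, types2, signs, smin, smax,
                           slopes, intercepts)
    node_v2, types2, _ = _refit_knots(x, y_raw, knots2, types2, signs, smin, smax)
    knots2, node_v2, types2 = _merge_segments(knots2, node_v2, types2)
    return (list(knots2[:-1]), list(knots2[1:]), list(node_v2[:-1]),
            list(node_v2[1:]), list(types2))


def segment_signal(signal: ProbeSignal, params: FitParameters | None = None) -> SegmentationResult:
    """Segment a whole chromosome into a continuous CTR/TTR map.

    Probe gaps larger than ``gap_factor`` times the median spacing split
    the chromosome into independently segmented blocks (no fitting
    across centromeres or unprobed regions).
    """
    params = params or FitParameters()
    if len(signal) < 8:
        raise ValueError(f"chromosome {signal.chromosome} has <8 probes")
    raw = signal
    noise_raw = params.noise_sd if params.noise_sd is not None \
        else estimate_noise_mad(raw.values)
    filt = prefilter(raw, params)
    noise_eff = noise_raw * (_MEDIAN3_SD_FACTOR if params.prefilter_median else 1.0)
    sig_range = params.signal_range if params.signal_range is not None \
        else _robust_range(filt.values)
    logger.info("chromosome %s: noise sd %.4f (effective %.4f), range %.3f",
                signal.chromosome, noise_raw, noise_eff, sig_range)

    x_all = filt.positions.astype(float)
    y_all = filt.values
    y_raw_all = raw.values
    spacing = np.diff(x_all)
    med = np.median(spacing)
    cuts = np.flatnonzero(spacing > params.gap_factor * med) + 1
    blocks = np.split(np.arange(len(x_all)), cuts)

    seg_sx, seg_ex, seg_sv, seg_ev, seg_t, seg_b = [], [], [], [], [], []
    for bi, blk in enumerate(blocks):
        x, y = x_all[blk], y_all[blk]
        y_raw = y_raw_all[blk]
        if len(blk) < 8:
            # too short to model: one flat segment at the block mean
            logger.warning("block of %d probes on %s too short; flat fit", len(blk),
                           signal.chromosome)
            seg_sx.append(x[0]); seg_ex.append(x[-1])
            mv = float(np.mean(y_raw)); seg_sv.append(mv); seg_ev.append(mv)
            seg_t.append(CTR); seg_b.append(bi)
            continue
        sx, ex, sv, ev, tt = _segment_block(x, y, y_raw, signal.chromosome, params,
                                            noise_eff, sig_range)
        seg_sx += sx; seg_ex += ex; seg_sv += sv; seg_ev += ev; seg_t += tt
        seg_b += [bi] * len(tt)

    result = SegmentationResult(
        chromosome=signal.chromosome,
        seg_start_x=np.asarray(seg_sx), seg_end_x=np.asarray(seg_ex),
        seg_start_v=np.asarray(seg_sv), seg_end_v=np.asarray(seg_ev),
        seg_type=np.asarray(seg_t, dtype="<U3"), seg_block=np.asarray(seg_b, dtype=np.int64),
        positions=raw.positions.copy(), fitted=np.empty(len(raw)),
    )
    result.fitted = result.value_at(raw.positions)
    logger.info("chromosome %s: %d segments (%d CTR / %d TTR)", signal.chromosome,
                result.n_segments, int(np.sum(result.seg_type == CTR)),
                int(np.sum(result.seg_type == TTR)))
    return result


def segment_all(signals: dict[str, ProbeSignal],
                params: FitParameters | None = None) -> dict[str, SegmentationResult]:
    """Segment every chromosome; chromosomes with <8 probes are skipped."""
    out = {}
    for chrom, sig in signals.items():
        if len(sig) < 8:
            logger.warning("chromosome %s has <8 probes; skipped", chrom)
            continue
        out[chrom] = segment_signal(sig, params)
    return out
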