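import numpy as np
import pytest
from scipy.optimize import lsq_linear

from arto import (FitParameters, ProbeSignal, SimulationSpec, add_gaussian_noise,
                  dp_segment_window, estimate_noise_mad, hough_lines, prefilter,
                  segment_signal, simulate_clean_signal, slope_bounds)
from tests.conftest import make_v_signal


class TestSlopeBounds:
    def test_fastest_fork_gives_shallowest_slope(self):
        params = FitParameters()
        smin, smax = slope_bounds(params, 1.0)
        assert smin == pytest.approx(1 / (4 * 1000 * 480))
        assert smax == pytest.approx(16 * smin)

    def test_doubling_s_phase_halves_bounds(self):
        a = slope_bounds(FitParameters(s_phase_minutes=480), 1.0)
        b = slope_bounds(FitParameters(s_phase_minutes=960), 1.0)
        assert b[0] == pytest.approx(a[0] / 2)
        assert b[1] == pytest.approx(a[1] / 2)


class TestNoiseEstimate:
    def test_constant_series_has_zero_noise(self):
        assert estimate_noise_mad(np.full(100, 1.3)) == 0.0

    def test_pure_gaussian_noise_recovered(self):
        rng = np.random.default_rng(0)
        sigma = 0.12
        est = estimate_noise_mad(rng.normal(0, sigma, 10_000))
        assert abs(est - sigma) / sigma < 0.05

    def test_piecewise_linear_trend_does_not_bias(self, default_spec):
        clean, _ = simulate_clean_signal(default_spec, seed=9)
        sigma = 0.15 * clean.value_range
        noisy = add_gaussian_noise(clean, 0.15, seed=10)
        est = estimate_noise_mad(noisy.values)
        assert abs(est - sigma) / sigma < 0.10

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_mad([1.0] * 7)


class TestPrefilter:
    def test_disabled_is_identity(self, flat_signal):
        out = prefilter(flat_signal, FitParameters(prefilter_median=False))
        assert out is flat_signal

    def test_spike_replaced_by_neighbors(self):
        sig = ProbeSignal("c", [1, 2, 3, 4, 5], [1.0, 1.0, 11.0, 1.0, 1.0])
        out = prefilter(sig, FitParameters())
        np.testing.assert_allclose(out.values, [1.0, 1.0, 1.0, 1.0, 1.0])

    def test_monotone_series_unchanged(self):
        vals = np.linspace(1.0, 2.0, 9)
        sig = ProbeSignal("c", np.arange(1, 10), vals)
        out = prefilter(sig, FitParameters())
        np.testing.assert_allclose(out.values, vals)


class TestHoughLines:
    params = FitParameters(signal_range=1.0, noise_sd=0.01)

    def test_flat_line_tops_accumulator(self):
        pos = 40_000 * np.arange(1, 21)
        win = ProbeSignal("c", pos, np.full(20, 1.5))
        cands = hough_lines(win, self.params)
        assert cands[0].slope == 0.0
        assert cands[0].votes == 20
        assert cands[0].intercept == pytest.approx(1.5, abs=1e-9)

    def test_flat_and_sloped_lines_both_recovered(self):
        slope = 1.0e-6
        pos = 40_000 * np.arange(1, 21)
        vals = np.concatenate([np.full(10, 1.8),
                               1.8 - slope * 40_000 * np.arange(1, 11)])
        win = ProbeSignal("c", pos, vals)
        cands = hough_lines(win, self.params)
        flat = [c for c in cands if c.slope == 0 and abs(c.intercept - 1.8) < 0.02]
        assert flat and flat[0].votes >= 9
        sloped = [c for c in cands
                  if c.slope < 0 and abs(abs(c.slope) - slope) / slope < 0.15]
        assert sloped and max(c.votes for c in sloped) >= 9

    def test_inadmissibly_steep_line_not_captured(self):
        smin, smax = slope_bounds(self.params, 1.0)
        steep = 2 * smax
        pos = 40_000 * np.arange(1, 41)
        vals = 3.0 - steep * (pos - pos[0])
        win = ProbeSignal("c", pos, vals)
        cands = hough_lines(win, self.params)
        band = 0.75 * 0.01 + 0.05   # vote band + grid-mismatch allowance, generous
        for c in cands:
            assert c.slope == 0 or abs(c.slope) <= smax * (1 + 1e-9)
            pred = c.intercept + c.slope * (pos - pos[0])
            assert np.sum(np.abs(pred - vals) <= band) < len(pos) / 2


def _exhaustive_best(x, y, penalty, smin, smax, max_segments=3):
    """Brute-force penalized piecewise-linear fit (independent oracle).

    Knots at probe-gap midpoints; per-segment type in {flat, rising,
    falling}; continuous fit via a value-at-origin + bounded-slope
    parametrization solved with bounded least squares.
    """
    n = len(x)

    def fit(splits, types):
        knots = np.concatenate([[x[0]],
                                [(x[g - 1] + x[g]) / 2 for g in splits],
                                [x[-1]]])
        cols, lb, ub = [np.ones(n)], [-np.inf], [np.inf]
        for j, t in enumerate(types):
            if t == 0:
                continue
            cols.append(np.clip(x - knots[j], 0, knots[j + 1] - knots[j]))
            lb.append(smin if t > 0 else -smax)
            ub.append(smax if t > 0 else -smin)
        A = np.column_stack(cols)
        res = lsq_linear(A, y, bounds=(np.array(lb), np.array(ub)), method="bvls")
        return float(np.sum((A @ res.x - y) ** 2))

    best = np.inf
    type_opts = (0, 1, -1)
    for t in type_opts:
        best = min(best, fit([], [t]))
    for g in range(1, n):
        for t1 in type_opts:
            for t2 in type_opts:
                if t1 == t2 == 0:
                    continue
                best = min(best, fit([g], [t1, t2]) + penalty)
    if max_segments >= 3:
        for g1 in range(1, n - 1):
            for g2 in range(g1 + 1, n):
                for t1 in type_opts:
                    for t2 in type_opts:
                        for t3 in type_opts:
                            if t1 == t2 == 0 or t2 == t3 == 0:
                                continue
                            best = min(best, fit([g1, g2], [t1, t2, t3]) + 2 * penalty)
    return best


class TestDpSegmentWindow:
    def test_constant_window_is_single_ctr(self, flat_signal):
        params = FitParameters(signal_range=1.0, noise_sd=0.01)
        fit = dp_segment_window(flat_signal, None, params)
        assert fit.n_segments == 1
        assert fit.seg_type[0] == "CTR"
        np.testing.assert_allclose(fit.fitted, flat_signal.values, atol=1e-9)

    def test_noiseless_v_shape_recovered(self):
        sig = make_v_signal(n_left=20, n_mid=20, n_right=20, slope=2.0e-6)
        params = FitParameters(signal_range=1.0, noise_sd=0.0)
        fit = dp_segment_window(sig, None, params)
        assert list(fit.seg_type) == ["CTR", "TTR", "CTR"]
        # breakpoints within one probe of the true junctions
        assert abs(fit.seg_end_x[0] - sig.positions[19]) <= 40_000
        assert abs(fit.seg_end_x[1] - sig.positions[39]) <= 40_000
        assert np.abs(fit.fitted - sig.values).max() < 1e-6

    def test_infinite_penalty_forces_single_segment(self, v_signal):
        params = FitParameters(signal_range=1.0, noise_sd=0.0,
                               breakpoint_penalty=1e9)
        fit = dp_segment_window(v_signal, None, params)
        assert fit.n_segments == 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_objective_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sig = make_v_signal(n_left=14, n_mid=12, n_right=14, slope=1.5e-6, level=1.7)
        noise = rng.normal(0, 0.05, len(sig))
        noisy = ProbeSignal(sig.chromosome, sig.positions, sig.values + noise)
        penalty = 0.05
        params = FitParameters(signal_range=1.0, noise_sd=0.05,
                               breakpoint_penalty=penalty)
        fit = dp_segment_window(noisy, None, params)
        smin, smax = slope_bounds(params, 1.0)
        oracle = _exhaustive_best(noisy.positions.astype(float), noisy.values,
                                  penalty, smin, smax)
        assert fit.objective <= 1.05 * oracle


class TestSegmentSignal:
    def test_noiseless_recovery_is_exact(self, clean_signal):
        clean, truth = clean_signal
        res = segment_signal(clean)
        rng = np.ptp(truth.clean_values)
        rmse = np.sqrt(np.mean((res.fitted - truth.clean_values) ** 2)) / rng
        assert rmse < 1e-3

    def test_deterministic(self, noisy_signal):
        noisy, _ = noisy_signal
        a = segment_signal(noisy)
        b = segment_signal(noisy)
        np.testing.assert_array_equal(a.fitted, b.fitted)
        np.testing.assert_array_equal(a.seg_start_x, b.seg_start_x)

    def test_continuity_at_interior_breakpoints(self, noisy_signal):
        noisy, _ = noisy_signal
        res = segment_signal(noisy)
        for i in range(res.n_segments - 1):
            if res.seg_block[i] == res.seg_block[i + 1]:
                assert res.seg_end_x[i] == res.seg_start_x[i + 1]
                assert res.seg_end_v[i] == res.seg_start_v[i + 1]

    def test_slope_admissibility(self, noisy_signal):
        noisy, _ = noisy_signal
        params = FitParameters()
        res = segment_signal(noisy, params)
        # bounds as derived by the tool itself from its range estimate
        from arto.segmentation import _robust_range
        filt = prefilter(noisy, params)
        smin, smax = slope_bounds(params, _robust_range(filt.values))
        slopes = res.segment_slopes
        for s, t in zip(slopes, res.seg_type):
            if t == "CTR":
                assert s == 0.0
            else:
                assert smin * (1 - 1e-9) <= abs(s) <= smax * (1 + 1e-9)

    def test_fitted_values_within_raw_range_plus_noise(self, noisy_signal):
        noisy, _ = noisy_signal
        res = segment_signal(noisy)
        sigma = estimate_noise_mad(noisy.values)
        assert res.fitted.min() >= noisy.values.min() - 3 * sigma
        assert res.fitted.max() <= noisy.values.max() + 3 * sigma

    def test_too_few_probes_rejected(self):
        sig = ProbeSignal("c", np.arange(1, 6), np.ones(5))
        with pytest.raises(ValueError):
            segment_signal(sig)

    def test_large_gap_splits_blocks(self):
        pos = np.concatenate([40_000 * np.arange(1, 31),
                              40_000 * np.arange(200, 230)])
        vals = np.concatenate([np.full(30, 1.2), np.full(30, 1.8)])
        res = segment_signal(ProbeSignal("c", pos, vals))
        assert len(np.unique(res.seg_block)) == 2
        # no segment bridges the gap
        gap_lo, gap_hi = 40_000 * 30, 40_000 * 200
        for a, b in zip(res.seg_start_x, res.seg_end_x):
            assert not (a < gap_lo < gap_hi <= b)
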