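import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arto import (GenomicRegion, compare_activity_types, compare_tor_maps,
                  ctr_residence_enrichment, distance_to_regions, filter_intergenic,
                  paired_difference_test, select_matched_pairs, window_feature_density)
from tests.test_annotate import make_result

MB = 1_000_000


def annot_frame(n=500, seed=0, activity=None):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "chromosome": "chr1",
        "position": 40_000 * np.arange(1, n + 1),
        "fitted_tor": rng.uniform(1.0, 2.0, n),
        "activity": activity if activity is not None else
            rng.choice(["CTR", "TTR"], n),
    })


class TestCompareTorMaps:
    def test_self_comparison_is_one_and_symmetric(self):
        a = annot_frame()
        assert compare_tor_maps(a, a) == 1.0
        b = annot_frame(seed=1)
        assert compare_tor_maps(a, b) == compare_tor_maps(b, a)

    def test_offset_above_threshold_gives_zero(self):
        a = annot_frame()
        rng = a["fitted_tor"].max() - a["fitted_tor"].min()
        b = a.assign(fitted_tor=a["fitted_tor"] + 0.31 * rng)
        assert compare_tor_maps(a, b) == 0.0

    def test_constructed_partial_shift(self):
        a = annot_frame(n=1000)
        rng = a["fitted_tor"].max() - a["fitted_tor"].min()
        b = a.copy()
        b.loc[:199, "fitted_tor"] += 0.5 * rng   # exactly 20% of probes
        assert compare_tor_maps(a, b) == pytest.approx(0.80, abs=0.02)

    def test_too_few_shared_probes_rejected(self):
        a = annot_frame(n=50)
        with pytest.raises(ValueError):
            compare_tor_maps(a, a)


class TestCompareActivityTypes:
    def test_identical_maps_agree_fully(self):
        a = annot_frame()
        assert compare_activity_types(a, a) == 1.0

    def test_opposite_maps_agree_never(self):
        a = annot_frame(activity=np.repeat("CTR", 500))
        b = a.assign(activity="TTR")
        assert compare_activity_types(a, b) == 0.0

    def test_constructed_discordance(self):
        a = annot_frame(activity=np.repeat("CTR", 500))
        act = np.repeat("CTR", 500).astype(object)
        act[:50] = "TTR"
        b = a.assign(activity=act)
        assert compare_activity_types(a, b) == pytest.approx(0.90)

    def test_undefined_probes_excluded(self):
        a = annot_frame(activity=np.repeat("CTR", 500))
        act = np.repeat("CTR", 500).astype(object)
        act[:250] = "undefined"
        b = a.assign(activity=act)
        assert compare_activity_types(a, b) == 1.0


class TestSelectMatchedPairs:
    def test_identical_pools_match_exactly(self):
        tor = np.linspace(1.0, 2.0, 200)
        pairs = select_matched_pairs(tor, tor.copy(), n_pairs=100, seed=0)
        assert len(pairs) > 0
        np.testing.assert_allclose(pairs.ctr_tor, pairs.ttr_tor)

    def test_within_pair_tolerance_respected(self):
        rng = np.random.default_rng(1)
        pairs = select_matched_pairs(rng.uniform(1, 2, 2000), rng.uniform(1, 2, 2000),
                                     n_pairs=600, seed=2)
        assert np.all(np.abs(pairs.ctr_tor - pairs.ttr_tor) <= pairs.tor_tolerance)

    def test_reproducible_and_no_probe_reuse(self):
        rng = np.random.default_rng(3)
        c, t = rng.uniform(1, 2, 2000), rng.uniform(1, 2, 2000)
        a = select_matched_pairs(c, t, n_pairs=500, seed=4)
        b = select_matched_pairs(c, t, n_pairs=500, seed=4)
        np.testing.assert_array_equal(a.ctr_index, b.ctr_index)
        assert len(np.unique(a.ctr_index)) == len(a)
        assert len(np.unique(a.ttr_index)) == len(a)

    def test_pair_tor_distributions_match(self):
        rng = np.random.default_rng(5)
        # pools with very different ToR distributions
        c = rng.beta(2, 5, 20_000) + 1.0
        t = rng.beta(5, 2, 20_000) + 1.0
        pairs = select_matched_pairs(c, t, n_pairs=1000, seed=6)
        assert len(pairs) >= 600   # the working regime: 600-1000 pairs
        ks = stats.ks_2samp(pairs.ctr_tor, pairs.ttr_tor).statistic
        assert ks < 0.1

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_matched_pairs([], [1.0], n_pairs=10, seed=0)


class TestFilterIntergenic:
    genes = [GenomicRegion("chr1", 1_000_000, 1_100_000)]

    def probes(self, positions):
        return pd.DataFrame({"chromosome": "chr1", "position": positions})

    def test_no_genes_is_identity(self):
        p = self.probes([100, 200])
        out = filter_intergenic(p, [])
        pd.testing.assert_frame_equal(out, p)

    def test_twenty_kb_rule(self):
        p = self.probes([1_119_000, 1_121_000])   # 19 kb and 21 kb past the end
        out = filter_intergenic(p, self.genes)
        assert list(out["position"]) == [1_121_000]

    def test_probe_inside_gene_removed(self):
        p = self.probes([1_050_000, 2_000_000])
        out = filter_intergenic(p, self.genes)
        assert list(out["position"]) == [2_000_000]

    def test_distance_metric(self):
        d = distance_to_regions([980_000, 1_050_000, 1_120_000], self.genes)
        assert d[0] == 20_000
        assert d[1] == 0
        assert d[2] == pytest.approx(20_001)


class TestWindowFeatureDensity:
    def test_no_features_gives_zeros(self):
        out = window_feature_density([], [100, 200], 30_000)
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_feature_at_probe_position_counted(self):
        probes = [100_000, 200_000]
        out = window_feature_density(probes, probes, 1)
        np.testing.assert_array_equal(out, [1.0, 1.0])

    def test_hand_placed_features(self):
        probe = [1_000_000]
        feats = [984_000, 990_000, 1_000_000, 1_014_000, 1_016_000]
        out = window_feature_density(feats, probe, 30_000)
        assert out[0] == 3.0   # two features fall outside +/-15 kb

    def test_disjoint_windows_sum_to_total(self):
        rng = np.random.default_rng(0)
        feats = np.sort(rng.integers(0, 1_000_000, 500))
        centers = np.arange(5_000, 1_000_000, 10_000)   # tiles [0, 1 Mb)
        counts = window_feature_density(feats, centers, 9_999.98)
        assert counts.sum() == len(feats)

    def test_weighted_mode_returns_mean_and_nan(self):
        out = window_feature_density([100, 200], [150, 10_000], 200,
                                     weights=[1.0, 3.0])
        assert out[0] == pytest.approx(2.0)
        assert np.isnan(out[1])


@pytest.fixture()
def enrichment_map():
    # alternating CTR/TTR with distinct ToR strata
    seg_x = [40_000, 3 * MB, 5 * MB, 8 * MB, 10 * MB, 13 * MB]
    seg_v = [1.8, 1.8, 1.2, 1.2, 1.8, 1.8]
    types = ["CTR", "TTR", "CTR", "TTR", "CTR"]
    return make_result(seg_x, seg_v, types)


class TestCtrResidenceEnrichment:
    def test_regions_planted_in_ctrs(self, enrichment_map):
        regions = [GenomicRegion("chrA", s, s + 50_000)
                   for s in (1_000_000, 1_500_000, 2_000_000, 5_800_000,
                             6_200_000, 11_000_000, 11_500_000, 12_000_000)]
        enr = ctr_residence_enrichment(regions, enrichment_map, n_random=50,
                                       seed=0, keep_null_regions=True)
        assert enr.observed_pct == 100.0
        assert 0 < enr.p_value <= 1
        assert len(enr.null_pcts) == 50

    def test_null_sets_preserve_length_and_chromosome(self, enrichment_map):
        regions = [GenomicRegion("chrA", 1_000_000, 1_070_000),
                   GenomicRegion("chrA", 6_000_000, 6_030_000)]
        enr = ctr_residence_enrichment(regions, enrichment_map, n_random=20,
                                       seed=1, keep_null_regions=True)
        for null_set in enr.null_regions:
            assert [len(r) for r in null_set] == [70_000, 30_000]
            assert all(r.chromosome == "chrA" for r in null_set)

    def test_p_value_uses_plus_one_correction(self, enrichment_map):
        regions = [GenomicRegion("chrA", 1_000_000, 1_050_000)]
        enr = ctr_residence_enrichment(regions, enrichment_map, n_random=10, seed=2)
        assert enr.p_value >= 1 / 11


class TestPairedDifferenceTest:
    def test_identical_values_give_null_result(self):
        v = np.arange(20.0)
        mean, t, p = paired_difference_test(v, v)
        assert (mean, t, p) == (0.0, 0.0, 1.0)

    def test_constant_shift_is_degenerate(self):
        v = np.arange(100.0)
        mean, t, p = paired_difference_test(v, v + 1.0)
        assert mean == 1.0
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_small_shift_detected_with_high_power(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 1000)
        shifted = base + 0.5 + rng.normal(0, 0.5, 1000)
        _, t, p = paired_difference_test(base, shifted)
        assert p < 1e-6 and t > 0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_difference_test(np.ones(5), np.ones(5))

    def test_nan_pairs_dropped(self):
        v = np.arange(30.0)
        w = v + 1.0
        w[0] = np.nan
        mean, t, p = paired_difference_test(v, w)
        assert mean == 1.0
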