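import itertools

import numpy as np
import pytest

from stmvpa import stats
from stmvpa.containers import ParameterError, ValidationError


class TestSignPermutation:
    def test_all_zero_effects_give_p_one(self):
        res = stats.sign_permutation_test(np.zeros((6, 4)), n_perm=200,
                                          seed=0)
        np.testing.assert_allclose(res.p_values, 1.0)

    def test_minimum_p_is_one_over_n_perm(self):
        eff = np.full(8, 3.0) + np.random.default_rng(0).normal(0, 0.1, 8)
        res = stats.sign_permutation_test(eff, n_perm=256, tail="one")
        assert res.p_values[0] == pytest.approx(1.0 / 256)

    def test_two_sided_detects_negative_effects(self):
        eff = -np.abs(np.random.default_rng(1).normal(2, 0.2, 10))
        one = stats.sign_permutation_test(eff, n_perm=1024, tail="one")
        two = stats.sign_permutation_test(eff, n_perm=1024, tail="two")
        assert two.p_values[0] < 0.01 < one.p_values[0]

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            eff = rng.normal(0.4, 1.0, 5)
            res = stats.sign_permutation_test(eff, n_perm=32, tail="one")
            obs = np.mean(eff)
            null = [np.mean(np.array(s) * eff)
                    for s in itertools.product([1, -1], repeat=5)]
            assert res.exhaustive
            assert res.p_values[0] == pytest.approx(
                np.mean([v >= obs for v in null]))

    def test_invalid_args_rejected(self):
        with pytest.raises(ParameterError):
            stats.sign_permutation_test(np.ones((4, 2)), n_perm=0)
        with pytest.raises(ParameterError):
            stats.sign_permutation_test(np.ones((1, 2)), n_perm=10)


class TestFdr:
    def test_hand_step_up_case(self):
        mask = stats.fdr_bh(np.array([0.001, 0.02, 0.9]), q=0.05)
        np.testing.assert_array_equal(mask, [True, True, False])

    def test_all_ones_rejects_nothing(self):
        assert not stats.fdr_bh(np.ones(10)).any()

    @pytest.mark.parametrize("p,expect", [(0.04, True), (0.06, False)])
    def test_single_p(self, p, expect):
        assert stats.fdr_bh(np.array([p]), q=0.05)[0] == expect

    def test_mask_monotone_in_q(self):
        p = np.random.default_rng(3).uniform(0, 0.2, 30)
        small = stats.fdr_bh(p, q=0.01)
        large = stats.fdr_bh(p, q=0.10)
        assert np.all(large[small])

    def test_superset_of_bonferroni(self):
        p = np.random.default_rng(4).uniform(0, 0.1, 50)
        fdr = stats.fdr_bh(p, q=0.05)
        bonf = p <= 0.05 / p.size
        assert np.all(fdr[bonf])


class TestClusterPermutation:
    def test_recovers_planted_temporal_cluster(self):
        rng = np.random.default_rng(0)
        eff = rng.standard_normal((10, 40)) * 0.3
        eff[:, 10:20] += 2.0
        res = stats.cluster_permutation(eff, n_perm=1024, seed=1)
        sig = [c for c, s in zip(res.clusters, res.significant) if s]
        assert len(sig) == 1
        assert set(range(10, 20)) <= set(sig[0].tolist())

    def test_empty_suprathreshold_returns_empty_result(self):
        eff = np.random.default_rng(2).standard_normal((8, 20)) * 0.1
        res = stats.cluster_permutation(eff, forming_p=1e-6, n_perm=256,
                                        seed=0)
        assert res.clusters == []
        assert res.significant.size == 0

    def test_cross_test_threshold_dominates_single_tests(self):
        rng = np.random.default_rng(5)
        effs = [rng.standard_normal((8, 30)) for _ in range(3)]
        joint = stats.cluster_permutation(effs, cross_test_max=True,
                                          forming_p=0.05, n_perm=256, seed=9)
        for i, eff in enumerate(effs):
            single = stats.cluster_permutation(eff, forming_p=0.05,
                                               n_perm=256, seed=9)
            assert np.quantile(joint[i].null_max_sizes, 0.95) >= \
                np.quantile(single.null_max_sizes, 0.95)

    def test_tgm_adjacency_uses_4_connectivity(self):
        rng = np.random.default_rng(6)
        eff = rng.standard_normal((8, 36)) * 0.2
        # two blobs touching only diagonally must stay separate clusters
        grid = np.zeros((6, 6))
        grid[1:3, 1:3] = 3.0
        grid[3:5, 3:5] = 3.0
        eff += grid.ravel()
        res = stats.cluster_permutation(eff, adjacency="tgm", shape=(6, 6),
                                        forming_p=0.01, n_perm=256, seed=0)
        sizes = sorted(len(c) for c in res.clusters)
        # the two blobs touch only diagonally: they must not merge
        assert max(sizes) == 4
        assert sizes.count(4) == 2


class TestConjunction:
    def test_identical_and_disjoint_masks(self):
        m = np.array([True, False, True])
        np.testing.assert_array_equal(stats.conjunction_mask([m, m]), m)
        assert not stats.conjunction_mask([m, ~m]).any()

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        masks = [rng.random(25) > 0.5 for _ in range(3)]
        expect = masks[0] & masks[1] & masks[2]
        np.testing.assert_array_equal(stats.conjunction_mask(masks), expect)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            stats.conjunction_mask([np.ones(3, bool), np.ones(4, bool)])


class TestBootstrapPeak:
    times = np.arange(-100, 401, 10.0)

    def test_identical_noiseless_curves_zero_width_ci(self):
        curve = np.exp(-(self.times - 120) ** 2 / (2 * 40.0 ** 2))
        tc = np.tile(curve, (6, 1))
        res = stats.bootstrap_peak(tc, self.times, n_boot=500, seed=0)
        assert res.peak_latency == 120.0
        assert res.ci_low == res.ci_high == 120.0

    def test_window_restriction_changes_detected_peak(self):
        curve = np.exp(-(self.times - 300) ** 2 / (2 * 30.0 ** 2)) \
            + 0.5 * np.exp(-(self.times - 100) ** 2 / (2 * 30.0 ** 2))
        tc = np.tile(curve, (5, 1))
        full = stats.bootstrap_peak(tc, self.times, n_boot=100, seed=0)
        early = stats.bootstrap_peak(tc, self.times, n_boot=100,
                                     window=(-100, 200), seed=0)
        assert full.peak_latency == 300.0
        assert early.peak_latency == 100.0

    def test_difference_of_identical_conditions_not_significant(self):
        rng = np.random.default_rng(2)
        tc = np.exp(-(self.times - 150) ** 2 / (2 * 50.0 ** 2)) \
            + rng.normal(0, 0.05, (8, self.times.size))
        res = stats.bootstrap_peak_difference(tc, tc, self.times,
                                              n_boot=500, seed=1)
        assert res.difference == 0.0
        assert not res.significant

    def test_planted_latency_difference_detected(self):
        rng = np.random.default_rng(3)
        a = np.exp(-(self.times - 100) ** 2 / (2 * 30.0 ** 2)) \
            + rng.normal(0, 0.02, (10, self.times.size))
        b = np.exp(-(self.times - 150) ** 2 / (2 * 30.0 ** 2)) \
            + rng.normal(0, 0.02, (10, self.times.size))
        res = stats.bootstrap_peak_difference(a, b, self.times, n_boot=500,
                                              seed=2)
        assert res.significant
        assert res.ci_high < 0

    def test_difference_antisymmetric_with_shared_seed(self):
        rng = np.random.default_rng(4)
        a = np.exp(-(self.times - 100) ** 2 / (2 * 30.0 ** 2)) \
            + rng.normal(0, 0.1, (8, self.times.size))
        b = np.exp(-(self.times - 180) ** 2 / (2 * 30.0 ** 2)) \
            + rng.normal(0, 0.1, (8, self.times.size))
        ab = stats.bootstrap_peak_difference(a, b, self.times, n_boot=300,
                                             seed=7)
        ba = stats.bootstrap_peak_difference(b, a, self.times, n_boot=300,
                                             seed=7)
        assert ab.ci_low == pytest.approx(-ba.ci_high)
        assert ab.ci_high == pytest.approx(-ba.ci_low)


class TestTost:
    def test_identical_samples_are_equivalent(self):
        a = np.random.default_rng(0).normal(100, 5, 50)
        assert stats.tost_equivalence(a, a, bounds_ms=1.0) < 0.05

    def test_large_difference_not_equivalent(self):
        a = np.full(30, 100.0) + np.random.default_rng(1).normal(0, 1, 30)
        b = a + 50.0
        assert stats.tost_equivalence(a, b, bounds_ms=10.0) > 0.9

    def test_bound_width_decides_equivalence(self):
        rng = np.random.default_rng(2)
        a = rng.normal(100, 2, 40)
        b = a - 5.0 + rng.normal(0, 0.5, 40)
        assert stats.tost_equivalence(a, b, bounds_ms=10.0) < 0.05
        assert stats.tost_equivalence(a, b, bounds_ms=2.0) > 0.5

    def test_missing_bounds_rejected(self):
        with pytest.raises(ParameterError):
            stats.tost_equivalence(np.ones(5), np.ones(5), bounds_ms=None)

    def test_bootstrap_scale_option(self):
        rng = np.random.default_rng(3)
        a = rng.normal(100, 1, 500)
        b = rng.normal(102, 1, 500)
        assert stats.tost_equivalence(a, b, bounds_ms=10.0,
                                      scale="bootstrap") < 0.05
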