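import numpy as np
import pytest

from stmvpa import decoding, synth
from stmvpa.containers import (BetaSet, EpochSet, ParameterError,
                               ValidationError, default_times)


@pytest.fixture(scope="module")
def sets_small(epochs_small):
    return decoding.make_supertrials(epochs_small.select("photo"),
                                     group_size=2, n_repetitions=2, seed=5)


class TestNoiseNormalize:
    def test_scaled_channel_variances_equalized(self, gt_small, short_times):
        ep = synth.simulate_epochs(gt_small, 20, 6, short_times, seed=1,
                                   depictions=("photo",))
        data = ep.data.copy()
        data[:, 0, :] *= 10.0
        ep = EpochSet(data, ep.category, ep.depiction, ep.times, ep.srate)
        out = decoding.noise_normalize(ep)
        resid = out.data.copy()
        for c in np.unique(out.category):
            m = out.category == c
            resid[m] -= resid[m].mean(axis=0)
        var = resid.transpose(1, 0, 2).reshape(out.n_channels, -1).var(axis=1)
        assert var.max() / var.min() < 2.0

    def test_white_data_nearly_unchanged_and_idempotent(self):
        rng = np.random.default_rng(2)
        times = default_times(0, 180, 50)
        data = rng.standard_normal((120, 5, len(times)))
        ep = EpochSet(data, np.repeat([0, 1, 2], 40),
                      np.array(["photo"] * 120), times, 50.0)
        once = decoding.noise_normalize(ep)
        assert np.abs(once.data - ep.data).mean() < 0.2 * np.abs(ep.data).mean()
        twice = decoding.noise_normalize(once)
        assert np.abs(twice.data - once.data).mean() < \
            0.1 * np.abs(once.data).mean()

    def test_singular_without_shrinkage_raises(self):
        times = default_times(0, 80, 50)
        rng = np.random.default_rng(3)
        base = rng.standard_normal((8, 1, len(times)))
        data = np.repeat(base, 4, axis=1)   # rank-1 channel space
        ep = EpochSet(data, np.repeat([0, 1], 4), np.array(["photo"] * 8),
                      times, 50.0)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            decoding.noise_normalize(ep, shrinkage=0.0)


class TestSupertrials:
    def test_24_trials_give_12_supertrials(self, gt_small, short_times):
        ep = synth.simulate_epochs(gt_small, 24, 6, short_times, seed=4,
                                   depictions=("photo",))
        sets = decoding.make_supertrials(ep, 2, 1, seed=0)
        for c in range(gt_small.n_categories):
            assert np.sum(sets[0].category == c) == 12

    def test_indivisible_trials_rejected(self, gt_small, short_times):
        ep = synth.simulate_epochs(gt_small, 8, 6, short_times, seed=4,
                                   depictions=("photo",))
        with pytest.raises(ParameterError):
            decoding.make_supertrials(ep, 3, 1, seed=0)

    def test_grand_mean_preserved(self, epochs_small):
        photo = epochs_small.select("photo")
        sets = decoding.make_supertrials(photo, 2, 3, seed=1)
        for st in sets:
            np.testing.assert_allclose(st.data.mean(axis=0),
                                       photo.data.mean(axis=0), atol=1e-12)

    def test_averaging_identical_trials_returns_trial(self, short_times):
        one = np.random.default_rng(0).standard_normal((1, 4, len(short_times)))
        data = np.concatenate([np.repeat(one, 4, axis=0)] * 3)
        ep = EpochSet(data, np.repeat([0, 1, 2], 4),
                      np.array(["photo"] * 12), short_times, 25.0)
        sets = decoding.make_supertrials(ep, 2, 1, seed=0)
        np.testing.assert_allclose(sets[0].data[0], one[0], atol=1e-14)

    def test_assignments_differ_across_repetitions(self, epochs_small):
        sets = decoding.make_supertrials(epochs_small.select("photo"), 2, 2,
                                         seed=2)
        assert not np.allclose(sets[0].data, sets[1].data)


class TestTimecourseDecoding:
    def test_noise_free_patterns_decode_perfectly_in_window(self, gt_small,
                                                            short_times):
        ep = synth.simulate_epochs(gt_small, 6, 8, short_times, seed=6,
                                   noise_sd=1e-6, depictions=("photo",))
        sets = decoding.make_supertrials(ep, 2, 1, seed=0)
        tc = decoding.pairwise_decode_timecourse(sets)
        window = gt_small.response_profile(short_times) > 0.5
        assert np.all(tc.values[window] == 100.0)

    def test_accuracy_invariant_to_channel_permutation(self, sets_small):
        tc = decoding.pairwise_decode_timecourse(sets_small)
        perm = np.random.default_rng(7).permutation(sets_small[0].data.shape[1])
        permuted = [decoding.SupertrialSet(s.data[:, perm], s.category,
                                           s.times, s.srate,
                                           s.assignment_repetition)
                    for s in sets_small]
        tcp = decoding.pairwise_decode_timecourse(permuted)
        np.testing.assert_allclose(tcp.values, tc.values, atol=1e-10)

    def test_accuracy_nonincreasing_in_noise(self, gt_small, short_times):
        means = []
        for noise in [0.5, 2.0, 8.0]:
            accs = []
            for seed in range(4):
                ep = synth.simulate_epochs(gt_small, 8, 8, short_times,
                                           seed=100 + seed, noise_sd=noise,
                                           depictions=("photo",))
                sets = decoding.make_supertrials(ep, 2, 1, seed=seed)
                accs.append(decoding.pairwise_decode_timecourse(
                    sets).values.mean())
            means.append(np.mean(accs))
        assert means[0] > means[1] > means[2] - 1.0

    def test_robust_to_svm_regularization(self, sets_small):
        a = decoding.pairwise_decode_timecourse(sets_small, C=1.0)
        b = decoding.pairwise_decode_timecourse(sets_small, C=10.0)
        assert np.abs(a.values - b.values).mean() < 5.0


class TestCrossDecoding:
    def test_identical_inputs_equal_within_decoding(self, sets_small):
        within = decoding.pairwise_decode_timecourse(sets_small)
        cross = decoding.cross_decode_timecourse(sets_small, sets_small)
        np.testing.assert_array_equal(cross.values, within.values)

    def test_symmetric_in_arguments(self, gt_small, short_times):
        ep = synth.simulate_epochs(gt_small, 6, 8, short_times, seed=8,
                                   depictions=("photo", "drawing"))
        sa = decoding.make_supertrials(ep.select("photo"), 2, 1, seed=0)
        sb = decoding.make_supertrials(ep.select("drawing"), 2, 1, seed=0)
        ab = decoding.cross_decode_timecourse(sa, sb)
        ba = decoding.cross_decode_timecourse(sb, sa)
        np.testing.assert_allclose(ab.values, ba.values, atol=1e-12)

    def test_roi_cross_equals_within_for_identical_sets(self, gt_small):
        bs = synth.simulate_betas(gt_small, 3, n_voxels=8, noise_sd=0.5,
                                  seed=1)
        within = decoding.pairwise_decode_roi(bs)
        cross = decoding.cross_decode_roi(bs, bs)
        assert cross == pytest.approx(within)

    def test_label_mismatch_rejected(self, gt_small):
        a = synth.simulate_betas(gt_small, 2, n_voxels=6, seed=1)
        b = synth.simulate_betas(gt_small, 2, n_voxels=6, seed=2)
        b.condition_ids = b.condition_ids + 1
        with pytest.raises(ValidationError):
            decoding.cross_decode_roi(a, b)


class TestTemporalGeneralization:
    def test_diagonal_equals_timecourse(self, sets_small):
        tc = decoding.pairwise_decode_timecourse(sets_small)
        tgm = decoding.temporal_generalization(sets_small)
        np.testing.assert_allclose(np.diag(tgm.values), tc.values,
                                   atol=1e-12)

    def test_sign_reversal_generalizes_below_chance(self):
        times = default_times(0, 280, 25)
        patterns = np.random.default_rng(1).standard_normal((3, 10))
        half = times < 140
        prof_a = np.where(half, 1.0, 0.0)
        prof_b = np.where(~half, 1.0, 0.0)
        ep = synth.simulate_staged_epochs([patterns, -patterns],
                                          [prof_a, prof_b], 8, 12, times,
                                          noise_sd=0.3, seed=2)
        sets = decoding.make_supertrials(ep, 2, 1, seed=0)
        tgm = decoding.temporal_generalization(sets).values
        early, late = np.flatnonzero(half), np.flatnonzero(~half)
        assert tgm[np.ix_(early, late)].mean() < 40.0
        assert tgm[np.ix_(early, early)].mean() > 60.0


class TestRoiDecoding:
    def test_identical_runs_no_noise_is_perfect(self, gt_small):
        bs = synth.simulate_betas(gt_small, 3, n_voxels=8, noise_sd=0.0,
                                  seed=0)
        assert decoding.pairwise_decode_roi(bs) == 100.0

    def test_matches_exhaustive_fold_enumeration(self, gt_small):
        from sklearn.svm import SVC
        bs = synth.simulate_betas(gt_small, 2, n_voxels=2, noise_sd=1.0,
                                  seed=3)
        b = bs.betas[:, :3]     # 3 conditions x 2 runs x 2 voxels toy
        correct = total = 0
        for i in range(3):
            for j in range(i + 1, 3):
                for test_run in range(2):
                    train_run = 1 - test_run
                    clf = SVC(kernel="linear", C=1.0).fit(
                        [b[train_run, i], b[train_run, j]], [0, 1])
                    pred = clf.predict([b[test_run, i], b[test_run, j]])
                    correct += int(pred[0] == 0) + int(pred[1] == 1)
                    total += 2
        expect = 100.0 * correct / total
        coords = np.column_stack([np.arange(2), np.zeros(2, int),
                                  np.zeros(2, int)])
        got = decoding.pairwise_decode_roi(BetaSet(b, coords))
        assert got == pytest.approx(expect, abs=1e-12)

    def test_run_shuffled_labels_at_chance(self, gt_small):
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(100):
            bs = synth.simulate_betas(gt_small, 2, n_voxels=6, noise_sd=6.0,
                                      seed=seed)
            b = bs.betas.copy()
            for r in range(b.shape[0]):      # break label-pattern coupling
                b[r] = b[r, rng.permutation(b.shape[1])]
            accs.append(decoding.pairwise_decode_roi(
                BetaSet(b, bs.voxel_coords)))
        n = 100 * 6 * 2 * 2
        band = 2.576 * np.sqrt(0.25 / n) * 100
        assert abs(np.mean(accs) - 50.0) < 3 * band

    def test_single_run_rejected(self, gt_small):
        with pytest.raises(ParameterError):
            BetaSet(np.zeros((1, 3, 4)),
                    np.column_stack([np.arange(4), np.zeros(4, int),
                                     np.zeros(4, int)]))


class TestSearchlight:
    def test_sphere_radius_four_has_257_voxels(self):
        assert decoding.sphere_offsets(4).shape[0] == 257

    def test_sphere_matches_brute_force_lattice_count(self):
        for radius in [1, 2, 3]:
            count = sum(1 for x in range(-radius, radius + 1)
                        for y in range(-radius, radius + 1)
                        for z in range(-radius, radius + 1)
                        if x * x + y * y + z * z <= radius * radius)
            assert decoding.sphere_offsets(radius).shape[0] == count

    def test_radius_below_one_rejected(self):
        with pytest.raises(ParameterError):
            decoding.sphere_offsets(0.5)

    def test_blob_recovery(self, gt_small):
        bs = synth.simulate_betas(gt_small, 3, grid_shape=(7, 7, 7),
                                  blob_radius=1.5, noise_sd=0.3, seed=4)
        amap = decoding.searchlight_decode(bs, radius_voxels=2,
                                           smoothing_fwhm_mm=5.0)
        best = np.nanargmax(amap.values)
        center = np.array([3, 3, 3])
        assert np.linalg.norm(amap.voxel_coords[best] - center) <= 2.5

    def test_zero_signal_near_chance(self):
        rng = np.random.default_rng(5)
        betas = rng.standard_normal((2, 3, 27))
        coords = np.indices((3, 3, 3)).reshape(3, -1).T
        amap = decoding.searchlight_decode(BetaSet(betas, coords),
                                           radius_voxels=1,
                                           smoothing_fwhm_mm=0)
        assert abs(np.nanmean(amap.values) - 50.0) < 15.0
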