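import numpy as np
import pytest
from scipy import stats

from synapcount._geom import stamp_discs
from synapcount.coloc import (
    DendriteAreaError,
    corrected_density,
    count_colocalizations,
    crosscorr_profile,
    estimate_disc_count,
    noise_by_randomization,
    randomization_null_counts,
    randomize_puncta,
    triple_and,
)
from synapcount.puncta import PunctaSet


from _oracles import flood_count as _flood_count


class TestTripleAnd:
    def test_all_false_annihilates(self, rng):
        m = rng.random((16, 16)) > 0.5
        empty = np.zeros((16, 16), bool)
        assert not triple_and(m, empty, m).any()

    def test_idempotent_on_identical_masks(self, rng):
        m = rng.random((16, 16)) > 0.5
        assert np.array_equal(triple_and(m, m, m), m)

    def test_matches_elementwise_loop_oracle(self, rng):
        a, b, c = (rng.random((12, 12)) > 0.6 for _ in range(3))
        out = triple_and(a, b, c)
        for i in range(12):
            for j in range(12):
                assert out[i, j] == (a[i, j] and b[i, j] and c[i, j])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            triple_and(np.ones((4, 4), bool), np.ones((5, 5), bool), np.ones((4, 4), bool))


class TestCountColocalizations:
    def test_empty_mask_counts_zero(self):
        assert count_colocalizations(np.zeros((16, 16), bool)) == 0

    def test_two_disjoint_discs(self):
        mask = stamp_discs((32, 32), [(8, 8), (24, 24)], 2)
        assert count_colocalizations(mask) == 2
        assert _flood_count(mask) == 2

    def test_discs_sharing_a_pixel_merge(self):
        mask = stamp_discs((32, 32), [(10, 10), (10, 14)], 2)
        assert count_colocalizations(mask) == 1
        assert _flood_count(mask) == 1

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(15):
            mask = rng.random((20, 20)) > 0.7
            assert count_colocalizations(mask) == _flood_count(mask)


class TestRandomizePuncta:
    def test_empty_set_stays_empty(self):
        out = randomize_puncta(PunctaSet(np.empty((0, 2)), 2, (64, 64)), 3)
        assert len(out) == 0

    def test_count_and_radius_conserved_positions_move(self, rng):
        puncta = PunctaSet(rng.integers(0, 64, (100, 2)), 2, (64, 64))
        out = randomize_puncta(puncta, 7)
        assert len(out) == 100
        assert out.radius_px == 2
        assert not np.array_equal(out.centroids, puncta.centroids)

    def test_deterministic_given_seed(self, rng):
        puncta = PunctaSet(rng.integers(0, 64, (50, 2)), 2, (64, 64))
        assert np.array_equal(randomize_puncta(puncta, 9).centroids, randomize_puncta(puncta, 9).centroids)

    def test_positions_uniform_over_image_chi_square(self):
        # 1000 seeds x 10 puncta on a 4x4 spatial grid; complete spatial
        # randomness should not be rejected at alpha = 0.01
        puncta = PunctaSet([(0, 0)] * 10, 2, (64, 64))
        counts = np.zeros(16)
        for seed in range(1000):
            out = randomize_puncta(puncta, seed)
            cells = (out.centroids[:, 0] // 16) * 4 + out.centroids[:, 1] // 16
            np.add.at(counts, cells, 1)
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestNoiseByRandomization:
    def test_empty_pre_set_gives_zero(self, rng):
        pre = PunctaSet(np.empty((0, 2)), 2, (64, 64))
        post = PunctaSet(rng.integers(0, 64, (50, 2)), 2, (64, 64))
        assert noise_by_randomization(pre, post, np.ones((64, 64), bool), 5, 0) == 0.0

    def test_deterministic_given_seed(self, rng):
        pre = PunctaSet(rng.integers(0, 64, (40, 2)), 2, (64, 64))
        post = PunctaSet(rng.integers(0, 64, (40, 2)), 2, (64, 64))
        dend = np.ones((64, 64), bool)
        assert noise_by_randomization(pre, post, dend, 5, 3) == noise_by_randomization(pre, post, dend, 5, 3)

    def test_matches_independent_monte_carlo_oracle(self, rng):
        # full-image dendrite, 200 discs per channel on 256^2: the estimate
        # must agree with a from-scratch simulation within 3 standard errors
        shape = (256, 256)
        pre = PunctaSet(rng.integers(0, 256, (200, 2)), 2, shape)
        post = PunctaSet(rng.integers(0, 256, (200, 2)), 2, shape)
        dend = np.ones(shape, bool)
        est_counts = randomization_null_counts(pre, post, dend, 50, 11)
        oracle = []
        r2 = np.random.default_rng(999)
        for _ in range(100):
            a = stamp_discs(shape, np.stack([r2.integers(0, 256, 200), r2.integers(0, 256, 200)], 1), 2)
            b = stamp_discs(shape, np.stack([r2.integers(0, 256, 200), r2.integers(0, 256, 200)], 1), 2)
            oracle.append(count_colocalizations(a & b))
        oracle = np.asarray(oracle, float)
        se = np.hypot(est_counts.std(ddof=1) / np.sqrt(len(est_counts)), oracle.std(ddof=1) / 10.0)
        assert abs(est_counts.mean() - oracle.mean()) <= 3 * se


class TestCrossCorrProfile:
    def test_zero_shift_equals_total_count(self, rng):
        pre = stamp_discs((128, 128), rng.integers(0, 128, (60, 2)), 2)
        post = stamp_discs((128, 128), rng.integers(0, 128, (60, 2)), 2)
        dend = np.ones((128, 128), bool)
        prof = crosscorr_profile(pre, post, dend, 30)
        assert prof.counts[0] == count_colocalizations(pre & post & dend)

    def test_single_pair_vanishes_beyond_disc_reach(self):
        pre = stamp_discs((64, 64), [(32, 32)], 2)
        post = stamp_discs((64, 64), [(32, 32)], 2)
        dend = np.ones((64, 64), bool)
        prof = crosscorr_profile(pre, post, dend, 20)
        assert prof.counts[0] == 1
        assert (prof.counts[prof.shifts_px >= 5] == 0).all()
        assert prof.asymptote == 0.0

    def test_shift_exceeding_image_raises(self):
        m = np.zeros((32, 32), bool)
        with pytest.raises(ValueError):
            crosscorr_profile(m, m, m, max_shift_px=32)


class TestEstimateDiscCount:
    def test_recovers_csr_disc_count_within_two_percent(self, rng):
        n = 2000
        mask = stamp_discs((512, 512), np.stack([rng.integers(0, 512, n), rng.integers(0, 512, n)], 1), 2)
        n_hat = estimate_disc_count(mask, 2)
        assert n_hat == pytest.approx(n, rel=0.02)

    def test_sparse_masks_count_exactly(self):
        mask = stamp_discs((256, 256), [(30, 30), (90, 90), (150, 150)], 2)
        assert estimate_disc_count(mask, 2) == 3


class TestCorrectedDensity:
    def test_subtraction(self):
        dend = np.zeros((256, 256), bool)
        dend[:100, :100] = True
        res = corrected_density(100, 25.0, dend, 50.0)
        assert res.corrected_count == 75.0
        assert not res.negative

    def test_total_equal_noise_gives_zero(self):
        dend = np.ones((64, 64), bool)
        assert corrected_density(40, 40.0, dend, 50.0).corrected_count == 0.0

    def test_forty_thousand_pixels_at_50nm_is_100_um2(self):
        dend = np.zeros((250, 250), bool)
        dend.ravel()[:40_000] = True
        res = corrected_density(60, 10.0, dend, 50.0)
        assert res.dendritic_area_um2 == pytest.approx(100.0)
        assert res.density_per_100um2 == pytest.approx(res.corrected_count)

    def test_negative_corrected_flagged_not_clamped(self):
        res = corrected_density(10, 25.0, np.ones((64, 64), bool), 50.0)
        assert res.corrected_count == -15.0
        assert res.negative

    def test_empty_dendrite_is_unusable(self):
        with pytest.raises(DendriteAreaError):
            corrected_density(10, 0.0, np.zeros((32, 32), bool), 50.0)

    def test_invalid_pixel_size(self):
        with pytest.raises(ValueError):
            corrected_density(10, 0.0, np.ones((8, 8), bool), 0.0)


def test_coloc_count_bounded_by_single_channel_counts(rng):
    # components of pre&post&dend can never exceed those of either channel on
    # the dendrite
    for _ in range(10):
        pre = stamp_discs((128, 128), rng.integers(0, 128, (40, 2)), 2)
        post = stamp_discs((128, 128), rng.integers(0, 128, (40, 2)), 2)
        dend = rng.random((128, 128)) > 0.4
        n = count_colocalizations(triple_and(pre, post, dend))
        assert n <= count_colocalizations(pre & dend)
        assert n <= count_colocalizations(post & dend)
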