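import numpy as np
import pytest
import scipy.ndimage as ndi

from synapcount.puncta import (
    DetectionParams,
    PunctaSet,
    build_puncta_mask,
    detect_maxima,
    detect_puncta,
    fraction_threshold,
    median_filter,
    puncta_from_mask,
    segment_dendrites,
    subtract_background,
)


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        out = subtract_background(np.full((32, 32), 500.0), 4)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_output_nonnegative(self, rng):
        out = subtract_background(rng.uniform(0, 4095, (32, 32)), 4)
        assert (out >= 0).all()

    def test_narrow_spot_on_ramp_preserved_within_ten_percent(self):
        # oracle: morphological grey opening with a ball-shaped structuring
        # element estimates the same background
        ramp = np.tile(np.linspace(0, 200, 64), (64, 1))
        img = ramp.copy()
        img[30:33, 30:33] += 1000.0  # 3-px spot, narrower than the protected zone
        out = subtract_background(img, 4)
        r = 4
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = zz * zz + yy * yy + xx * xx <= r * r
        # half-ball height profile as grayscale SE
        se = np.where(ball.any(axis=0), ball.sum(axis=0).astype(float), -np.inf)
        bg = ndi.grey_erosion(img, structure=se)
        bg = ndi.grey_dilation(bg, structure=se)
        oracle = np.clip(img - bg, 0, None)
        assert out[31, 31] == pytest.approx(oracle[31, 31], rel=0.10)
        assert out[31, 31] == pytest.approx(1000.0, rel=0.10)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((8, 8)), 0)


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((16, 16), 42.0)
        assert np.array_equal(median_filter(img, 3), img)

    def test_single_hot_pixel_removed(self):
        img = np.zeros((16, 16))
        img[8, 8] = 4095
        assert np.array_equal(median_filter(img, 3), np.zeros((16, 16)))

    def test_matches_sorted_neighborhood_oracle(self, rng):
        img = rng.integers(0, 100, (10, 10)).astype(float)
        out = median_filter(img, 3)
        padded = np.pad(img, 1, mode="symmetric")  # scipy's "reflect" duplicates the edge
        for i in range(10):
            for j in range(10):
                window = sorted(padded[i : i + 3, j : j + 3].ravel())
                assert out[i, j] == window[4]

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros((8, 8)), 4)


class TestFractionThreshold:
    def test_constant_image_returns_that_value(self):
        assert fraction_threshold(np.full((10, 10), 7.0), 0.45) == 7.0

    def test_permutation_of_0_to_99_gives_rank_value(self, rng):
        img = rng.permutation(100).reshape(10, 10)
        # rank rule: sorted pixel at index floor(0.45 * N)
        assert fraction_threshold(img, 0.45) == 45

    def test_monotone_in_fraction(self, rng):
        img = rng.uniform(0, 4095, (20, 20))
        ts = [fraction_threshold(img, f) for f in (0.1, 0.3, 0.45, 0.6, 0.9)]
        assert ts == sorted(ts)

    def test_default_below_mean_for_skewed_image(self, rng):
        # sparse bright signal drags the mean above the 45th percentile
        img = rng.normal(100, 3, (64, 64))
        img[:4, :4] = 4000
        assert fraction_threshold(img, 0.45) < img.mean()

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_out_of_range(self, f):
        with pytest.raises(ValueError):
            fraction_threshold(np.ones((4, 4)), f)

    def test_empty_image(self):
        with pytest.raises(ValueError):
            fraction_threshold(np.empty((0,)), 0.45)


def _maxima_oracle(img, threshold):
    """Exhaustive neighborhood comparison with plateau collapse."""
    h, w = img.shape
    cand = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            if img[i, j] <= threshold:
                continue
            neigh = [
                img[a, b]
                for a in range(max(i - 1, 0), min(i + 2, h))
                for b in range(max(j - 1, 0), min(j + 2, w))
                if (a, b) != (i, j)
            ]
            if all(img[i, j] >= v for v in neigh) and any(img[i, j] > v for v in neigh):
                cand[i, j] = True
    lbl, n = ndi.label(cand, structure=np.ones((3, 3), bool))
    out = []
    for k in range(1, n + 1):
        rows, cols = np.nonzero(lbl == k)
        order = np.lexsort((cols, rows))
        out.append((rows[order[0]], cols[order[0]]))
    return sorted(out)


class TestDetectMaxima:
    def test_all_zero_image_gives_no_maxima(self):
        assert detect_maxima(np.zeros((16, 16)), 0.0).shape == (0, 2)

    def test_single_gaussian_spot(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 100 * np.exp(-((yy - 30) ** 2 + (xx - 41) ** 2) / 8.0)
        maxima = detect_maxima(img, 1.0)
        assert maxima.tolist() == [[30, 41]]

    def test_two_separated_spots(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 100 * np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / 6.0)
        img += 80 * np.exp(-((yy - 20) ** 2 + (xx - 44) ** 2) / 6.0)
        assert len(detect_maxima(img, 1.0)) == 2

    def test_matches_exhaustive_oracle_with_plateaus(self, rng):
        for _ in range(20):
            img = rng.integers(0, 6, (14, 14)).astype(float)  # small range forces plateaus
            got = sorted(map(tuple, detect_maxima(img, 1.0)))
            assert got == _maxima_oracle(img, 1.0)

    def test_strictly_greater_than_threshold(self):
        img = np.zeros((9, 9))
        img[4, 4] = 5.0
        assert len(detect_maxima(img, 5.0)) == 0
        assert len(detect_maxima(img, 4.9)) == 1


class TestBuildPunctaMask:
    def test_empty_set_gives_empty_mask(self):
        mask = build_puncta_mask(PunctaSet(np.empty((0, 2)), 2, (32, 32)))
        assert not mask.any()

    def test_radius_two_disc_has_thirteen_pixels(self):
        mask = build_puncta_mask(PunctaSet([(16, 16)], 2, (32, 32)))
        assert mask.sum() == 13
        rows, cols = np.nonzero(mask)
        assert ((rows - 16) ** 2 + (cols - 16) ** 2 <= 4).all()

    def test_border_centroid_is_clipped_not_dropped(self):
        mask = build_puncta_mask(PunctaSet([(0, 0)], 2, (32, 32)))
        assert 0 < mask.sum() < 13

    def test_out_of_bounds_centroid_rejected(self):
        with pytest.raises(ValueError):
            PunctaSet([(40, 2)], 2, (32, 32))

    def test_centroid_recovery_for_well_separated_puncta(self, rng):
        centers = [(10, 10), (10, 40), (40, 10), (40, 40), (25, 25)]
        puncta = PunctaSet(centers, 2, (64, 64))
        recovered = puncta_from_mask(puncta.to_mask(), 2)
        got = sorted(map(tuple, recovered.centroids))
        assert all(
            abs(a[0] - b[0]) <= 1 and abs(a[1] - b[1]) <= 1 for a, b in zip(got, sorted(centers))
        )


class TestSegmentDendrites:
    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_dendrites(np.full((32, 32), 9.0), 2)
        assert not mask.any()

    def test_half_bright_half_dark_matches_threshold_dilation_oracle(self):
        img = np.zeros((40, 40))
        img[:, 20:] = 100.0
        got = segment_dendrites(img, 2)
        base = img > img.mean()
        rr, cc = np.mgrid[-2:3, -2:3]
        se = rr * rr + cc * cc <= 4
        oracle = ndi.binary_dilation(base, structure=se)
        assert np.array_equal(got, oracle)
        # boundary extended exactly 2 px into the dark half
        assert got[:, 18].all() and not got[:, 17].any()


class TestDetectionParams:
    def test_defaults_follow_protocol(self):
        p = DetectionParams()
        assert p.rollball_radius_px == 4
        assert p.median_size_px == 3
        assert p.puncta_threshold_fraction == 0.45
        assert p.puncta_dilation_px == 2
        assert p.dendrite_dilation_px == 2

    @pytest.mark.parametrize("kwargs", [dict(puncta_threshold_fraction=0.0), dict(rollball_radius_px=0)])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectionParams(**kwargs)

    def test_key_value_file_roundtrip(self, tmp_path):
        path = tmp_path / "params.cfg"
        path.write_text("puncta_threshold_fraction = 0.6\ndendrite_dilation_px = 4  # caption variant\n")
        p = DetectionParams.from_file(path)
        assert p.puncta_threshold_fraction == 0.6
        assert p.dendrite_dilation_px == 4

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "params.cfg"
        path.write_text("bogus = 1\n")
        with pytest.raises(KeyError):
            DetectionParams.from_file(path)


class TestDetectionPipeline:
    def test_masks_nest_as_threshold_fraction_increases(self, rng):
        img = rng.normal(50, 5, (64, 64))
        for r, c in [(10, 12), (30, 44), (50, 20)]:
            img[r, c] += rng.uniform(20, 200)
        lo = detect_puncta(img, DetectionParams(puncta_threshold_fraction=0.30))
        hi = detect_puncta(img, DetectionParams(puncta_threshold_fraction=0.70))
        assert (lo.mask | hi.mask == lo.mask).all()  # hi ⊆ lo

    def test_detection_is_deterministic(self, rng):
        img = rng.uniform(0, 4095, (64, 64))
        a = detect_puncta(img)
        b = detect_puncta(img)
        assert np.array_equal(a.puncta.centroids, b.puncta.centroids)
        assert a.threshold == b.threshold
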