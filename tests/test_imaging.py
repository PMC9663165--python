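"""Image scoring: thresholding, profiles, continuity, puncta, spines."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from epibind import imaging, synthetic as syn


class TestBackgroundSubtraction:
    def test_constant_image_goes_to_zero(self):
        img = np.full((64, 64), 37.0)
        out = imaging.subtract_background(img, radius=10)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_all_zero_unchanged(self):
        out = imaging.subtract_background(np.zeros((32, 32)), radius=10)
        np.testing.assert_array_equal(out, 0.0)

    def test_small_bright_disk_preserved(self):
        img = np.full((96, 96), 40.0)
        yy, xx = np.mgrid[0:96, 0:96]
        disk = (xx - 48) ** 2 + (yy - 48) ** 2 <= 3 ** 2
        img[disk] = 200.0
        out = imaging.subtract_background(img, radius=30)
        assert out[48, 48] == pytest.approx(160.0, rel=0.05)

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            imaging.subtract_background(np.zeros((8, 8)), radius=0)


class TestThreshold:
    def test_fixed_threshold_checkerboard(self):
        img = np.indices((8, 8)).sum(axis=0) % 2
        img = np.where(img == 1, 150, 50).astype(np.uint8)
        out = imaging.threshold_channel(img, 100)
        np.testing.assert_array_equal(out, np.where(img == 150, 255, 0))

    def test_pixel_at_threshold_is_off(self):
        img = np.array([[100, 101]], dtype=np.uint8)
        out = imaging.threshold_channel(img, 100)
        np.testing.assert_array_equal(out, [[0, 255]])

    def test_otsu_matches_exhaustive_between_class_variance(self):
        rng = np.random.default_rng(0)
        img = np.concatenate([
            rng.normal(40, 6, 600), rng.normal(190, 10, 400)
        ]).clip(0, 255).astype(np.uint8).reshape(25, 40)
        out = imaging.threshold_channel(img, "otsu")
        # exhaustive search over integer thresholds maximizing
        # between-class variance
        flat = img.ravel().astype(float)
        best_t, best_v = None, -1.0
        for t in range(int(flat.min()), int(flat.max())):
            lo, hi = flat[flat <= t], flat[flat > t]
            if lo.size == 0 or hi.size == 0:
                continue
            w0, w1 = lo.size / flat.size, hi.size / flat.size
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_t, best_v = t, v
        np.testing.assert_array_equal(out, np.where(flat > best_t, 255,
                                                    0).reshape(img.shape))

    def test_otsu_on_constant_image_raises(self):
        with pytest.raises(ValueError, match="fixed"):
            imaging.threshold_channel(np.full((8, 8), 7, dtype=np.uint8),
                                      "otsu")

    def test_rescaled_intensities_with_rescaled_fixed_threshold(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 101, size=(16, 16)).astype(float)
        a = imaging.threshold_channel(img, 50)
        b = imaging.threshold_channel(img * 2.0, 100)
        np.testing.assert_array_equal(a, b)


class TestProfileSampling:
    def test_horizontal_path_over_bright_row(self):
        img = np.zeros((5, 20), dtype=np.uint8)
        img[2, :] = 255
        prof = imaging.sample_profile(img, np.array([[0, 2], [10, 2]]))
        assert prof.size == 11
        assert (prof == 255).all()

    def test_all_zero_image_gives_zero_profile(self):
        prof = imaging.sample_profile(np.zeros((10, 10)),
                                      np.array([[1, 1], [8, 8]]))
        assert (prof == 0).all()

    def test_diagonal_path_matches_nearest_pixel_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 2, size=(30, 30)).astype(np.uint8) * 255
        path = np.array([[2.0, 3.0], [25.0, 17.0]])
        prof = imaging.sample_profile(img, path)
        # independent nearest-pixel lookup
        total = np.hypot(23.0, 14.0)
        n = int(round(total)) + 1
        t = np.linspace(0, 1, n)
        xs, ys = 2 + t * 23.0, 3 + t * 14.0
        expected = img[np.round(ys).astype(int), np.round(xs).astype(int)]
        np.testing.assert_array_equal(prof, expected)

    def test_out_of_bounds_vertex_named(self):
        with pytest.raises(ValueError, match="vertex 1"):
            imaging.sample_profile(np.zeros((10, 10)),
                                   np.array([[1, 1], [50, 1]]))


class TestContinuity:
    def test_exact_identities(self):
        full = np.full(101, 255.0)
        assert imaging.map2_continuity(full).score == 100.0
        assert imaging.map2_continuity(np.zeros(101)).score == 0.0
        half = np.concatenate([np.full(50, 255.0), np.zeros(50)])
        assert imaging.map2_continuity(half).score == 50.0

    def test_auc_formula_equals_fraction_of_on_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            prof = rng.choice([0, 255], size=rng.integers(5, 200))
            sc = imaging.map2_continuity(prof.astype(float))
            assert sc.score == pytest.approx(100.0 * (prof == 255).mean())
            assert sc.score == pytest.approx(
                100.0 * sc.auc / (255.0 * sc.n_samples))

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            imaging.map2_continuity(np.array([]))

    def test_generator_gap_fraction_recovered(self):
        p = syn.DendriteSimParams(map2_gap_fraction=0.3, seed=2)
        channels, paths, _ = syn.gen_dendrite_image(p)
        sub = imaging.subtract_background(channels["MAP2"]).astype(np.uint8)
        binary = imaging.threshold_channel(sub, "otsu")
        prof = imaging.sample_profile(binary, paths[0])
        sc = imaging.map2_continuity(prof)
        assert sc.score == pytest.approx(70.0, abs=5.0)


class TestPuncta:
    def test_empty_image(self):
        assert imaging.detect_puncta(np.zeros((16, 16), np.uint8)) == []

    def test_ten_disjoint_blobs(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        for i in range(10):
            r, c = 4 * (i // 5) + 2, 7 * (i % 5) + 2
            img[r, c:c + 5] = 255  # 5-pixel line blobs
        puncta = imaging.detect_puncta(img, min_area=2, max_area=50)
        assert len(puncta) == 10

    def test_blob_below_min_area_ignored(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[5, 5] = 255
        assert imaging.detect_puncta(img, min_area=2, max_area=50) == []

    def test_min_greater_than_max_raises(self):
        with pytest.raises(ValueError):
            imaging.detect_puncta(np.zeros((4, 4)), min_area=5, max_area=2)

    def test_translation_invariance_of_count(self):
        p = syn.DendriteSimParams(seed=5)
        channels, paths, _ = syn.gen_dendrite_image(p)
        binary = imaging.threshold_channel(channels["PSD95"], 100)
        n0 = len(imaging.detect_puncta(binary))
        shifted = np.roll(binary, (7, 11), axis=(0, 1))
        # roll wraps; valid as long as no blob crosses the border
        assert len(imaging.detect_puncta(shifted)) == n0


class TestPunctaDensity:
    PATH = np.array([[0.0, 0.0], [50.0, 0.0]])

    def test_zero_puncta(self):
        rec = imaging.puncta_density([], self.PATH, pixel_size_um=1.0)
        assert rec.count == 0 and rec.density_per_um == 0.0

    def test_ten_on_fifty_micron_path(self):
        puncta = [imaging.PunctaRecord((x, 0.2), 5)
                  for x in np.linspace(1, 49, 10)]
        rec = imaging.puncta_density(puncta, self.PATH, pixel_size_um=1.0)
        assert rec.count == 10
        assert rec.density_per_um == pytest.approx(0.2)

    def test_lateral_capture_is_inclusive(self):
        puncta = [imaging.PunctaRecord((25.0, 1.0), 5),   # exactly 1 µm off
                  imaging.PunctaRecord((25.0, 1.5), 5)]   # beyond
        rec = imaging.puncta_density(puncta, self.PATH, pixel_size_um=1.0,
                                     max_lateral_um=1.0)
        assert rec.count == 1

    def test_generator_density_recovered_from_ground_truth_centroids(self):
        # oracle route: count true centroids near the path, no detection
        p = syn.DendriteSimParams(puncta_density={"PSD95": 0.3},
                                  path_length_px=1500, shape=(512, 512),
                                  seed=6)
        _, paths, gt = syn.gen_dendrite_image(p)
        cents = gt.labels["puncta_centroids"]["PSD95"]
        puncta = [imaging.PunctaRecord(tuple(c), 5) for c in cents]
        rec = imaging.puncta_density(puncta, paths[0], p.pixel_size_um)
        lam, L = 0.3, rec.length_um
        assert rec.density_per_um == pytest.approx(
            lam, abs=3 * np.sqrt(lam / L))

    def test_density_invariant_to_pixel_size_at_fixed_geometry(self):
        # same physical layout sampled twice as finely
        path_coarse = np.array([[0.0, 0.0], [100.0, 0.0]])
        path_fine = path_coarse * 2.0
        pts_um = np.linspace(5, 95, 12)
        coarse = [imaging.PunctaRecord((x, 0.0), 5) for x in pts_um]
        fine = [imaging.PunctaRecord((2 * x, 0.0), 5) for x in pts_um]
        r1 = imaging.puncta_density(coarse, path_coarse, pixel_size_um=1.0)
        r2 = imaging.puncta_density(fine, path_fine, pixel_size_um=0.5)
        assert r1.density_per_um == pytest.approx(r2.density_per_um)


class TestContactPaths:
    def mask(self):
        m = np.zeros((40, 40), dtype=bool)
        m[10:20, 10:20] = True
        return m

    def test_path_inside_mask_is_contact(self):
        paths = [np.array([[12.0, 12.0], [18.0, 18.0]])]
        assert imaging.contact_paths(paths, self.mask(), 1.0) == {0}

    def test_far_path_is_not_contact(self):
        paths = [np.array([[30.0, 30.0], [38.0, 38.0]])]
        assert imaging.contact_paths(paths, self.mask(), 1.0,
                                     dilation_um=2.0) == set()

    def test_tangent_at_exact_radius_is_contact(self):
        # mask edge at column 19; path at column 24 -> distance 5 px
        paths = [np.array([[24.0, 12.0], [24.0, 18.0]])]
        assert imaging.contact_paths(paths, self.mask(), 1.0,
                                     dilation_um=5.0) == {0}
        assert imaging.contact_paths(paths, self.mask(), 1.0,
                                     dilation_um=4.0) == set()

    def test_empty_mask_warns_and_returns_nothing(self):
        paths = [np.array([[1.0, 1.0], [5.0, 5.0]])]
        with pytest.warns(UserWarning, match="empty"):
            out = imaging.contact_paths(paths, np.zeros((10, 10)), 1.0)
        assert out == set()


class TestSpineDensity:
    def test_arithmetic(self):
        table = pd.DataFrame({"group": ["a"], "neuron_id": ["a_0"],
                              "count": [10], "length_um": [10.0]})
        per_neuron, per_group = imaging.spine_density(table)
        assert per_neuron["density_per_um"].iloc[0] == 1.0
        assert per_group.loc[0, "mean"] == 1.0

    def test_equal_groups_zero_difference(self):
        table = pd.DataFrame({
            "group": ["a"] * 3 + ["b"] * 3,
            "neuron_id": list("abcdef"),
            "count": [10, 20, 30, 10, 20, 30],
            "length_um": [10.0] * 6})
        _, per_group = imaging.spine_density(table)
        m = per_group.set_index("group")["mean"]
        assert m["a"] == m["b"]

    def test_zero_length_raises(self):
        table = pd.DataFrame({"group": ["a"], "neuron_id": ["x"],
                              "count": [1], "length_um": [0.0]})
        with pytest.raises(ValueError):
            imaging.spine_density(table)

    def test_forty_percent_reduction_recovered_end_to_end(self):
        p = syn.SpineSimParams(group_multipliers={"control": 1.0,
                                                  "treated": 0.6},
                               neurons_per_group=72, seed=7)
        table, gt = syn.gen_spine_counts(p)
        _, per_group = imaging.spine_density(table)
        g = per_group.set_index("group")
        est = 100 * (1 - g.loc["treated", "mean"] / g.loc["control", "mean"])
        ratio = g.loc["treated", "mean"] / g.loc["control", "mean"]
        se = 100 * ratio * np.sqrt(
            (g.loc["treated", "sem"] / g.loc["treated", "mean"]) ** 2
            + (g.loc["control", "sem"] / g.loc["control", "mean"]) ** 2)
        assert abs(est - 40.0) <= 3 * se


def test_16bit_input_is_rescaled_with_warning():
    img = (np.arange(256, dtype=np.uint16) * 257).reshape(16, 16)
    with pytest.warns(UserWarning, match="rescal"):
        out = imaging.normalize_to_8bit(img)
    assert out.dtype == np.uint8
    assert out.min() == 0 and out.max() == 255


class TestContinuityProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.sampled_from([0, 255]), min_size=1, max_size=400))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_score_equals_on_sample_fraction(self, samples):
        profile = np.asarray(samples, dtype=float)
        sc = imaging.map2_continuity(profile)
        assert sc.score == pytest.approx(100.0 * (profile == 255).mean())
        assert 0.0 <= sc.score <= 100.0
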