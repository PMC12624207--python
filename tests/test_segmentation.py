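"""Unit and oracle tests for the punctum-segmentation chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.morphology import disk, opening

from conftest import disc_mask, noise_free, puncta_config, random_label_map
from trisyn.scenes import generate_scene
from trisyn.segmentation import (
    SegmentationParams,
    binarize,
    filter_small,
    gaussian_smooth,
    measure_particles,
    segment_channel,
    subtract_background,
    watershed_split,
)


class TestSubtractBackground:
    def test_constant_plane_goes_to_zero(self):
        plane = np.full((40, 40), 7.5)
        out = subtract_background(plane, 5)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_radius_zero_is_identity(self, rng):
        plane = rng.random((30, 30))
        assert np.array_equal(subtract_background(plane, 0), plane)

    def test_spot_on_gradient_background(self):
        yy, xx = np.mgrid[0:80, 0:80]
        background = 10 + 0.1 * xx  # smooth gradient
        plane = background.astype(float)
        plane[40, 40] += 100.0  # 1-px spike survives opening subtraction
        out = subtract_background(plane, 6)
        assert out[40, 40] >= 0.9 * 100.0
        off_spot = out[disc_mask(out.shape, 40, 40, 8) == 0]
        assert np.median(off_spot) <= 0.1 * np.median(background)

    def test_matches_independent_opening(self, rng):
        plane = rng.random((48, 48)) * 50
        expected = plane - opening(plane, disk(4))
        out = subtract_background(plane, 4)
        assert np.allclose(out, np.clip(expected, 0, None))


class TestGaussianSmooth:
    def test_sigma_zero_identity_and_constant_invariance(self, rng):
        plane = rng.random((25, 25))
        assert np.array_equal(gaussian_smooth(plane, 0), plane)
        const = np.full((25, 25), 3.0)
        assert np.allclose(gaussian_smooth(const, 2.0), const)

    def test_delta_impulse_matches_explicit_kernel(self):
        plane = np.zeros((41, 41))
        plane[20, 20] = 1.0
        sigma = 1.7
        out = gaussian_smooth(plane, sigma)
        # independent oracle: explicit truncated-Gaussian kernel, normalised
        r = int(4 * sigma + 0.5)
        ax = np.arange(-r, r + 1)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        assert np.allclose(out[20 - r : 20 + r + 1, 20 - r : 20 + r + 1], kernel, atol=1e-6)
        assert out[20, 20] == pytest.approx(kernel[r, r], rel=1e-5)

    def test_total_intensity_conserved(self, rng):
        plane = rng.random((60, 60)) * 10
        out = gaussian_smooth(plane, 2.5)
        assert out.sum() == pytest.approx(plane.sum(), rel=0.01)


class TestBinarize:
    def test_two_level_plane_otsu_selects_bright_pixels(self, rng):
        plane = np.zeros((50, 50))
        bright = rng.choice(2500, size=250, replace=False)  # 10 % of pixels
        plane.ravel()[bright] = 10.0
        # oracle: exhaustive threshold search on the 2-level histogram —
        # any threshold in (0, 10) yields exactly the bright class
        mask = binarize(plane, "otsu")
        assert mask.sum() == 250
        assert np.array_equal(mask, plane == 10.0)

    def test_manual_threshold_at_max_empty(self, rng):
        plane = rng.random((20, 20))
        assert binarize(plane, "manual", manual_threshold=plane.max()).sum() == 0

    def test_constant_plane_empty(self):
        assert binarize(np.full((20, 20), 4.0), "otsu").sum() == 0

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            binarize(np.zeros((5, 5)), "magic")


class TestWatershedSplit:
    def test_single_blob_one_label(self):
        mask = disc_mask((40, 40), 20, 20, 8)
        labels = watershed_split(mask)
        assert labels.max() == 1

    def test_two_overlapping_discs_split(self):
        # centres 1.5 radii apart merge into one component
        r = 8
        mask = disc_mask((50, 60), 25, 22, r) | disc_mask((50, 60), 25, 34, r)
        from scipy import ndimage as ndi

        assert ndi.label(mask)[1] == 1  # merged
        labels = watershed_split(mask)
        assert labels.max() == 2
        # split line lies between the centres
        assert labels[25, 22] != labels[25, 34]

    def test_empty_mask(self):
        assert watershed_split(np.zeros((10, 10), dtype=bool)).max() == 0

    def test_union_equals_mask(self, rng):
        mask = random_label_map(rng, (64, 64)) > 0
        labels = watershed_split(mask)
        assert np.array_equal(labels > 0, mask)


class TestFilterSmall:
    def test_paper_rule_keeps_area_ge_8(self):
        labels = np.zeros((30, 30), dtype=int)
        labels[0, 0:5] = 1  # 5 px -> dropped
        labels[5, 0:8] = 2  # 8 px -> kept
        labels[10, 0:12] = 3  # 12 px -> kept
        out = filter_small(labels, 8)
        sizes = sorted(np.bincount(out.ravel())[1:])
        assert sizes == [8, 12]
        assert sorted(np.unique(out)) == [0, 1, 2]  # relabelled contiguously

    def test_min_one_is_identity(self, rng):
        labels = random_label_map(rng)
        assert np.array_equal(filter_small(labels, 1), labels)

    def test_matches_pixel_count_oracle(self, rng):
        for _ in range(10):
            labels = random_label_map(rng)
            out = filter_small(labels, 8)
            surviving = set()
            for lab in np.unique(labels[labels > 0]):
                if (labels == lab).sum() >= 8:
                    surviving.add(lab)
            out_sizes = sorted(np.bincount(out.ravel())[1:])
            exp_sizes = sorted(int((labels == lab).sum()) for lab in surviving)
            assert out_sizes == exp_sizes

    @settings(deadline=None, max_examples=20)
    @given(st.integers(min_value=1, max_value=30), st.integers(min_value=0, max_value=2**31 - 1))
    def test_monotone_in_min_size(self, min_size, seed):
        labels = random_label_map(np.random.default_rng(seed))
        a = filter_small(labels, min_size)
        b = filter_small(labels, min_size + 3)
        assert b.max() <= a.max()
        assert (b > 0).sum() <= (a > 0).sum()


class TestMeasureParticles:
    def test_uniform_particle(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2, 0:10] = 1
        raw = np.full((10, 10), 7.0)
        t = measure_particles(labels, raw, 0.04)
        assert t.loc[0, "area_px"] == 10
        assert t.loc[0, "mean_raw_intensity"] == 7.0
        assert t.loc[0, "area_um2"] == pytest.approx(10 * 0.04**2)

    def test_two_value_mean(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0:2] = 1
        raw = np.zeros((4, 4))
        raw[0, 0], raw[0, 1] = 2.0, 4.0
        t = measure_particles(labels, raw, 1.0)
        assert t.loc[0, "mean_raw_intensity"] == 3.0

    def test_matches_pixel_loop_oracle(self, rng):
        labels = random_label_map(rng)
        raw = rng.random(labels.shape) * 100
        t = measure_particles(labels, raw, 0.04).set_index("label")
        for lab in np.unique(labels[labels > 0]):
            pix = raw[labels == lab]
            assert t.loc[lab, "area_px"] == pix.size
            assert t.loc[lab, "mean_raw_intensity"] == pytest.approx(pix.mean())


class TestSegmentChannel:
    def test_recovers_well_separated_puncta_exactly(self):
        cfg = puncta_config(
            field_size_px=(512, 512),
            min_separation_px=24,
            seed=4,
            **noise_free(),
        )
        scene, gt = generate_scene(cfg)
        params = SegmentationParams(background_radius_px=0, watershed_min_distance_px=5)
        table, _ = segment_channel(scene, "vacht", params)
        assert len(table) == len(gt.presyn)

    def test_tiny_puncta_filtered_to_zero(self):
        # 4-px particles, deterministic manual threshold
        from trisyn.segmentation import MultiChannelScene

        plane = np.zeros((64, 64))
        for cy in (10, 30, 50):
            plane[cy : cy + 2, 10:12] = 50.0  # 4-px squares
        scene = MultiChannelScene(planes={"vacht": plane}, pixel_size_um=0.04)
        params = SegmentationParams(
            background_radius_px=0,
            gaussian_sigma_px=0,
            threshold_method="manual",
            manual_threshold=25.0,
        )
        table, _ = segment_channel(scene, "vacht", params)
        assert len(table) == 0

    def test_count_non_increasing_in_min_size(self):
        cfg = puncta_config(seed=9)
        scene, _ = generate_scene(cfg)
        counts = []
        for ms in (1, 8, 20, 50):
            params = SegmentationParams(background_radius_px=5, min_size_px=ms)
            table, _ = segment_channel(scene, "vacht", params)
            counts.append(len(table))
        assert counts == sorted(counts, reverse=True)

    def test_missing_role_raises(self):
        cfg = puncta_config(seed=1)
        scene, _ = generate_scene(cfg)
        with pytest.raises(KeyError, match="psd95"):
            segment_channel(scene, "psd95")
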