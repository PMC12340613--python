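"""Subvolume cropping, binarization, skeletons, density and distances."""

import numpy as np
import pytest
from scipy import ndimage

from stallox import simkit
from stallox.geometry import (
    AngiogramVolume,
    crop_subvolume,
    density_histogram,
    compare_density_by_class,
    nearest_large_vessel,
    preprocess_and_binarize,
    skeletonize_mask,
)


@pytest.fixture(scope="module")
def tube_angiogram():
    # radius >= 4 um: the 3x3x3 median filter erodes the one-voxel shell of
    # thinner tubes, which dominates their surface-to-volume ratio
    tubes = [
        simkit.TubeSpec((15.0, 10.0, 0.0), (15.0, 10.0, 39.0), 4.0, "arteriole"),
        simkit.TubeSpec((5.0, 30.0, 0.0), (5.0, 30.0, 39.0), 4.0, "venule"),
    ]
    return simkit.simulate_angiogram((30, 40, 40), (1, 1, 1), tubes, seed=7,
                                     noise_sd=4.0, blur_sigma_um=0.5)


class TestCrop:
    def test_interior_crop_spans_151_voxels(self):
        vol = AngiogramVolume(np.zeros((160, 160, 160), dtype=np.uint8), (1, 1, 1))
        sub, local = crop_subvolume(vol, (80, 80, 80), half_extent_vox=75)
        assert sub.intensity.shape == (151, 151, 151)
        assert local == (75, 75, 75)
        assert not sub.clipped

    def test_corner_point_clipped_with_flag(self):
        vol = AngiogramVolume(np.zeros((40, 40, 40)), (1, 1, 1))
        sub, local = crop_subvolume(vol, (2, 2, 2), half_extent_vox=10)
        assert sub.clipped
        assert sub.intensity.shape == (13, 13, 13)
        assert local == (2, 2, 2)

    def test_crop_idempotent_at_same_center(self):
        vol = AngiogramVolume(np.arange(64000).reshape(40, 40, 40), (1, 1, 1))
        once, local = crop_subvolume(vol, (20, 20, 20), half_extent_vox=10)
        twice, local2 = crop_subvolume(once, local, half_extent_vox=10)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_point_outside_raises(self):
        vol = AngiogramVolume(np.zeros((10, 10, 10)), (1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            crop_subvolume(vol, (10, 0, 0))


class TestBinarize:
    def test_noiseless_two_level_volume_exact(self):
        # planar boundary: the median filter is exact on half-spaces
        truth = np.zeros((20, 20, 20), dtype=bool)
        truth[10:] = True
        vol = AngiogramVolume(np.where(truth, 100.0, 10.0), (1, 1, 1))
        mask, flags = preprocess_and_binarize(vol)
        np.testing.assert_array_equal(mask, truth)

    def test_synthetic_tube_dice_over_09(self, tube_angiogram):
        vol = AngiogramVolume(tube_angiogram.volume, (1, 1, 1))
        mask, _ = preprocess_and_binarize(vol)
        truth = tube_angiogram.vessel_truth_mask
        dice = 2 * np.sum(mask & truth) / (mask.sum() + truth.sum())
        assert dice >= 0.9

    def test_impulse_noise_removed_by_median_filter(self):
        truth = np.zeros((20, 20, 20), dtype=bool)
        truth[8:12, 8:12, 8:12] = True
        img = np.where(truth, 100.0, 10.0)
        clean, _ = preprocess_and_binarize(AngiogramVolume(img.copy(), (1, 1, 1)))
        img[2, 2, 2] = 500.0  # single-voxel impulse
        mask, _ = preprocess_and_binarize(AngiogramVolume(img, (1, 1, 1)))
        np.testing.assert_array_equal(mask, clean)
        assert not mask[2, 2, 2]

    def test_constant_volume_empty_mask_with_flag(self):
        mask, flags = preprocess_and_binarize(
            AngiogramVolume(np.full((8, 8, 8), 3.0), (1, 1, 1))
        )
        assert not mask.any()
        assert "constant_volume" in flags


class TestSkeleton:
    def test_straight_tube_gives_single_axis_path(self):
        mask = np.zeros((15, 15, 40), dtype=bool)
        zz, yy = np.mgrid[0:15, 0:15]
        disk = (zz - 7) ** 2 + (yy - 7) ** 2 <= 9
        mask[disk] = True
        skel = skeletonize_mask(mask)
        assert skel[mask].sum() == skel.sum()  # skeleton within mask
        assert ndimage.label(skel)[1] == 1
        length = skel.any(axis=(0, 1)).sum()
        # thinning erodes the open tube ends by up to ~the tube radius
        assert 40 - 2 * 3 <= length <= 40
        # interior: single voxel per axial slice, on the true centerline
        mid = skel[:, :, 20]
        assert mid.sum() == 1 and mid[7, 7]

    def test_empty_mask_empty_skeleton(self):
        assert not skeletonize_mask(np.zeros((5, 5, 5), dtype=bool)).any()

    def test_two_tubes_two_components(self, tube_angiogram):
        vol = AngiogramVolume(tube_angiogram.volume, (1, 1, 1))
        mask, _ = preprocess_and_binarize(vol)
        skel = skeletonize_mask(mask)
        assert np.all(mask[skel])
        assert ndimage.label(mask)[1] == ndimage.label(skel)[1] == 2


class TestDensity:
    def test_single_voxel_at_10um(self):
        mask = np.zeros((21, 21, 21), dtype=bool)
        mask[10, 10, 20] = True
        hist = density_histogram((10, 10, 10), mask, (1, 1, 1))
        assert hist.counts.sum() == 1
        assert hist.counts[10] == 1  # bin [10, 11)

    def test_total_equals_vessel_voxel_count(self, tube_angiogram, rng):
        vol = AngiogramVolume(tube_angiogram.volume, (1, 1, 1))
        mask, _ = preprocess_and_binarize(vol)
        hist = density_histogram((15, 20, 20), mask, (1, 1, 1))
        assert hist.counts.sum() == mask.sum()

    def test_solid_sphere_cumulative_growth_is_cubic(self):
        n = 41
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
        c = n // 2
        r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
        mask = r <= 15
        hist = density_histogram((c, c, c), mask, (1, 1, 1))
        cum = np.cumsum(hist.counts)
        radii = hist.bin_edges_um[1:]
        inside = (radii >= 5) & (radii <= 15)
        expect = 4.0 / 3.0 * np.pi * radii[inside] ** 3
        assert np.max(np.abs(cum[inside] / expect - 1.0)) < 0.1

    def test_anisotropic_distances_honored(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 4] = True  # 2 voxels in x
        mask[4, 2, 2] = True  # 2 voxels in z
        hist = density_histogram((2, 2, 2), mask, (3.0, 1.0, 1.0))
        # x offset: 2 um; z offset: 6 um
        assert hist.counts[2] == 1
        assert hist.counts[6] == 1


class TestNearestLargeVessel:
    def test_point_inside_arteriole_is_zero(self, tube_angiogram):
        out = nearest_large_vessel((15, 10, 20),
                                   tube_angiogram.large_vessel_labels, (1, 1, 1))
        assert out["arteriole"] == 0.0

    def test_three_four_five_triangle(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[5, 8, 9] = 1  # offset (0, 3, 4) from point
        out = nearest_large_vessel((5, 5, 5), labels, (1, 1, 1))
        assert out["arteriole"] == pytest.approx(5.0)
        assert out["venule"] is None

    def test_matches_brute_force_scan(self, tube_angiogram, rng):
        labels = tube_angiogram.large_vessel_labels
        for _ in range(5):
            p = tuple(int(rng.integers(0, s)) for s in labels.shape)
            out = nearest_large_vessel(p, labels, (2.0, 1.0, 1.0))
            for name, code in (("arteriole", 1), ("venule", 2)):
                coords = np.argwhere(labels == code)
                d = np.sqrt(
                    (((coords - p) * np.array([2.0, 1.0, 1.0])) ** 2).sum(axis=1)
                ).min()
                assert abs(out[name] - d) < 1e-9

    def test_constructed_offset_recovered(self):
        tubes = [simkit.TubeSpec((5.0, 25.0, 0.0), (5.0, 25.0, 19.0), 2.0,
                                 "arteriole")]
        angio = simkit.simulate_angiogram((11, 40, 20), (1, 1, 1), tubes, seed=0)
        out = nearest_large_vessel((5, 5, 10), angio.large_vessel_labels, (1, 1, 1))
        # distance to tube edge = 20 - radius
        assert out["arteriole"] == pytest.approx(18.0, abs=1.0)


class TestDensityByClass:
    def _hist(self, counts):
        from stallox.geometry import DensityHistogram

        counts = np.asarray(counts, dtype=float)
        return DensityHistogram(
            np.arange(counts.size + 1, dtype=float), counts, (0, 0, 0), (0, 0, 0),
            (1, 1, 1),
        )

    def test_identical_histograms_identical_curves(self):
        h = self._hist([1, 2, 3])
        out = compare_density_by_class([h, h], ["hypoxic", "normoxic"])
        hyp = out[out["class"] == "hypoxic"]["mean_count"].to_numpy()
        nor = out[out["class"] == "normoxic"]["mean_count"].to_numpy()
        np.testing.assert_array_equal(hyp, nor)

    def test_single_event_per_class_returns_raw_histograms(self):
        a, b = self._hist([5, 0, 1]), self._hist([2, 2, 2])
        out = compare_density_by_class([a, b], ["x", "y"])
        np.testing.assert_array_equal(
            out[out["class"] == "x"]["mean_count"].to_numpy(), [5, 0, 1]
        )

    def test_class_dependent_far_field_density_diverges(self, rng):
        # same near-field, different far-field: curves agree near, split far
        hists, classes = [], []
        for k in range(10):
            near = np.full(10, 20.0)
            far = np.full(10, 5.0 if k < 5 else 20.0)
            hists.append(self._hist(np.concatenate([near, far])))
            classes.append("hypoxic" if k < 5 else "normoxic")
        out = compare_density_by_class(hists, classes)
        hyp = out[out["class"] == "hypoxic"].set_index("bin_center_um")["mean_count"]
        nor = out[out["class"] == "normoxic"].set_index("bin_center_um")["mean_count"]
        assert np.allclose(hyp.iloc[:10], nor.iloc[:10])
        assert (nor.iloc[10:] - hyp.iloc[10:]).min() > 10.0
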