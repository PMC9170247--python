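"""Channel normalization, smoothing, the three segmentations, and ratios."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from skimage.morphology import disk

from notopattern.imaging import (
    Image2D,
    SegmentationParams,
    cells_seg2,
    neighborhood_seg3,
    normalize_channel,
    relative_intensity,
    segment_image,
    smooth,
    threshold_seg1,
)
from notopattern.synthetic_data import synth_microscopy


class TestNormalizeChannel:
    def test_affine_map_to_unit_interval(self):
        img = np.array([[10.0, 15.0], [20.0, 10.0]])
        out = normalize_channel(img).pixels
        assert out.min() == 0.0 and out.max() == 1.0
        assert out[0, 1] == pytest.approx(0.5)

    def test_already_normalized_unchanged(self):
        img = np.array([[0.0, 0.25], [0.75, 1.0]])
        assert np.allclose(normalize_channel(img).pixels, img)

    def test_constant_image_maps_to_zeros_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = normalize_channel(np.full((4, 4), 7.0)).pixels
        assert np.array_equal(out, np.zeros((4, 4)))
        assert any("constant" in r.message for r in caplog.records)

    def test_non_finite_rejected(self):
        img = np.ones((3, 3))
        img[1, 1] = np.nan
        with pytest.raises(ValueError):
            normalize_channel(img)


def _reference_gaussian(img, sigma):
    """Independent separable Gaussian: explicit sampled kernel, reflect pad."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    out = np.pad(img, radius, mode="symmetric")
    out = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 0, out)
    out = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, out)
    return out[radius:-radius, radius:-radius]


class TestSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 0.4)
        assert np.allclose(smooth(img, 3).pixels, img, atol=1e-12)

    def test_single_peak_spreads_but_mass_preserved(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = smooth(img, 3).pixels
        assert out.max() < 1.0
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_reference_separable_filter(self, rng):
        img = rng.random((30, 35))
        assert np.allclose(smooth(img, 3).pixels, _reference_gaussian(img, 3.0), atol=1e-6)


class TestThresholdSeg1:
    def test_constant_image_gives_empty_mask(self):
        params = SegmentationParams(local_kernel_diameter=9)
        assert not threshold_seg1(np.full((30, 30), 0.5), params).any()

    def test_only_above_global_median_rule_passes(self):
        # mostly-ones image with one 3: median 1, global threshold 1.5 ->
        # only the 3-pixel can pass (and it clears its local mean)
        img = np.ones((4, 4))
        img[2, 2] = 3.0
        mask = threshold_seg1(img, SegmentationParams(local_kernel_diameter=3))
        assert mask.sum() == 1 and mask[2, 2]

    def test_matches_per_pixel_brute_force(self, rng):
        img = 0.1 * rng.random((36, 40))
        img[10:22, 12:26] += 0.8
        diameter = 15
        params = SegmentationParams(local_kernel_diameter=diameter)
        mask = threshold_seg1(img, params)
        foot = disk(diameter // 2).astype(bool)
        r = foot.shape[0] // 2
        padded = np.pad(img, r, mode="reflect")
        global_thr = params.global_factor * np.median(img)
        expect = np.zeros_like(img, bool)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                local = padded[i : i + 2 * r + 1, j : j + 2 * r + 1][foot].mean()
                expect[i, j] = (img[i, j] > global_thr) and (img[i, j] > local)
        assert np.array_equal(mask, expect)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            threshold_seg1(np.ones((20, 20)), SegmentationParams(local_kernel_diameter=120))


class TestCellsSeg2:
    def test_empty_mask_yields_zero_objects(self):
        assert cells_seg2(np.zeros((50, 50), bool)).max() == 0

    def test_area_filter_keeps_large_and_drops_small(self):
        mask = np.zeros((140, 260), bool)
        mask[20:80, 20:110] = True    # 60x90: still > 3500 after net erosion
        mask[20:60, 150:200] = True   # 40x50: shrinks well below 3500
        labels = cells_seg2(mask)
        assert labels.max() == 1
        assert labels[50, 60] > 0 and labels[40, 170] == 0

    def test_matches_reference_morphology(self, rng):
        from skimage.morphology import dilation as sk_dil
        from skimage.morphology import erosion as sk_ero

        # keep blobs away from the border so the comparison exercises the
        # morphology itself rather than out-of-canvas border policy
        interior = ndi.binary_dilation(rng.random((50, 50)) > 0.99, iterations=6)
        mask = np.pad(interior, 15)
        params = SegmentationParams(min_area=10)
        cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
        pad = params.dilate_fill + params.erode_fill + 2
        ref = np.pad(mask, pad)
        for _ in range(params.dilate_fill):
            ref = sk_dil(ref, cross)
        for _ in range(params.erode_fill):
            ref = sk_ero(ref, cross)
        ref = ref[pad:-pad, pad:-pad]
        ours = cells_seg2(mask, params) > 0
        ref_labels, n = ndi.label(ref, structure=np.ones((3, 3)))
        areas = ndi.sum_labels(np.ones_like(ref_labels), ref_labels, np.arange(1, n + 1))
        keep = np.isin(ref_labels, np.flatnonzero(areas >= params.min_area) + 1)
        assert np.array_equal(ours, keep)

    def test_object_count_monotone_in_min_area(self, rng):
        truth = synth_microscopy(seed=4)
        base = segment_image(truth.cell_channel).seg1
        counts = [
            cells_seg2(base, SegmentationParams(min_area=a)).max()
            for a in (500, 2000, 3500, 8000, 20000)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestNeighborhoodSeg3:
    def test_empty_input_empty_output(self):
        assert not neighborhood_seg3(np.zeros((40, 40), bool)).any()

    def test_disc_neighborhood_is_an_annulus(self):
        r = 30
        mask = np.zeros((200, 200), bool)
        mask[disk(r).nonzero()[0] + 70, disk(r).nonzero()[1] + 70] = True
        params = SegmentationParams()
        nbr = neighborhood_seg3(mask, params)
        inner, outer = r + params.boundary_dilate, r + params.neighborhood_dilate
        analytic = np.pi * (outer**2 - inner**2)
        assert nbr.sum() == pytest.approx(analytic, rel=0.05)

    def test_disjoint_from_boundary_dilation(self, rng):
        mask = rng.random((60, 60)) > 0.98
        params = SegmentationParams()
        nbr = neighborhood_seg3(mask, params)
        boundary = ndi.binary_dilation(mask, structure=disk(params.boundary_dilate))
        assert not (nbr & boundary).any()


class TestRelativeIntensity:
    def test_uniform_signal_is_unity(self):
        organ = np.ones((20, 20), bool)
        region = np.zeros((20, 20), bool)
        region[5:10, 5:10] = True
        assert relative_intensity(np.full((20, 20), 3.3), region, organ) == pytest.approx(1.0)

    def test_direct_ratio(self):
        signal = np.full((10, 10), 10.0)
        region = np.zeros((10, 10), bool)
        region[:5] = True
        signal[region] = 20.0
        organ = np.ones((10, 10), bool)
        assert relative_intensity(signal, region, organ) == pytest.approx(2.0)

    def test_empty_denominator_rejected(self):
        organ = np.zeros((5, 5), bool)
        region = np.ones((5, 5), bool)
        with pytest.raises(ValueError):
            relative_intensity(np.ones((5, 5)), region, organ)

    def test_recovers_planted_enrichment(self):
        truth = synth_microscopy(seed=0, enrichment=3.0)
        bundle = segment_image(truth.cell_channel)
        signal = normalize_channel(truth.signal_channel).pixels
        ratio = relative_intensity(signal, bundle.seg2 > 0, truth.organ_mask)
        assert 2.7 <= ratio <= 3.3


class TestPipelineInvariances:
    def test_masks_invariant_to_affine_intensity_changes(self):
        truth = synth_microscopy(seed=2)
        a = segment_image(truth.cell_channel)
        b = segment_image(5.0 * truth.cell_channel + 13.0)
        assert np.array_equal(a.seg1, b.seg1)
        assert np.array_equal(a.seg2, b.seg2)
        assert np.array_equal(a.seg3, b.seg3)

    def test_segmentation_params_validation(self):
        with pytest.raises(ValueError):
            SegmentationParams(erode_fill=3, dilate_fill=5)
        with pytest.raises(ValueError):
            SegmentationParams(sigma=-1)
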