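"""Histogram, threshold, grey-band, misclassification and edge operators."""

import numpy as np
import pytest

from canopyhp import (
    CameraConfig,
    binarize,
    edge_response_distance,
    gap_fraction_at_threshold,
    grey_pixel_bounds,
    greyness_histogram,
    misclassification_map,
    mpz_sobel,
    simulate_photograph,
)
from canopyhp.camera import Photograph, circular_mask
from canopyhp.image_analysis import BinaryMap, GreynessHistogram
from canopyhp.model_canopy import LABEL_CANOPY, LABEL_GREY, LABEL_SKY


def _photo_from_dn(dn: np.ndarray) -> Photograph:
    dn = np.asarray(dn, dtype=np.uint8)
    return Photograph(
        dn=dn,
        mask=np.ones(dn.shape, dtype=bool),
        exposure=0.0,
        blur_sigma=0.0,
        config=CameraConfig(),
    )


class TestHistogram:
    def test_uniform_image_single_bin(self):
        hist = greyness_histogram(_photo_from_dn(np.full((20, 20), 200)))
        assert hist.counts[200] == 400
        assert hist.total == 400

    def test_two_valued_image(self):
        dn = np.zeros((10, 10), dtype=np.uint8)
        dn[:5] = 255
        hist = greyness_histogram(_photo_from_dn(dn))
        assert hist.counts[0] == 50 and hist.counts[255] == 50
        assert (hist.counts[1:255] == 0).all()

    def test_bimodal_histogram_of_blurred_canopy(self, reference_photo):
        hist = greyness_histogram(reference_photo)
        counts = hist.counts
        canopy_peak = counts[:60].max()
        sky_peak = counts[100:].max()
        bridge = counts[40:100].max()
        assert canopy_peak > 10 * bridge
        assert sky_peak > 10 * bridge
        assert counts[25:120].sum() > 0  # grey pixels exist between humps

    def test_empty_mask_rejected(self):
        photo = _photo_from_dn(np.zeros((4, 4)))
        photo.mask[:] = False
        with pytest.raises(ValueError):
            greyness_histogram(photo)


class TestGapFractionCurve:
    def test_threshold_zero_gives_unity(self, reference_photo):
        hist = greyness_histogram(reference_photo)
        assert gap_fraction_at_threshold(hist, 0) == 1.0

    def test_two_valued_fraction(self):
        dn = np.zeros((10, 10), dtype=np.uint8)
        dn.flat[:40] = 255
        hist = greyness_histogram(_photo_from_dn(dn))
        assert gap_fraction_at_threshold(hist, 128) == pytest.approx(0.40)
        assert gap_fraction_at_threshold(hist, 255) == pytest.approx(0.40)

    def test_curve_is_non_increasing(self, reference_photo):
        curve = greyness_histogram(reference_photo).gap_fraction_curve()
        assert (np.diff(curve) <= 0).all()
        assert curve[0] == 1.0

    def test_out_of_range_threshold(self, reference_photo):
        hist = greyness_histogram(reference_photo)
        with pytest.raises(ValueError):
            gap_fraction_at_threshold(hist, 256)


class TestGreyPixelBounds:
    def _hist(self, counts: dict) -> GreynessHistogram:
        vector = np.zeros(256, dtype=np.int64)
        for dn, count in counts.items():
            vector[dn] = count
        return GreynessHistogram(vector)

    def test_two_delta_histogram_has_no_grey(self):
        hist = self._hist({0: 5000, 255: 5000})
        for method in ("amplitude", "peak"):
            summary = grey_pixel_bounds(hist, method=method)
            assert summary.grey_fraction == 0.0

    def test_flat_bridge_mass_recovered(self):
        # humps at 10 and 245 with a low flat bridge carrying 12% of pixels
        total_bridge = 0.12
        n = 1_000_000
        bridge_bins = np.arange(11, 245)
        counts = {10: int(n * 0.44), 245: int(n * 0.44)}
        per_bin = int(n * total_bridge / len(bridge_bins))
        for dn in bridge_bins:
            counts[dn] = per_bin
        hist = self._hist(counts)
        for method in ("amplitude", "peak"):
            summary = grey_pixel_bounds(hist, method=method)
            assert summary.grey_fraction == pytest.approx(0.12, rel=0.15)

    def test_uniform_histogram_has_zero_grey(self):
        summary = grey_pixel_bounds(self._hist({200: 999}))
        assert summary.grey_fraction == 0.0

    def test_saturated_histogram_collapses_low_bound(self):
        # one sky hump only: the low bound collapses to the histogram edge
        summary = grey_pixel_bounds(self._hist({255: 10_000, 250: 30}))
        assert summary.t_low == 0
        assert summary.sky_hump == 255

    def test_explicit_bounds_override(self, reference_photo):
        hist = greyness_histogram(reference_photo)
        summary = grey_pixel_bounds(hist, bounds=(20, 120))
        assert (summary.t_low, summary.t_high) == (20, 120)
        assert summary.grey_fraction == pytest.approx(
            hist.counts[21:120].sum() / hist.total
        )

    def test_grey_fraction_increases_with_blur(self, fig6_scene):
        fractions = []
        for sigma in (0.5, 1.0, 2.0, 3.0):
            photo = simulate_photograph(fig6_scene, 0.0, CameraConfig(blur_sigma=sigma))
            summary = grey_pixel_bounds(greyness_histogram(photo))
            fractions.append(summary.grey_fraction)
        assert all(b > a for a, b in zip(fractions, fractions[1:]))

    def test_invalid_alpha(self, reference_photo):
        hist = greyness_histogram(reference_photo)
        with pytest.raises(ValueError):
            grey_pixel_bounds(hist, alpha=1.5)


class TestBinarize:
    def test_threshold_extremes(self, reference_photo):
        assert binarize(reference_photo, 0).gap_fraction == 1.0
        only_saturated = binarize(reference_photo, 255)
        assert only_saturated.gap_fraction == pytest.approx(
            (reference_photo.masked_dn == 255).mean()
        )
        with pytest.raises(ValueError):
            binarize(reference_photo, 256)

    def test_consistent_with_histogram_route(self, reference_photo):
        hist = greyness_histogram(reference_photo)
        for threshold in (10, 60, 128, 200):
            assert binarize(reference_photo, threshold).gap_fraction == (
                gap_fraction_at_threshold(hist, threshold)
            )


class TestMisclassification:
    def _setup(self):
        labels = np.full((8, 8), LABEL_CANOPY, dtype=np.uint8)
        labels[:, 4:] = LABEL_SKY
        labels[:, 3:5] = LABEL_GREY
        mask = np.ones((8, 8), dtype=bool)
        # the matched reference classifies both grey columns as canopy
        reference = BinaryMap(sky=labels == LABEL_SKY, mask=mask, threshold=100)
        return labels, mask, reference

    def test_identical_maps_have_zero_misclassified(self):
        labels, mask, reference = self._setup()
        audit = misclassification_map(reference, labels, reference)
        assert audit.n_misclassified == 0

    def test_categories_partition_the_mask(self):
        labels, mask, reference = self._setup()
        shifted = BinaryMap(sky=np.roll(reference.sky, 1, axis=1), mask=mask, threshold=90)
        audit = misclassification_map(shifted, labels, reference)
        assert sum(audit.counts.values()) == int(mask.sum())

    def test_grey_pixels_judged_against_reference(self):
        labels, mask, reference = self._setup()
        # flip one grey column to sky relative to the matched reference
        sky = reference.sky.copy()
        sky[:, 4] = True
        audit = misclassification_map(
            BinaryMap(sky=sky, mask=mask, threshold=90), labels, reference
        )
        assert audit.counts["false_sky"] == 8
        assert audit.counts["false_canopy"] == 0

    def test_geometry_mismatch_rejected(self):
        labels, mask, reference = self._setup()
        other = BinaryMap(
            sky=np.zeros((4, 4), dtype=bool),
            mask=np.ones((4, 4), dtype=bool),
            threshold=1,
        )
        with pytest.raises(ValueError):
            misclassification_map(other, labels, reference)

    def test_rgb_colour_code(self):
        labels, mask, reference = self._setup()
        audit = misclassification_map(reference, labels, reference)
        rgb = audit.to_rgb()
        assert rgb.shape == (8, 8, 3)
        # correct sky is white, correct canopy black
        assert (rgb[0, 7] == [255, 255, 255]).all()
        assert (rgb[0, 0] == [0, 0, 0]).all()


def _bruteforce_sobel_edges(img: np.ndarray) -> np.ndarray:
    """Independent 3x3 Sobel with replicated borders, plain loops."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = kx.T
    rows, cols = img.shape
    padded = np.pad(img.astype(float), 1, mode="edge")
    out = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            window = padded[r : r + 3, c : c + 3]
            gx = float((window * kx).sum())
            gy = float((window * ky).sum())
            out[r, c] = (gx * gx + gy * gy) > 1e-18
    return out


class TestMPZ:
    def test_uniform_map_has_no_edges(self):
        bmap = BinaryMap(
            sky=np.ones((16, 16), dtype=bool),
            mask=np.ones((16, 16), dtype=bool),
            threshold=1,
        )
        assert mpz_sobel(bmap).mpz_fraction == 0.0

    def test_vertical_step_flanked_by_two_columns(self):
        sky = np.zeros((16, 16), dtype=bool)
        sky[:, 8:] = True
        bmap = BinaryMap(sky=sky, mask=np.ones((16, 16), dtype=bool), threshold=1)
        result = mpz_sobel(bmap)
        expected = np.zeros((16, 16), dtype=bool)
        expected[:, 7:9] = True
        assert (result.edge_mask == expected).all()
        assert result.mpz_fraction == pytest.approx(2 / 16)

    def test_matches_bruteforce_oracle_on_random_maps(self):
        rng = np.random.default_rng(20260923)
        for _ in range(200):
            img = rng.random((16, 16)) < rng.uniform(0.2, 0.8)
            bmap = BinaryMap(
                sky=img, mask=np.ones((16, 16), dtype=bool), threshold=128
            )
            assert (mpz_sobel(bmap).edge_mask == _bruteforce_sobel_edges(img)).all()

    def test_mpz_tracks_border_length_through_origin(self, experiment_result):
        # over the rendered suite the MPZ fraction is linear in the border
        # length per unit area with zero intercept
        from canopyhp.stats import origin_r2, zero_intercept_slope

        records = experiment_result.records
        ref = records[(records.exposure == 0.0) & (records.etm == 0.0)]
        b = ref.scb_per_area_measured.to_numpy()
        mpz = ref.mpz_fraction.to_numpy()
        assert origin_r2(b, mpz) > 0.99
        # two flanking pixels per border crossing: slope ~ 2 px * pixel scale
        slope = zero_intercept_slope(b, mpz)
        pixel_scale = experiment_result.config.pixel_scale
        assert slope == pytest.approx(2.0 * pixel_scale, rel=0.25)


class TestSharpness:
    def test_unblurred_step_has_subpixel_rise(self, step_scene):
        cfg = CameraConfig(gamma=1.0, sky_dn_at_reference=250.0, blur_sigma=0.0)
        photo = simulate_photograph(step_scene, 0.0, cfg)
        assert edge_response_distance(photo).rise_distance <= 1.0

    @pytest.mark.parametrize("sigma", [2.0, 3.0, 4.0])
    def test_gaussian_blur_rise_distance(self, step_scene, sigma):
        cfg = CameraConfig(gamma=1.0, sky_dn_at_reference=250.0, blur_sigma=sigma)
        photo = simulate_photograph(step_scene, 0.0, cfg)
        estimate = edge_response_distance(photo)
        assert estimate.rise_distance == pytest.approx(2.5631 * sigma, rel=0.02)
        assert estimate.sharpness == pytest.approx(1 / (2.5631 * sigma), rel=0.02)

    def test_doubling_blur_doubles_rise(self, step_scene):
        cfg2 = CameraConfig(gamma=1.0, sky_dn_at_reference=250.0, blur_sigma=2.0)
        cfg4 = CameraConfig(gamma=1.0, sky_dn_at_reference=250.0, blur_sigma=4.0)
        rise2 = edge_response_distance(simulate_photograph(step_scene, 0.0, cfg2))
        rise4 = edge_response_distance(simulate_photograph(step_scene, 0.0, cfg4))
        assert rise4.rise_distance / rise2.rise_distance == pytest.approx(2.0, rel=0.05)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError):
            edge_response_distance(np.full((8, 32), 100, dtype=np.uint8))
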