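"""Quality-control indices: sticky cards, exoskeleton density, image counts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from whiteflysim.qc import (
    CARD_AREA_SQIN_DEFAULT,
    PUNCH_RADIUS_IN,
    CountImage,
    ExoskeletonField,
    InsufficientCountError,
    StickyCardObservation,
    calibrate_count,
    count_whiteflies,
    exoskeleton_density,
    leaf_area_from_mask,
    sticky_index,
)
from whiteflysim.synth import SyntheticImageConfig, generate_count_image


class TestStickyIndex:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, 0.0), (11, 0.2957), (1, 0.02688)],  # observed weekly range 1-11
    )
    def test_standard_card_rates(self, count, expected):
        obs = StickyCardObservation(count=count)  # 16 cm^2 card, 15 min
        assert sticky_index(obs) == pytest.approx(expected, abs=5e-5)

    def test_card_area_conversion(self):
        assert CARD_AREA_SQIN_DEFAULT == pytest.approx(16.0 / 6.4516)

    @given(
        st.integers(0, 500),
        st.floats(0.5, 10.0),
        st.floats(1.0, 120.0),
    )
    def test_linearity_and_inverse_proportionality(self, count, area, duration):
        base = sticky_index(StickyCardObservation(count, area, duration))
        assert sticky_index(
            StickyCardObservation(2 * count, area, duration)
        ) == pytest.approx(2 * base)
        assert sticky_index(
            StickyCardObservation(count, 2 * area, duration)
        ) == pytest.approx(base / 2)
        assert sticky_index(
            StickyCardObservation(count, area, 2 * duration)
        ) == pytest.approx(base / 2)

    def test_invalid_observation(self):
        with pytest.raises(ValueError):
            StickyCardObservation(-1)
        with pytest.raises(ValueError):
            StickyCardObservation(1, card_area_sqin=0.0)


class TestExoskeletonDensity:
    def test_stops_at_initial_punch_radius_when_enough(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.3, 0.3, size=(40, 2))  # all inside punch radius
        r, dens = exoskeleton_density(ExoskeletonField(points=pts))
        assert r == pytest.approx(PUNCH_RADIUS_IN)
        assert dens == pytest.approx(40 / (math.pi * PUNCH_RADIUS_IN**2))

    def test_twenty_four_points_insufficient(self):
        pts = np.zeros((24, 2))
        with pytest.raises(InsufficientCountError) as exc:
            exoskeleton_density(ExoskeletonField(points=pts))
        assert exc.value.best_density > 0

    def test_poisson_field_estimator_consistency(self):
        """Mean density over 200 seeded homogeneous fields of intensity 30
        per sq.in. lands within 10% of the truth."""
        rng = np.random.default_rng(2026)
        intensity, R = 30.0, 2.0
        densities = []
        for _ in range(200):
            n = rng.poisson(intensity * math.pi * R * R)
            rr = R * np.sqrt(rng.uniform(size=n))
            th = rng.uniform(0, 2 * math.pi, size=n)
            pts = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
            _, d = exoskeleton_density(ExoskeletonField(points=pts, max_radius=R))
            densities.append(d)
        assert np.mean(densities) == pytest.approx(intensity, rel=0.10)

    def test_radius_non_increasing_as_min_count_drops(self):
        rng = np.random.default_rng(5)
        rr = 1.5 * np.sqrt(rng.uniform(size=60))
        th = rng.uniform(0, 2 * math.pi, size=60)
        pts = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        field = ExoskeletonField(points=pts, max_radius=1.6)
        radii = [
            exoskeleton_density(field, min_count=mc)[0] for mc in (50, 40, 25, 10, 1)
        ]
        assert all(b <= a for a, b in zip(radii, radii[1:]))


class TestCountWhiteflies:
    def test_blank_image_counts_zero_with_warning(self):
        img = CountImage(pixels=np.zeros((64, 64), dtype=np.uint8))
        with pytest.warns(UserWarning, match="blank"):
            assert count_whiteflies(img, threshold=128) == 0

    def test_saturated_image_counts_zero(self):
        img = CountImage(pixels=np.full((64, 64), 255, dtype=np.uint8))
        with pytest.warns(UserWarning, match="saturated"):
            assert count_whiteflies(img, threshold=128) == 0

    def test_recovers_exact_count_at_zero_overlap(self):
        img, truth, _ = generate_count_image(
            SyntheticImageConfig(seed=3, n_blobs=500, shape=(1024, 1024))
        )
        assert count_whiteflies(img, threshold=100) == truth == 500

    def test_near_touching_pairs_within_few_percent(self):
        """5% of blobs placed as near-touching pairs: the automated count
        may merge some pairs but must stay within a few percent of truth."""
        img, truth, _ = generate_count_image(
            SyntheticImageConfig(
                seed=4, n_blobs=400, shape=(1024, 1024), overlap_fraction=0.05
            )
        )
        auto = count_whiteflies(img, threshold=100)
        assert abs(auto - truth) / truth <= 0.05

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        img = np.zeros((128, 128), dtype=np.uint8)
        for _ in range(10):
            y, x = rng.integers(10, 80, size=2)
            img[y : y + 3, x : x + 3] = 200
        n0 = count_whiteflies(CountImage(pixels=img), threshold=100)
        shifted = np.roll(np.roll(img, 20, axis=0), 20, axis=1)
        n1 = count_whiteflies(CountImage(pixels=shifted), threshold=100)
        assert n0 == n1

    def test_uniform_offset_below_threshold_invariance(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[10:14, 10:14] = 200
        img[30:34, 30:34] = 200
        n0 = count_whiteflies(CountImage(pixels=img), threshold=128)
        lifted = np.where(img == 0, 40, img).astype(np.uint8)  # offset stays below 128
        n1 = count_whiteflies(CountImage(pixels=lifted), threshold=128)
        assert n0 == n1 == 2

    def test_min_blob_filter_drops_specks(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[5, 5] = 200  # 1-px speck
        img[20:24, 20:24] = 200  # real blob
        assert count_whiteflies(CountImage(pixels=img), 128, min_blob_px=4) == 1

    def test_invalid_threshold(self):
        img = CountImage(pixels=np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            count_whiteflies(img, threshold=300)


class TestCalibrateCount:
    def test_synthetic_quadrant_truth_passes(self):
        img, _, quadrant_truth = generate_count_image(
            SyntheticImageConfig(seed=6, n_blobs=300, shape=(1024, 1024))
        )
        report = calibrate_count(img, threshold=100)
        assert report["manual"] == quadrant_truth
        assert report["relative_error"] == 0.0
        assert report["passed"]

    def test_six_percent_error_fails_default_tolerance(self):
        img = np.zeros((100, 100), dtype=np.uint8)
        # 53 isolated blobs in the quadrant, manual count claims 50
        k = 0
        for y in range(5, 95, 12):
            for x in range(5, 95, 12):
                if k < 53:
                    img[y : y + 2, x : x + 2] = 200
                    k += 1
        ci = CountImage(pixels=img, quadrant=(0, 100, 0, 100), manual_count=50)
        report = calibrate_count(ci, threshold=128)
        assert report["automated"] == 53
        assert report["relative_error"] == pytest.approx(0.06)
        assert not report["passed"]

    def test_zero_manual_count_flagged_undefined(self):
        ci = CountImage(
            pixels=np.zeros((32, 32), dtype=np.uint8),
            quadrant=(0, 16, 0, 16),
            manual_count=0,
        )
        with pytest.warns(UserWarning):
            report = calibrate_count(ci, threshold=128)
        assert report["undefined"] and math.isnan(report["relative_error"])

    def test_missing_quadrant_rejected(self):
        ci = CountImage(pixels=np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(ValueError):
            calibrate_count(ci, threshold=128)


def test_leaf_area_from_mask_scales_with_pixel_size():
    mask = np.zeros((100, 100), dtype=bool)
    mask[:50, :] = True  # 5000 px
    assert leaf_area_from_mask(mask, 0.01) == pytest.approx(5000 * 1e-4)
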