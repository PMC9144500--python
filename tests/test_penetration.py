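"""Penetration read-outs: dye mask, surface, ART, depth, SCT, TEWL QC."""

import numpy as np
import pytest

from dermaquant import (
    Micrograph,
    compute_art,
    compute_depth,
    detect_surface,
    make_skin_section,
    measure_sct,
    qc_tewl,
    relative_sct,
    rgb_threshold,
)

from conftest import SMALL_SHAPE, rgb


class TestRgbThreshold:
    def test_strong_pure_green_passes(self):
        assert rgb_threshold(rgb(10, 200, 10)).all()

    def test_achromatic_autofluorescence_rejected(self):
        assert not rgb_threshold(rgb(200, 200, 200)).any()

    @pytest.mark.parametrize(
        "r,g,b,expected",
        [
            (0, 50, 30, True),  # exactly g_min and margin met
            (0, 49, 0, False),  # below g_min
            (31, 50, 0, False),  # margin 19 < 20
            (0, 255, 236, False),  # blue too close to green
        ],
    )
    def test_boundaries(self, r, g, b, expected):
        assert bool(rgb_threshold(rgb(r, g, b)).all()) is expected

    def test_grey_input_rejected(self):
        grey = Micrograph(np.zeros((4, 4), dtype=np.uint8), scale=1.0)
        with pytest.raises(ValueError, match="RGB"):
            rgb_threshold(grey)


class TestDetectSurface:
    def test_recovers_known_surface_row(self):
        img, truth = make_skin_section("control_groupI", 13, size=SMALL_SHAPE)
        surface = detect_surface(img)
        hits = np.abs(surface - truth.surface_row) <= 2
        assert hits.mean() >= 0.95

    def test_translation_equivariance(self):
        img, _ = make_skin_section("control_groupI", 14, size=SMALL_SHAPE,
                                   noise=False)
        before = detect_surface(img)
        shift = 50
        shifted = np.vstack([np.full((shift, img.pixels.shape[1], 3), 8,
                                     dtype=np.uint8),
                             img.pixels])[: img.pixels.shape[0]]
        after = detect_surface(Micrograph(shifted, scale=img.scale))
        assert np.median(after - before) == pytest.approx(shift, abs=1)

    def test_pure_background_raises(self):
        flat = Micrograph(np.full((64, 64, 3), 8, dtype=np.uint8), scale=1.0)
        with pytest.raises(ValueError, match="no tissue"):
            detect_surface(flat)


class TestArt:
    def test_partial_mask_counts_roi_zeros(self):
        """2 masked px (green 100, 200) over a 10-px ROI → 30 MGV/px."""
        px = np.zeros((1, 10, 3), dtype=np.uint8)
        px[0, 0, 1], px[0, 1, 1] = 100, 200
        img = Micrograph(px, scale=1.0)
        mask = np.zeros((1, 10), dtype=bool)
        mask[0, :2] = True
        roi = np.ones((1, 10), dtype=bool)
        assert compute_art(img, mask, roi) == pytest.approx(30.0)

    def test_empty_mask_is_zero(self):
        img = rgb(0, 120, 0, shape=(4, 4))
        zeros = np.zeros((4, 4), dtype=bool)
        assert compute_art(img, zeros, ~zeros) == 0.0

    def test_fully_masked_uniform_green(self):
        img = rgb(0, 50, 0, shape=(4, 4))
        ones = np.ones((4, 4), dtype=bool)
        assert compute_art(img, ones, ones) == pytest.approx(50.0)

    def test_empty_roi_rejected(self):
        img = rgb(0, 50, 0, shape=(4, 4))
        zeros = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="ROI"):
            compute_art(img, zeros, zeros)


class TestDepth:
    def test_depth_arithmetic_at_skin_scale(self):
        """Surface at row 10, deepest mask at row 294, 2.84 px/µm → 100 µm."""
        mask = np.zeros((300, 4), dtype=bool)
        mask[290:295, :] = True
        surface = np.full(4, 10, dtype=np.intp)
        assert compute_depth(mask, surface, scale=2.84) == pytest.approx(100.0)

    def test_empty_mask_depth_zero(self):
        mask = np.zeros((20, 4), dtype=bool)
        assert compute_depth(mask, np.zeros(4, dtype=np.intp), scale=1.0) == 0.0

    def test_isolated_speck_despeckled(self):
        mask = np.zeros((600, 8), dtype=bool)
        mask[0:143, :] = True  # true signal to 50 µm at 2.84 px/µm
        mask[568, 3] = True  # lone 1-px speck at 200 µm
        surface = np.zeros(8, dtype=np.intp)
        assert compute_depth(mask, surface, scale=2.84) == pytest.approx(50.0, abs=0.5)

    def test_percentile_mode(self):
        mask = np.zeros((100, 4), dtype=bool)
        mask[:50, :] = True
        surface = np.zeros(4, dtype=np.intp)
        p50 = compute_depth(mask, surface, 1.0, mode="percentile", percentile=50)
        assert p50 == pytest.approx(24.5, abs=1.0)
        with pytest.raises(ValueError, match="mode"):
            compute_depth(mask, surface, 1.0, mode="median")


def _banded_image(surface_row=20, band_px=28, h=512, w=64):
    """Background, bright 28-px SC band, dim tissue below."""
    px = np.zeros((h, w, 3), dtype=np.uint8)
    px[:surface_row] = 8
    px[surface_row:] = (36, 20, 40)
    px[surface_row : surface_row + band_px] = (110, 90, 90)
    return Micrograph(px, scale=2.84)


class TestSct:
    def test_known_band_thickness(self):
        img = _banded_image(band_px=28)
        surface = np.full(64, 20, dtype=np.intp)
        assert measure_sct(img, surface, scale=2.84) == pytest.approx(28 / 2.84,
                                                                      abs=0.4)

    def test_sct_factor_ratio_recovered(self):
        """sct_factor 110 vs 100 presets → measured ratio ≈ 1.10."""
        ratios = []
        for seed in range(6):
            vals = {}
            for name in ("control_groupI", "glycerol_control"):
                img, _ = make_skin_section(name, 500 + seed, size=SMALL_SHAPE,
                                           jitter=False)
                vals[name] = measure_sct(img, detect_surface(img), img.scale)
            ratios.append(vals["glycerol_control"] / vals["control_groupI"])
        assert np.mean(ratios) == pytest.approx(1.10, abs=0.02)

    def test_no_band_rejected(self):
        img = Micrograph(np.full((128, 16, 3), 30, dtype=np.uint8), scale=1.0)
        with pytest.raises(ValueError, match="stratum corneum"):
            measure_sct(img, np.full(16, 10, dtype=np.intp), scale=1.0)


class TestRelativeSct:
    def test_control_vs_itself_is_100(self):
        assert relative_sct([40.0, 41.0], [40.0, 41.0]) == pytest.approx(100.0)

    @pytest.mark.parametrize("treated,control,expected",
                             [([46.0], [40.0], 115.0), ([44.0], [40.0], 110.0)])
    def test_arithmetic(self, treated, control, expected):
        assert relative_sct(treated, control) == pytest.approx(expected)

    def test_empty_or_zero_control_rejected(self):
        with pytest.raises(ValueError):
            relative_sct([], [40.0])
        with pytest.raises(ValueError):
            relative_sct([40.0], [0.0])


class TestTewl:
    @pytest.mark.parametrize("tewl,expected",
                             [(16.0, "exclude"), (15.0, "include"), (0.0, "include")])
    def test_strictly_greater_than_15_excludes(self, tewl, expected):
        assert qc_tewl(tewl) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            qc_tewl(-1.0)


class TestDepthTranslationInvariance:
    def test_depth_referenced_to_surface(self):
        """Whole-section vertical shift leaves the measured depth unchanged."""
        img, _ = make_skin_section("control_groupI", 77, size=SMALL_SHAPE,
                                   noise=False)
        surface = detect_surface(img)
        mask = rgb_threshold(img)
        d0 = compute_depth(mask, surface, img.scale)
        shift = 30
        shifted_px = np.vstack([np.full((shift, img.pixels.shape[1], 3), 8,
                                        dtype=np.uint8), img.pixels])[:img.pixels.shape[0]]
        shifted = Micrograph(shifted_px, scale=img.scale)
        d1 = compute_depth(rgb_threshold(shifted), detect_surface(shifted),
                           shifted.scale)
        assert d1 == pytest.approx(d0, abs=1.0)
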