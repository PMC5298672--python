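"""Image→spectrum extraction: ROI detection, resampling, gap filling."""

import math

import numpy as np
import pytest

from phylis.errors import AllGaps, AmbiguousRegion, NoRegionFound, OutOfRange, TooFewColumns
from phylis.image_extraction import (
    N_POINTS,
    RawSpectrum,
    RegionOfInterest,
    detect_roi,
    extract_column_means,
    extract_spectrum,
    fill_gaps,
    position_to_wavelength,
    resample_to_scale,
)
from phylis.synthetic_data import RenderSpec, make_class_curve, render_photograph


@pytest.fixture(scope="module")
def curve():
    return make_class_curve(np.random.default_rng(42))


class TestDetectRoi:
    def test_recovers_rendered_circle_geometry(self, curve):
        spec = RenderSpec(center_offset=(12.0, -8.0), radius=460.0)
        img = render_photograph(curve, spec, seed=1)
        roi = detect_roi(img)
        cx, cy = spec.center
        assert abs(roi.center_x - cx) <= 2
        assert abs(roi.center_y - cy) <= 2
        assert abs(roi.radius - spec.radius) <= 2

    def test_all_black_image_raises(self):
        img = np.zeros((100, 120, 3), dtype=np.uint8)
        with pytest.raises(NoRegionFound):
            detect_roi(img)

    def test_two_equal_regions_are_ambiguous(self):
        img = np.zeros((100, 200, 3), dtype=np.uint8)
        img[20:60, 10:50] = 200    # 1600 px
        img[20:60, 120:160] = 200  # 1600 px
        with pytest.raises(AmbiguousRegion):
            detect_roi(img)

    def test_band_box_tracks_circle_translation(self, curve):
        """Shifting the aperture must shift the band with it: same spectrum."""
        a = render_photograph(curve, RenderSpec(center_offset=(0, 0), noise_sd=0), seed=2)
        b = render_photograph(curve, RenderSpec(center_offset=(15, 0), noise_sd=0), seed=2)
        sa = extract_spectrum(a).values
        sb = extract_spectrum(b).values
        rms = np.sqrt(np.mean((sa - sb) ** 2))
        assert rms < 0.01 * (sa.max() - sa.min())


class TestColumnMeans:
    def _roi(self, left, top, right, bottom):
        return RegionOfInterest(center_x=0, center_y=0, radius=1,
                                band_box=(left, top, right, bottom))

    def test_saturated_column_gives_765(self):
        img = np.full((4, 3, 3), 255, dtype=np.uint8)
        cols = extract_column_means(img, self._roi(0, 0, 3, 4))
        assert all(v == 765 for _, v in cols)

    def test_mean_over_band_rows(self):
        img = np.zeros((2, 1, 3), dtype=np.uint8)
        img[0, 0] = (100, 0, 0)
        img[1, 0] = (0, 100, 0)
        (_, v), = extract_column_means(img, self._roi(0, 0, 1, 2))
        assert v == 100

    def test_values_bounded(self, curve):
        img = render_photograph(curve, seed=3)
        roi = detect_roi(img)
        vals = np.array([v for _, v in extract_column_means(img, roi)])
        assert np.all(vals >= 0) and np.all(vals <= 765)

    def test_round_trip_against_generator_curve(self, curve):
        spec = RenderSpec(noise_sd=0.5)
        img = render_photograph(curve, spec, seed=4)
        roi = detect_roi(img)
        cols = np.array([v for _, v in extract_column_means(img, roi)])
        n = len(cols)
        scale_pos = 1 + np.arange(n) * (N_POINTS - 1) / (n - 1)
        truth = np.interp(scale_pos, np.arange(1, N_POINTS + 1), curve) * 765
        assert np.max(np.abs(cols - truth)) <= 2.0


class TestResample:
    def test_matching_width_has_no_gaps(self):
        cols = [(i, float(i)) for i in range(1000)]
        raw = resample_to_scale(cols)
        assert not raw.gap_mask.any()
        np.testing.assert_allclose(raw.values, np.arange(1000.0))

    def test_750_columns_leave_250_isolated_gaps(self):
        # independent brute-force oracle: round-half-up mapping for N=750
        occupied = {math.floor(1 + (i - 1) * 999 / 749 + 0.5) for i in range(1, 751)}
        expected_gaps = sorted(set(range(1, 1001)) - occupied)
        assert len(expected_gaps) == 250
        assert all(b - a > 1 for a, b in zip(expected_gaps, expected_gaps[1:]))

        raw = resample_to_scale([(i, 1.0) for i in range(750)])
        got_gaps = (np.flatnonzero(raw.gap_mask) + 1).tolist()
        assert got_gaps == expected_gaps

    def test_two_columns_map_to_endpoints(self):
        raw = resample_to_scale([(0, 5.0), (1, 9.0)])
        assert raw.values[0] == 5.0 and raw.values[-1] == 9.0
        assert raw.gap_mask.sum() == 998

    def test_single_column_rejected(self):
        with pytest.raises(TooFewColumns):
            resample_to_scale([(0, 1.0)])


class TestFillGaps:
    def test_single_gap_gets_neighbour_mean(self):
        values = np.full(1000, np.nan)
        mask = np.ones(1000, dtype=bool)
        values[499], values[501] = 10.0, 20.0
        mask[499] = mask[501] = False
        out = fill_gaps(RawSpectrum(values=values, gap_mask=mask))
        assert out.values[500] == 15.0

    def test_no_gaps_is_identity(self):
        values = np.random.default_rng(0).random(1000)
        out = fill_gaps(RawSpectrum(values=values, gap_mask=np.zeros(1000, bool)))
        np.testing.assert_array_equal(out.values, values)

    def test_linear_ramp_reconstructed_through_resampling(self):
        ramp = np.linspace(0.0, 100.0, 750)
        raw = resample_to_scale([(i, v) for i, v in enumerate(ramp)])
        out = fill_gaps(raw)
        expected = np.linspace(0.0, 100.0, 1000)
        assert np.max(np.abs(out.values - expected)) <= 0.5

    def test_occupied_positions_never_modified(self):
        rng = np.random.default_rng(1)
        values = rng.random(1000)
        mask = rng.random(1000) < 0.25
        values[mask] = np.nan
        raw = RawSpectrum(values=values, gap_mask=mask)
        out = fill_gaps(raw)
        np.testing.assert_array_equal(out.values[~mask], values[~mask])
        assert np.all(np.isfinite(out.values))

    def test_all_gaps_rejected(self):
        with pytest.raises(AllGaps):
            fill_gaps(RawSpectrum(values=np.full(1000, np.nan),
                                  gap_mask=np.ones(1000, bool)))


class TestWavelengthAxis:
    @pytest.mark.parametrize("p,nm", [(1, 390.0), (1000, 700.0), (500.5, 545.0)])
    def test_linear_calibration(self, p, nm):
        assert position_to_wavelength(p) == pytest.approx(nm)

    @pytest.mark.parametrize("p", [0, 1001, -3])
    def test_out_of_range(self, p):
        with pytest.raises(OutOfRange):
            position_to_wavelength(p)


class TestExtractSpectrum:
    def test_round_trip_correlation(self, curve):
        img = render_photograph(curve, seed=5)
        s = extract_spectrum(img)
        r = np.corrcoef(s.values, curve * 765)[0, 1]
        assert r > 0.99

    def test_invariance_to_circle_radius(self, curve):
        small = RenderSpec(width=800, height=700, radius=240, noise_sd=0)
        large = RenderSpec(width=800, height=700, radius=260, noise_sd=0)
        sa = extract_spectrum(render_photograph(curve, small, seed=6)).values
        sb = extract_spectrum(render_photograph(curve, large, seed=6)).values
        rms = np.sqrt(np.mean((sa - sb) ** 2))
        assert rms < 0.01 * (sa.max() - sa.min())

    def test_saturated_band_is_flat_765(self):
        img = render_photograph(np.ones(1000), RenderSpec(noise_sd=0), seed=7)
        s = extract_spectrum(img)
        np.testing.assert_allclose(s.values, 765.0, atol=1.5)
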