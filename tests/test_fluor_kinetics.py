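"""Photobleaching quantification: PE arithmetic, exponential-rate fitting,
ROI segmentation and the red-to-blue ratio series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdtmon.fluor_kinetics import (
    AlignmentError,
    DoseSeries,
    FluorescenceFrame,
    InsufficientDataError,
    NoFluorescenceError,
    ROIMask,
    dose_from_exposure,
    fit_bleach_rate,
    mean_intensity,
    photobleaching_efficiency,
    ratio_series,
    red_blue_ratio,
    segment_fluorescing_area,
)
from pdtmon.synthetic_data import SessionSpec, generate_bleach_series


def make_series(alpha, doses=(0, 10, 20, 30, 40, 50), if1=100.0, excitation=405):
    d = np.asarray(doses, dtype=float)
    return DoseSeries(
        doses=d, intensities=if1 * np.exp(-alpha * d), excitation_nm=excitation
    )


class TestPhotobleachingEfficiency:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(100.0, 58.0, 42.0), (7.5, 7.5, 0.0), (50.0, 0.0, 100.0)],
    )
    def test_arithmetic(self, before, after, expected):
        assert photobleaching_efficiency(before, after) == pytest.approx(expected)

    def test_exponential_model_closed_form(self):
        """PE after 50 J/cm2 at the blue-regime rate 0.011 (J/cm2)^-1 is
        100*(1-e^-0.55) = 42.31%, consistent with the measured ~42% level."""
        pe = photobleaching_efficiency(1.0, np.exp(-0.011 * 50))
        assert pe == pytest.approx(100 * (1 - np.exp(-0.55)), abs=1e-12)
        assert pe == pytest.approx(42.31, abs=0.01)

    @pytest.mark.parametrize("before", [0.0, -1.0])
    def test_nonpositive_before_rejected(self, before):
        with pytest.raises(ValueError):
            photobleaching_efficiency(before, 1.0)

    @given(
        a=st.floats(0.1, 1e6),
        b=st.floats(0.0, 1e6),
        c=st.floats(1e-3, 1e3),
    )
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, a, b, c):
        assert photobleaching_efficiency(c * a, c * b) == pytest.approx(
            photobleaching_efficiency(a, b), rel=1e-9
        )

    def test_pe_of_dose_increasing_to_100(self):
        doses = np.linspace(0, 1000, 200)
        pe = np.array(
            [photobleaching_efficiency(1.0, np.exp(-0.011 * d)) for d in doses]
        )
        assert pe[0] == 0.0
        assert np.all(np.diff(pe) > 0)
        assert pe[-1] < 100.0 and pe[-1] > 99.9


class TestFitBleachRate:
    def test_exact_on_noiseless_data(self):
        fit = fit_bleach_rate(make_series(0.017))
        assert fit.alpha == pytest.approx(0.017, rel=1e-9)
        assert fit.If1 == pytest.approx(100.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_two_point_log_solution(self):
        """On exact exponential data through (0, 100) and (50, 57.695) the
        fitted rate equals the closed-form ln(100/57.695)/50 = 0.011."""
        alpha_closed = np.log(100.0 / 57.695) / 50.0
        assert alpha_closed == pytest.approx(0.011, abs=1e-5)
        fit = fit_bleach_rate(make_series(alpha_closed, doses=(0, 25, 50)))
        assert fit.alpha == pytest.approx(alpha_closed, rel=1e-9)

    def test_noisy_replicates_recover_rate(self):
        """Mean fitted rate over 3 replicates at 5% CV stays within 10%."""
        spec = SessionSpec(seed=42, alpha_405=0.014, noise_cv=0.05,
                           n_replicates=3)
        fits = [fit_bleach_rate(s) for s in generate_bleach_series(spec, 405)]
        mean_alpha = np.mean([f.alpha for f in fits])
        assert mean_alpha == pytest.approx(0.014, rel=0.10)

    def test_too_few_points(self):
        s = DoseSeries(doses=np.array([0.0, 10.0]),
                       intensities=np.array([100.0, 90.0]), excitation_nm=405)
        with pytest.raises(InsufficientDataError):
            fit_bleach_rate(s)

    def test_alpha_se_positive_on_noisy_data(self):
        spec = SessionSpec(seed=1, alpha_405=0.011, noise_cv=0.05,
                           n_replicates=1)
        fit = fit_bleach_rate(generate_bleach_series(spec, 405)[0])
        assert fit.alpha_se > 0
        assert 0 <= fit.r_squared <= 1


class TestDoseSeriesValidation:
    def test_must_start_at_zero(self):
        with pytest.raises(ValueError):
            DoseSeries(doses=np.array([1.0, 2.0, 3.0]),
                       intensities=np.ones(3), excitation_nm=405)

    def test_strictly_increasing(self):
        with pytest.raises(ValueError):
            DoseSeries(doses=np.array([0.0, 10.0, 10.0]),
                       intensities=np.ones(3), excitation_nm=405)

    def test_positive_intensities(self):
        with pytest.raises(ValueError):
            DoseSeries(doses=np.array([0.0, 10.0]),
                       intensities=np.array([1.0, 0.0]), excitation_nm=660)


class TestSegmentation:
    @staticmethod
    def frame(px, exc=405, dose=0.0):
        return FluorescenceFrame(pixels=px, excitation_nm=exc,
                                 cumulative_dose=dose)

    def test_bright_disc_on_dark_background(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2
        px = np.where(disc, 1000.0, 10.0)
        roi = segment_fluorescing_area(self.frame(px), 0.2)
        assert np.array_equal(roi.mask, disc)

    def test_all_zero_frame(self):
        with pytest.raises(NoFluorescenceError):
            segment_fluorescing_area(self.frame(np.zeros((16, 16))))

    def test_linear_ramp_against_enumeration(self):
        px = np.tile(np.linspace(0, 100, 64), (64, 1))
        roi = segment_fluorescing_area(self.frame(px), 0.5)
        thr = 0.5 * np.percentile(px, 99)
        expected = int(np.sum(px >= thr))  # ramp: single connected block
        assert roi.pixel_count == expected

    def test_keeps_largest_component(self):
        px = np.zeros((32, 32))
        px[2:4, 2:4] = 100.0  # 4 pixels
        px[10:20, 10:20] = 100.0  # 100 pixels
        roi = segment_fluorescing_area(self.frame(px), 0.2)
        assert roi.pixel_count == 100


class TestMeanIntensity:
    def test_constant_frame(self):
        f = FluorescenceFrame(np.full((8, 8), 7.0), 405, 0.0)
        roi = ROIMask(np.ones((8, 8), dtype=bool))
        assert mean_intensity(f, roi) == 7.0

    def test_two_pixel_roi(self):
        px = np.zeros((4, 4))
        px[0, 0], px[0, 1] = 4.0, 6.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :2] = True
        assert mean_intensity(FluorescenceFrame(px, 660, 0.0), ROIMask(mask)) == 5.0

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 100, (32, 32))
        mask = rng.random((32, 32)) > 0.5
        got = mean_intensity(FluorescenceFrame(px, 405, 0.0), ROIMask(mask))
        total, count = 0.0, 0
        for i in range(32):
            for j in range(32):
                if mask[i, j]:
                    total += px[i, j]
                    count += 1
        assert got == pytest.approx(total / count, rel=1e-12)

    def test_shape_mismatch(self):
        f = FluorescenceFrame(np.ones((8, 8)), 405, 0.0)
        with pytest.raises(ValueError):
            mean_intensity(f, ROIMask(np.ones((4, 4), dtype=bool)))


class TestRatioSeries:
    @pytest.mark.parametrize("i660, i405, expected",
                             [(0.9, 1.0, 0.9), (3.3, 3.3, 1.0), (1.1, 1.0, 1.1)])
    def test_red_blue_ratio(self, i660, i405, expected):
        assert red_blue_ratio(i660, i405) == pytest.approx(expected)

    def test_ratio_rejects_nonpositive_denominator(self):
        with pytest.raises(ValueError):
            red_blue_ratio(1.0, 0.0)

    def test_identical_series_constant_one(self):
        rs = ratio_series(make_series(0.01, excitation=660),
                          make_series(0.01, excitation=405))
        assert np.allclose(rs.ratios, 1.0)
        assert rs.trend == "flat"

    def test_faster_blue_bleaching_gives_rising_ratio(self):
        # blue-light PDT: superficial bleaching, alpha_405 > alpha_660
        rs = ratio_series(make_series(0.009, excitation=660),
                          make_series(0.011, excitation=405))
        assert rs.trend == "rising"
        assert np.all(np.diff(rs.ratios) > 0)

    def test_faster_red_bleaching_gives_falling_ratio(self):
        # red-light PDT rates: ratio decays like exp((0.014-0.017) D)
        rs = ratio_series(make_series(0.017, excitation=660),
                          make_series(0.014, excitation=405))
        assert rs.trend == "falling"
        assert np.all(np.diff(rs.ratios) < 0)
        expected = np.exp((0.014 - 0.017) * rs.doses) * (100.0 / 100.0)
        assert np.allclose(rs.ratios, expected)

    def test_interpolation_onto_coarser_grid(self):
        fine = make_series(0.01, doses=np.arange(0, 51, 5.0), excitation=660)
        coarse = make_series(0.012, doses=np.arange(0, 51, 10.0), excitation=405)
        rs = ratio_series(fine, coarse)
        assert np.array_equal(rs.doses, coarse.doses)

    def test_insufficient_overlap_rejected(self):
        # the 405 grid has a single point inside the 660 dose range
        s660 = make_series(0.01, doses=(0, 1, 2, 3), excitation=660)
        s405 = DoseSeries(doses=np.array([0.0, 40.0, 50.0]),
                          intensities=np.array([1.0, 0.9, 0.8]),
                          excitation_nm=405)
        with pytest.raises(AlignmentError):
            ratio_series(s660, s405)


class TestDoseFromExposure:
    @pytest.mark.parametrize("rate, secs, dose",
                             [(200, 250, 50.0), (200, 750, 150.0), (123, 0, 0.0)])
    def test_unit_conversion(self, rate, secs, dose):
        assert dose_from_exposure(rate, secs) == pytest.approx(dose)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dose_from_exposure(-1.0, 10.0)
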