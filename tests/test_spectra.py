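"""Spectrum container, inner-filter correction, integration, derivatives, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmzbind import (
    InnerFilterInput,
    Spectrum,
    band_area,
    inner_filter_correct,
    inner_filter_correct_spectrum,
    read_spectrum,
    resample,
    second_derivative,
    write_spectrum,
)
from tmzbind.errors import (
    InvalidInputError,
    InvalidParameterError,
    RangeError,
)


class TestSpectrumInvariants:
    def test_rejects_non_monotonic_wavelengths(self):
        with pytest.raises(InvalidInputError, match="strictly increasing"):
            Spectrum([300.0, 310.0, 305.0], [1.0, 1.0, 1.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            Spectrum([300.0, 310.0], [1.0])

    def test_rejects_negative_extinction(self):
        with pytest.raises(InvalidInputError):
            Spectrum([300.0, 310.0], [1.0, -1.0], kind="extinction")

    def test_rejects_single_point(self):
        with pytest.raises(InvalidInputError):
            Spectrum([300.0], [1.0])


class TestInnerFilter:
    @pytest.mark.parametrize(
        "iobs,aex,aem,expected",
        [
            (100.0, 0.0, 0.0, 100.0),      # zero absorbance leaves I untouched
            (100.0, 1.0, 1.0, 1000.0),     # exponent 1 multiplies by 10
            (100.0, 0.1, 0.1, 125.8925412),  # 100 * 10**0.1
        ],
    )
    def test_scalar_correction(self, iobs, aex, aem, expected):
        got = inner_filter_correct(InnerFilterInput(iobs, aex, aem))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_elementwise_aem(self):
        iobs = np.array([10.0, 20.0, 30.0])
        aem = np.array([0.0, 0.2, 0.4])
        got = inner_filter_correct(InnerFilterInput(iobs, 0.2, aem))
        np.testing.assert_allclose(got, iobs * 10.0 ** ((0.2 + aem) / 2))

    def test_rejects_non_finite_absorbance(self):
        with pytest.raises(InvalidInputError):
            inner_filter_correct(InnerFilterInput(1.0, np.nan, 0.0))

    def test_spectrum_wrapper_preserves_grid(self, gaussian_emission):
        out = inner_filter_correct_spectrum(gaussian_emission, 0.05, 0.02)
        np.testing.assert_array_equal(out.wavelengths,
                                      gaussian_emission.wavelengths)
        assert np.all(out.values >= gaussian_emission.values)

    @given(aex=st.floats(0, 2), aem=st.floats(0, 2))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_correction_factor_at_least_one_for_nonneg_absorbance(self, aex, aem):
        got = inner_filter_correct(InnerFilterInput(50.0, aex, aem))
        assert got >= 50.0


class TestBandArea:
    def test_rectangle(self):
        wl = np.arange(290.0, 400.5, 0.5)
        s = Spectrum(wl, np.ones_like(wl))
        assert band_area(s, 290, 400) == pytest.approx(110.0)

    def test_gaussian_matches_analytic_area(self):
        wl = np.arange(250.0, 450.0 + 0.5, 0.5)
        sigma, amp = 12.0, 7.3
        s = Spectrum(wl, amp * np.exp(-0.5 * ((wl - 334.0) / sigma) ** 2))
        analytic = amp * sigma * np.sqrt(2 * np.pi)
        assert band_area(s, 250, 450) == pytest.approx(analytic, rel=1e-3)

    def test_interpolated_endpoints(self):
        wl = np.array([300.0, 310.0])
        s = Spectrum(wl, np.array([0.0, 10.0]))  # linear ramp
        # integral of (x-300) from 302 to 308 = (8^2 - 2^2)/2 = 30
        assert band_area(s, 302.0, 308.0) == pytest.approx(30.0, rel=1e-12)

    def test_additive_over_subintervals(self, gaussian_emission):
        whole = band_area(gaussian_emission, 295.3, 388.1)
        parts = (band_area(gaussian_emission, 295.3, 333.7)
                 + band_area(gaussian_emission, 333.7, 388.1))
        assert whole == pytest.approx(parts, rel=1e-9)

    def test_empty_overlap_raises(self, gaussian_emission):
        with pytest.raises(RangeError):
            band_area(gaussian_emission, 500.0, 600.0)

    def test_inverted_limits_raise(self, gaussian_emission):
        with pytest.raises(RangeError):
            band_area(gaussian_emission, 350.0, 300.0)


class TestSecondDerivative:
    def test_quadratic_gives_constant_two(self):
        wl = np.arange(300.0, 340.0, 1.0)
        s = Spectrum(wl, wl**2)
        d2 = second_derivative(s, window=7)
        np.testing.assert_allclose(d2.values, 2.0, rtol=1e-8)

    def test_linear_gives_zero(self):
        wl = np.arange(300.0, 340.0, 1.0)
        s = Spectrum(wl, 3.0 * wl - 7.0)
        d2 = second_derivative(s, window=7)
        np.testing.assert_allclose(d2.values, 0.0, atol=1e-8)

    def test_sine_matches_analytic(self):
        wl = np.arange(300.0, 360.0, 0.2)
        s = Spectrum(wl, np.sin(wl / 10.0))
        d2 = second_derivative(s, window=7)
        expected = -np.sin(wl / 10.0) / 100.0
        interior = slice(5, -5)
        np.testing.assert_allclose(d2.values[interior], expected[interior],
                                   rtol=1e-2)

    @pytest.mark.parametrize("window", [4, 6, 3, 1000])
    def test_bad_window_raises(self, window, gaussian_emission):
        with pytest.raises(InvalidParameterError):
            second_derivative(gaussian_emission, window=window)

    def test_nonuniform_grid_quadratic_still_exact(self):
        wl = np.sort(np.concatenate([np.arange(300, 340, 1.0),
                                     [305.3, 311.7, 322.9]]))
        s = Spectrum(wl, 0.5 * wl**2 - 4 * wl + 1)
        d2 = second_derivative(s, window=7)
        np.testing.assert_allclose(d2.values, 1.0, rtol=1e-8)


class TestResample:
    def test_identity_on_own_grid(self, gaussian_emission):
        out = resample(gaussian_emission, gaussian_emission.wavelengths)
        np.testing.assert_array_equal(out.values, gaussian_emission.values)

    def test_exact_on_linear_spectrum(self):
        wl = np.arange(300.0, 320.0, 2.0)
        s = Spectrum(wl, 2.0 * wl + 1.0)
        grid = np.array([301.3, 307.9, 315.4])
        out = resample(s, grid)
        np.testing.assert_allclose(out.values, 2.0 * grid + 1.0, rtol=1e-12)

    def test_extrapolation_rejected(self, gaussian_emission):
        with pytest.raises(RangeError):
            resample(gaussian_emission, np.array([280.0, 300.0]))


class TestSpectrumIO:
    def test_round_trip_preserves_decimal_text(self, tmp_path, gaussian_emission):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_spectrum(gaussian_emission, p1)
        s1 = read_spectrum(p1)
        write_spectrum(s1, p2)
        # strip labels which may differ from file stems
        body = lambda p: [l for l in p.read_text().splitlines()
                          if not l.startswith("#")]
        assert body(p1) == body(p2)
        np.testing.assert_array_equal(s1.wavelengths,
                                      read_spectrum(p2).wavelengths)

    def test_kind_inferred_from_header(self, tmp_path):
        p = tmp_path / "abs.csv"
        p.write_text("wavelength_nm,absorbance_AU\n300,0.1\n310,0.2\n")
        assert read_spectrum(p).kind == "absorbance"

    def test_non_monotonic_file_names_offending_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,intensity_AU\n300,1\n310,1\n305,1\n")
        with pytest.raises(InvalidInputError, match="row 4"):
            read_spectrum(p)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("lambda,value\n300,1\n310,1\n")
        with pytest.raises(InvalidInputError, match="wavelength_nm"):
            read_spectrum(p)
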