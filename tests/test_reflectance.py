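"""Absorbance conversion and the oxygenation / cytochrome ratio metrics."""

import numpy as np
import pytest

from myofluor import (
    AbsorbanceSpectrum,
    ReflectanceSpectrum,
    absorbance,
    cytochrome_ratio,
    difference_spectrum,
    oxygenation_ratio,
)
from myofluor.simulate import SpectralTemplates, simulate_reflectance

WL = np.arange(400.0, 701.0, 1.0)


def flat_absorbance(level):
    return AbsorbanceSpectrum(WL, np.full(WL.size, level))


def template_absorbance(oxy, cytc, templates=SpectralTemplates()):
    sample, white = simulate_reflectance(templates, oxy, cytc, noise=0.0)
    return absorbance(sample, white)


class TestAbsorbance:
    def test_identity_spectra_give_zero(self):
        s = ReflectanceSpectrum(WL, np.full(WL.size, 100.0))
        w = ReflectanceSpectrum(WL, np.full(WL.size, 100.0), role="white_reference")
        np.testing.assert_allclose(absorbance(s, w).absorbance, 0.0, atol=1e-12)

    def test_decade_attenuation(self):
        i0 = np.full(WL.size, 100.0)
        i = i0.copy()
        k = 50
        i[k] = 10.0
        s = ReflectanceSpectrum(WL, i)
        w = ReflectanceSpectrum(WL, i0, role="white_reference")
        assert absorbance(s, w).absorbance[k] == pytest.approx(1.0)
        assert absorbance(s, w, "as_printed").absorbance[k] == pytest.approx(-1.0)

    def test_sign_conventions_are_negations(self):
        spec = template_absorbance(0.7, 0.3)
        sample, white = simulate_reflectance(SpectralTemplates(), 0.7, 0.3, noise=0.0)
        printed = absorbance(sample, white, "as_printed")
        np.testing.assert_allclose(spec.absorbance, -printed.absorbance)

    def test_oxygenated_template_peaks_at_544_and_578(self):
        from scipy.signal import find_peaks

        spec = template_absorbance(1.0, 0.0)
        idx, _ = find_peaks(spec.absorbance, prominence=0.05)
        assert set(spec.wavelengths[idx]) == {544.0, 578.0}

    def test_zero_intensity_bins_masked_with_warning(self):
        i0 = np.full(WL.size, 100.0)
        i = i0.copy()
        i[10] = 0.0
        s = ReflectanceSpectrum(WL, i)
        w = ReflectanceSpectrum(WL, i0, role="white_reference")
        with pytest.warns(UserWarning, match="masking"):
            spec = absorbance(s, w)
        assert spec.wavelengths.size == WL.size - 1
        assert WL[10] not in spec.wavelengths

    def test_reference_interpolated_to_sample_grid(self):
        coarse = np.arange(400.0, 701.0, 5.0)
        w = ReflectanceSpectrum(coarse, np.linspace(50, 150, coarse.size),
                                role="white_reference")
        s = ReflectanceSpectrum(WL, np.interp(WL, coarse, w.intensities))
        np.testing.assert_allclose(absorbance(s, w).absorbance, 0.0, atol=1e-12)


class TestRatios:
    def test_flat_spectrum_gives_unity(self):
        assert oxygenation_ratio(flat_absorbance(0.3)) == pytest.approx(1.0)
        assert cytochrome_ratio(flat_absorbance(0.3)) == pytest.approx(1.0)

    def test_scale_invariance(self):
        spec = template_absorbance(0.8, 0.2)
        scaled = AbsorbanceSpectrum(spec.wavelengths, 3.7 * spec.absorbance)
        assert oxygenation_ratio(scaled) == pytest.approx(oxygenation_ratio(spec))
        assert cytochrome_ratio(scaled) == pytest.approx(cytochrome_ratio(spec))

    def test_oxygenation_ratio_separates_states(self):
        assert oxygenation_ratio(template_absorbance(1.0, 0.0)) > oxygenation_ratio(
            template_absorbance(0.0, 0.0)
        )

    def test_oxygenation_ratio_monotone_in_mixture(self):
        ratios = [oxygenation_ratio(template_absorbance(f, 0.0)) for f in np.linspace(0, 1, 11)]
        assert np.all(np.diff(ratios) > 0)

    def test_reduced_cytochrome_lowers_cytochrome_ratio(self):
        assert cytochrome_ratio(template_absorbance(0.0, 1.0)) < cytochrome_ratio(
            template_absorbance(0.0, 0.0)
        )

    def test_numerator_only_perturbation_raises_ratio(self):
        spec = flat_absorbance(0.4)
        bumped = AbsorbanceSpectrum(
            WL, spec.absorbance + 0.2 * (WL == 502.0)
        )
        assert cytochrome_ratio(bumped) == pytest.approx(0.6 / 0.4)

    def test_out_of_range_wavelength_rejected(self):
        short = AbsorbanceSpectrum(np.arange(520.0, 560.0), np.ones(40))
        with pytest.raises(ValueError, match="outside"):
            oxygenation_ratio(short)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            oxygenation_ratio(flat_absorbance(0.0))


class TestDifferenceSpectrum:
    def test_identical_spectra_give_no_extrema(self):
        spec = template_absorbance(1.0, 0.0)
        diff, extrema = difference_spectrum(spec, spec)
        np.testing.assert_allclose(diff.absorbance, 0.0)
        assert extrema.size == 0

    def test_oxy_minus_deoxy_extrema_near_578(self):
        diff, extrema = difference_spectrum(
            template_absorbance(1.0, 0.0), template_absorbance(0.0, 0.9)
        )
        assert extrema.size >= 1
        assert np.min(np.abs(extrema - 578.0)) <= 3.0

    def test_antisymmetry(self):
        a = template_absorbance(1.0, 0.0)
        b = template_absorbance(0.2, 0.5)
        d_ab, _ = difference_spectrum(a, b)
        d_ba, _ = difference_spectrum(b, a)
        np.testing.assert_allclose(d_ab.absorbance, -d_ba.absorbance)

    def test_disjoint_grids_rejected(self):
        a = AbsorbanceSpectrum(WL, np.ones(WL.size))
        b = AbsorbanceSpectrum(WL + 0.5, np.ones(WL.size))
        with pytest.raises(ValueError, match="common wavelength grid"):
            difference_spectrum(a, b)


class TestSpectrumValidation:
    def test_decreasing_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ReflectanceSpectrum(WL[::-1], np.ones(WL.size))

    def test_negative_intensity_rejected(self):
        i = np.ones(WL.size)
        i[3] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            ReflectanceSpectrum(WL, i)

    def test_out_of_band_wavelengths_rejected(self):
        wl = np.arange(300.0, 500.0)
        with pytest.raises(ValueError, match=r"\[350, 800\]"):
            ReflectanceSpectrum(wl, np.ones(wl.size))
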