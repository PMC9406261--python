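"""Lambda-stack analysis: ROI spectra, peak maps, red-shift classification."""

import numpy as np
import pytest

from eosinquant import (
    LambdaStack,
    PeakMap,
    SpectrumProfile,
    classify_redshift,
    extract_spectrum,
    normalize_spectrum,
    peak_wavelength_map,
)


def make_stack(planes, wavelengths=None):
    planes = np.asarray(planes, dtype=float)
    if wavelengths is None:
        wavelengths = 480.0 + 10.0 * np.arange(planes.shape[0])
    return LambdaStack(wavelengths=np.asarray(wavelengths, float), planes=planes)


class TestExtractSpectrum:
    def test_single_pixel_roi_returns_that_pixels_values(self):
        rng = np.random.default_rng(0)
        stack = make_stack(rng.random((6, 4, 4)))
        roi = np.zeros((4, 4), dtype=bool)
        roi[2, 1] = True
        profile = extract_spectrum(stack, roi)
        assert np.array_equal(profile.mean_intensity, stack.planes[:, 2, 1])
        assert profile.n_pixels == 1

    def test_constant_planes_give_constant_profile(self):
        consts = np.array([1.0, 3.0, 2.0, 5.0])
        stack = make_stack(consts[:, None, None] * np.ones((4, 3, 3)))
        profile = extract_spectrum(stack, np.ones((3, 3), dtype=bool))
        assert np.allclose(profile.mean_intensity, consts)

    def test_tissue_roi_of_phantom_peaks_at_550(self, noise_free_phantom):
        roi = noise_free_phantom.tissue_mask & ~noise_free_phantom.blood_mask
        profile = extract_spectrum(noise_free_phantom.stack, roi)
        assert profile.peak_wavelength == 550.0

    def test_blood_roi_of_phantom_peaks_at_570(self, noise_free_phantom):
        profile = extract_spectrum(noise_free_phantom.stack, noise_free_phantom.blood_mask)
        assert profile.peak_wavelength == 570.0

    def test_empty_roi_rejected(self):
        stack = make_stack(np.ones((3, 4, 4)))
        with pytest.raises(ValueError, match="empty ROI"):
            extract_spectrum(stack, np.zeros((4, 4), dtype=bool))

    def test_shape_mismatch_rejected(self):
        stack = make_stack(np.ones((3, 4, 4)))
        with pytest.raises(ValueError, match="does not match"):
            extract_spectrum(stack, np.ones((5, 5), dtype=bool))

    def test_linear_in_the_stack(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((5, 6, 6)), rng.random((5, 6, 6))
        roi = rng.random((6, 6)) > 0.4
        wl = 500.0 + 10.0 * np.arange(5)
        spec_a = extract_spectrum(make_stack(a, wl), roi).mean_intensity
        spec_b = extract_spectrum(make_stack(b, wl), roi).mean_intensity
        spec_sum = extract_spectrum(make_stack(a + b, wl), roi).mean_intensity
        assert np.allclose(spec_a + spec_b, spec_sum)


class TestNormalizeSpectrum:
    def test_divides_by_maximum(self):
        profile = SpectrumProfile(
            wavelengths=np.array([500.0, 510.0, 520.0]),
            mean_intensity=np.array([2.0, 4.0, 8.0]),
            n_pixels=10,
        )
        out = normalize_spectrum(profile)
        assert np.allclose(out.mean_intensity, [0.25, 0.5, 1.0])

    def test_idempotent(self):
        profile = SpectrumProfile(
            wavelengths=np.array([500.0, 510.0]),
            mean_intensity=np.array([0.5, 1.0]),
            n_pixels=1,
        )
        out = normalize_spectrum(profile)
        assert np.array_equal(out.mean_intensity, profile.mean_intensity)

    def test_argmax_preserved(self):
        rng = np.random.default_rng(2)
        values = rng.random(12) + 0.01
        profile = SpectrumProfile(
            wavelengths=480.0 + 10.0 * np.arange(12), mean_intensity=values, n_pixels=3
        )
        assert normalize_spectrum(profile).peak_wavelength == profile.peak_wavelength

    def test_zero_spectrum_rejected(self):
        profile = SpectrumProfile(
            wavelengths=np.array([500.0, 510.0]),
            mean_intensity=np.zeros(2),
            n_pixels=1,
        )
        with pytest.raises(ValueError, match="zero spectrum"):
            normalize_spectrum(profile)


class TestPeakWavelengthMap:
    def test_single_maximum_pixel(self):
        planes = np.zeros((8, 2, 2))
        planes[:, :, :] = 0.5  # keep every pixel above the validity cut
        planes[6, 0, 1] = 9.0  # band centre 480 + 6*10 = 540 nm
        stack = make_stack(planes, wavelengths=480.0 + 10.0 * np.arange(8))
        peakmap = peak_wavelength_map(stack, min_intensity=0.0)
        assert peakmap.peak_wavelength[0, 1] == 540.0

    def test_matches_bruteforce_argmax_oracle(self):
        rng = np.random.default_rng(3)
        planes = rng.random((8, 5, 5))
        stack = make_stack(planes)
        peakmap = peak_wavelength_map(stack, min_intensity=0.0, smooth_sigma=0.0)
        for i in range(5):
            for j in range(5):
                best, best_wl = -1.0, None
                for k in range(8):  # first maximum = lowest wavelength on ties
                    if planes[k, i, j] > best:
                        best, best_wl = planes[k, i, j], stack.wavelengths[k]
                assert peakmap.peak_wavelength[i, j] == best_wl

    def test_ties_break_to_lowest_wavelength(self):
        planes = np.ones((4, 1, 1))
        stack = make_stack(planes)
        peakmap = peak_wavelength_map(stack, min_intensity=0.0)
        assert peakmap.peak_wavelength[0, 0] == stack.wavelengths[0]

    def test_dim_pixels_marked_invalid_with_nan(self):
        planes = np.full((3, 2, 2), 0.01)
        planes[:, 0, 0] = 5.0
        stack = make_stack(planes)
        peakmap = peak_wavelength_map(stack, min_intensity=1.0)
        assert peakmap.valid_mask[0, 0]
        assert not peakmap.valid_mask[1, 1]
        assert np.isnan(peakmap.peak_wavelength[1, 1])

    def test_default_validity_excludes_background_of_phantom(self, noise_free_phantom):
        peakmap = peak_wavelength_map(noise_free_phantom.stack)
        background = ~noise_free_phantom.tissue_mask
        assert not peakmap.valid_mask[background].any()
        assert peakmap.valid_mask[noise_free_phantom.tissue_mask].all()

    def test_modal_blood_peak_is_570(self, noise_free_phantom):
        peakmap = peak_wavelength_map(noise_free_phantom.stack, smooth_sigma=0.0)
        blood_peaks = peakmap.peak_wavelength[noise_free_phantom.blood_mask]
        values, counts = np.unique(blood_peaks[~np.isnan(blood_peaks)], return_counts=True)
        assert values[np.argmax(counts)] == 570.0

    def test_spectral_smoothing_leaves_spatial_structure(self):
        rng = np.random.default_rng(4)
        planes = rng.random((10, 4, 4))
        stack = make_stack(planes)
        smoothed = peak_wavelength_map(stack, min_intensity=0.0, smooth_sigma=15.0)
        assert smoothed.peak_wavelength.shape == (4, 4)
        assert np.all(np.isin(smoothed.peak_wavelength, stack.wavelengths))

    def test_too_few_planes_rejected(self):
        stack = LambdaStack(wavelengths=np.array([500.0]), planes=np.ones((1, 2, 2)))
        with pytest.raises(ValueError, match="need >=2 spectral planes"):
            peak_wavelength_map(stack, min_intensity=0.0)


class TestClassifyRedshift:
    def make_map(self, value):
        peaks = np.full((3, 3), float(value))
        return PeakMap(
            peak_wavelength=peaks,
            valid_mask=np.ones((3, 3), dtype=bool),
            wavelength_range=(480.0, 690.0),
        )

    def test_all_below_cutoff_gives_empty_mask(self):
        assert not classify_redshift(self.make_map(550), cutoff=560.0).any()

    def test_all_above_cutoff_gives_full_mask(self):
        assert classify_redshift(self.make_map(570), cutoff=560.0).all()

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        peaks = rng.choice([500.0, 550.0, 570.0, 600.0], size=(10, 10))
        peakmap = PeakMap(
            peak_wavelength=peaks,
            valid_mask=np.ones((10, 10), dtype=bool),
            wavelength_range=(480.0, 690.0),
        )
        previous = None
        for cutoff in (500.0, 540.0, 560.0, 590.0, 650.0):
            mask = classify_redshift(peakmap, cutoff=cutoff)
            if previous is not None:
                assert np.all(mask <= previous)  # raising the cutoff never adds pixels
            previous = mask

    def test_cutoff_outside_stack_range_rejected(self):
        with pytest.raises(ValueError, match="outside the stack range"):
            classify_redshift(self.make_map(550), cutoff=700.0)

    def test_agreement_with_ground_truth_on_phantom(self, noise_free_phantom):
        peakmap = peak_wavelength_map(noise_free_phantom.stack, smooth_sigma=0.0)
        classified = classify_redshift(peakmap)
        agreement = np.mean(classified == noise_free_phantom.blood_mask)
        assert agreement >= 0.95
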