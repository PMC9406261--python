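"""Lambda-stack spectral analysis.

A lambda stack is a series of co-registered images of the same field, one
per narrow emission band (here 10-nm bands stepped across the visible
spectrum).  Eosin Y bound to most tissue emits with a maximum near 550 nm;
bound to erythrocytes the spectrum red-shifts to a maximum near 570 nm and
brightens.  This module extracts ROI spectra, builds per-pixel
peak-emission-wavelength maps and classifies red-shifted (blood-like)
pixels from that shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .thresholding import histogram256, huang_threshold, apply_threshold

__all__ = [
    "LambdaStack",
    "SpectrumProfile",
    "PeakMap",
    "extract_spectrum",
    "normalize_spectrum",
    "peak_wavelength_map",
    "classify_redshift",
    "DEFAULT_REDSHIFT_CUTOFF_NM",
]

#: Midpoint between the tissue (550 nm) and erythrocyte (570 nm) emission maxima.
DEFAULT_REDSHIFT_CUTOFF_NM = 560.0


@dataclass(frozen=True)
class LambdaStack:
    """Ordered emission-band image series.

    ``wavelengths`` are the band centres in nm (strictly increasing);
    ``planes`` is a float array of shape (n_bands, height, width) with
    non-negative intensities.  ``pixel_size_um`` is the physical pixel
    pitch, if known.
    """

    wavelengths: np.ndarray
    planes: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        planes = np.asarray(self.planes, dtype=np.float64)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelengths must be a non-empty 1-D sequence")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if planes.ndim != 3 or planes.shape[0] != wl.size:
            raise ValueError(
                "planes must have shape (n_wavelengths, height, width) matching wavelengths"
            )
        if np.any(planes < 0):
            raise ValueError("plane intensities must be non-negative")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "planes", planes)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def max_projection(self) -> np.ndarray:
        """Per-pixel maximum intensity across all bands."""
        return self.planes.max(axis=0)


@dataclass(frozen=True)
class SpectrumProfile:
    """Mean emission spectrum over a region of interest."""

    wavelengths: np.ndarray
    mean_intensity: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        mi = np.asarray(self.mean_intensity, dtype=np.float64)
        if wl.shape != mi.shape or wl.ndim != 1:
            raise ValueError("wavelengths and mean_intensity must be equal-length vectors")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "mean_intensity", mi)

    @property
    def peak_wavelength(self) -> float:
        """Wavelength of the spectral maximum (ties toward the shortest)."""
        return float(self.wavelengths[int(np.argmax(self.mean_intensity))])


@dataclass(frozen=True)
class PeakMap:
    """Per-pixel peak emission wavelength.

    ``peak_wavelength`` holds nm values, NaN at invalid pixels (too dim to
    call a peak); ``valid_mask`` marks the callable pixels.
    ``wavelength_range`` records the (min, max) of the source stack's grid
    so cutoffs can be validated.
    """

    peak_wavelength: np.ndarray
    valid_mask: np.ndarray
    wavelength_range: tuple[float, float]

    def __post_init__(self) -> None:
        pw = np.asarray(self.peak_wavelength, dtype=np.float64)
        vm = np.asarray(self.valid_mask, dtype=bool)
        if pw.shape != vm.shape:
            raise ValueError("peak_wavelength and valid_mask must share a shape")
        if np.any(np.isnan(pw[vm])):
            raise ValueError("valid pixels must carry a wavelength, not NaN")
        object.__setattr__(self, "peak_wavelength", pw)
        object.__setattr__(self, "valid_mask", vm)


def extract_spectrum(stack: LambdaStack, roi: np.ndarray) -> SpectrumProfile:
    """Mean spectrum of a lambda stack over a binary ROI.

    ``mean_intensity[k]`` is the mean of plane k over the ROI pixels; no
    normalisation is applied here (see :func:`normalize_spectrum`).
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.shape:
        raise ValueError(f"ROI shape {roi.shape} does not match stack shape {stack.shape}")
    n = int(roi.sum())
    if n == 0:
        raise ValueError("empty ROI")
    means = stack.planes[:, roi].mean(axis=1)
    return SpectrumProfile(wavelengths=stack.wavelengths, mean_intensity=means, n_pixels=n)


def normalize_spectrum(profile: SpectrumProfile) -> SpectrumProfile:
    """Scale a spectrum to unit maximum; the peak location is unchanged."""
    peak = float(profile.mean_intensity.max())
    if peak <= 0:
        raise ValueError("zero spectrum")
    return SpectrumProfile(
        wavelengths=profile.wavelengths,
        mean_intensity=profile.mean_intensity / peak,
        n_pixels=profile.n_pixels,
    )


def peak_wavelength_map(
    stack: LambdaStack,
    min_intensity: float | None = None,
    smooth_sigma: float = 0.0,
) -> PeakMap:
    """Per-pixel peak emission wavelength of a lambda stack.

    Each pixel's spectrum is optionally Gaussian-smoothed along the
    wavelength axis (``smooth_sigma`` in nm; never spatially, so ~5-um
    erythrocytes are not blurred), then the peak is the wavelength of the
    maximum on the sampling grid, ties broken toward the lowest wavelength.
    Pixels whose (unsmoothed) maximum intensity falls below
    ``min_intensity`` are marked invalid.  When ``min_intensity`` is None
    it defaults to the Huang threshold of the maximum-projection image.
    """
    if stack.n_bands < 2:
        raise ValueError("need >=2 spectral planes")
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be >= 0")

    maxproj = stack.max_projection()
    if min_intensity is None:
        result = huang_threshold(histogram256(maxproj))
        valid = apply_threshold(maxproj, result.threshold)
    else:
        if min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")
        valid = maxproj >= min_intensity

    planes = stack.planes
    if smooth_sigma > 0:
        steps = np.diff(stack.wavelengths)
        if not np.allclose(steps, steps[0]):
            raise ValueError("spectral smoothing requires a uniform wavelength grid")
        planes = gaussian_filter1d(planes, sigma=smooth_sigma / float(steps[0]), axis=0)

    # argmax returns the first maximum, i.e. the lowest wavelength on ties
    peaks = stack.wavelengths[np.argmax(planes, axis=0)]
    peaks = np.where(valid, peaks, np.nan)
    return PeakMap(
        peak_wavelength=peaks,
        valid_mask=valid,
        wavelength_range=(float(stack.wavelengths[0]), float(stack.wavelengths[-1])),
    )


def classify_redshift(peakmap: PeakMap, cutoff: float = DEFAULT_REDSHIFT_CUTOFF_NM) -> np.ndarray:
    """Mark valid pixels whose emission peak is red-shifted to >= cutoff nm.

    The default cutoff (560 nm) is the midpoint between the tissue and
    erythrocyte emission maxima.  Monotone in the cutoff: raising it never
    adds pixels.
    """
    lo, hi = peakmap.wavelength_range
    if not lo <= cutoff <= hi:
        raise ValueError(f"cutoff {cutoff} nm outside the stack range [{lo}, {hi}] nm")
    with np.errstate(invalid="ignore"):
        return peakmap.valid_mask & (peakmap.peak_wavelength >= cutoff)
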