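"""Detect the eosin red-shift in a lambda stack.

Extracts mean emission spectra over the tissue and blood regions of a
phantom, maps the per-pixel peak wavelength, and classifies red-shifted
(blood-like) pixels with the default 560-nm cutoff.
"""

import numpy as np

from eosinquant import (
    NoiseModel,
    PhantomSpec,
    classify_redshift,
    extract_spectrum,
    normalize_spectrum,
    peak_wavelength_map,
    render_phantom,
)

phantom = render_phantom(PhantomSpec(seed=11, noise=NoiseModel(0, 0)))
tissue_only = phantom.tissue_mask & ~phantom.blood_mask

tissue = normalize_spectrum(extract_spectrum(phantom.stack, tissue_only))
blood = normalize_spectrum(extract_spectrum(phantom.stack, phantom.blood_mask))
print(f"tissue emission peak: {tissue.peak_wavelength:.0f} nm  (n={tissue.n_pixels})")
print(f"blood emission peak:  {blood.peak_wavelength:.0f} nm  (n={blood.n_pixels})")
print(f"red-shift:            {blood.peak_wavelength - tissue.peak_wavelength:.0f} nm")

peakmap = peak_wavelength_map(phantom.stack, smooth_sigma=0.0)
classified = classify_redshift(peakmap)  # peak >= 560 nm
agreement = np.mean(classified == phantom.blood_mask)
print(f"red-shift mask vs ground truth: {100 * agreement:.2f} % pixel agreement")
# Tissue peaks at 550 nm, erythrocytes at 570 nm: thresholding the
# per-pixel peak wavelength at the 560-nm midpoint recovers the blood mask.
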