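# eosinquant

Identify and quantify intravascular blood in H&E-stained FFPE tissue
sections from the fluorescence of eosin Y.

Eosin Y, the routine counterstain of histopathology, is fluorescent:
excited in the blue, bulk tissue emits with a maximum near **550 nm**,
while eosin bound to erythrocytes is brighter, punctate, and red-shifted
to a maximum near **570 nm**. Erythrocytes appear as donut-shaped objects
roughly 5 µm across. That 20-nm red-shift separates blood from tissue with
nothing more than a standard green/red (FITC/TRITC) filter pair, so the
blood content of an ordinary H&E slide can be measured on any fluorescence
microscope — useful, for example, for scoring haemorrhage and microthrombi
in lung pathology.

`eosinquant` is aimed at image-analysis scientists and digital-pathology
developers. It provides:

- **Spectral analysis** of emission lambda stacks (one plane per 10-nm
  band, 480–690 nm): ROI spectra, per-pixel peak-wavelength maps, and
  red-shift classification (default cutoff 560 nm, the midpoint of the
  tissue and blood maxima).
- **Huang fuzzy-entropy automatic thresholding**, implemented from first
  principles. For a candidate threshold *t* with class means μ₀ (levels
  ≤ *t*) and μ₁ (levels > *t*), each grey level *g* gets the membership
  u(g) = 1 / (1 + |g − μ_class| / C) with C = g_max − g_min, and the
  threshold minimises the mean Shannon entropy
  E(t) = (1/N) Σ_g h(g) · S(u(g)), S(u) = −u ln u − (1−u) ln(1−u).
- **The two-channel quantification pipeline**: min–max normalise FITC and
  TRITC, average them (mean image ≈ all tissue), subtract the normalised
  FITC from the mean (≈ (TRITC−FITC)/2, clipped at 0 — high exactly over
  red-shifted blood), background-subtract, Huang-threshold the mean image
  (tissue mask) and the corrected difference image (blood mask), and report
  **blood % = 100 · blood area / tissue area**.
- **A synthetic phantom generator** that renders lambda stacks and channel
  pairs of simulated eosin-stained lung — tissue peaking at 550 nm, 5-µm
  donut erythrocytes peaking at 570 nm inside elliptical vessels, seeded
  shot + read noise — together with ground-truth masks, so the whole
  pipeline is validated by parameter recovery.

## Worked example

```python
from eosinquant import NoiseModel, PhantomSpec, quantify_blood, render_phantom

phantom = render_phantom(PhantomSpec(seed=11, noise=NoiseModel(0, 0)))
result = quantify_blood(phantom.channels)
print(f"estimated blood: {result.blood_percent:.2f} %  "
      f"true: {phantom.true_blood_percent:.2f} %")
```

```
estimated blood: 10.41 %  true: 10.41 %
```

The phantom records its exact ground truth (here 10.41% of the tissue area
is erythrocyte); the pipeline recovers it from the two channel images
alone. With the default noise model the same scene yields 9.52% — a
0.9-point recovery error. The spectral side behaves the same way
(`examples/02_spectral_redshift.py`):

```
tissue emission peak: 550 nm  (n=130228)
blood emission peak:  570 nm  (n=15130)
red-shift:            20 nm
red-shift mask vs ground truth: 100.00 % pixel agreement
```

The `examples/` directory holds one short script per capability:
phantom rendering, spectral red-shift detection, blood quantification and
Huang thresholding. A thin CLI wraps the same functions:

```sh
eosinquant simulate --config spec.yaml -o out/
eosinquant spectra --stack out/stack.tif --roi out/blood_mask.tif -o spectra/
eosinquant quantify --fitc a.tif --tritc b.tif --pixel-size 0.32 -o results/
eosinquant threshold --input image.tif --method huang -o thr/
```

Every run writes a `run_manifest.json` (arguments, version, input
checksums); results land in a fixed-header CSV.

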