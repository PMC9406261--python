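# Methods

## The measurement

Eosin Y fluorescence in FFPE sections carries two usable signatures of
erythrocytes: a ~20-nm red-shift of the emission maximum (tissue ≈ 550 nm,
blood ≈ 570 nm) and higher brightness with a punctate, ~5-µm donut
morphology. `eosinquant` implements two routes to the blood signal:

1. **Spectral route** — a lambda stack (one co-registered plane per narrow
   emission band) is reduced to a per-pixel peak-emission-wavelength map;
   pixels whose peak lies at or beyond a cutoff (default 560 nm, the
   midpoint of the two maxima) are classified blood-like.
2. **Two-channel route** — standard FITC (emission 520–540 nm) and TRITC
   (570–610 nm) images are combined arithmetically and auto-thresholded to
   yield a tissue mask, a blood mask, and the blood-to-tissue area
   percentage. This is the quantitative output.

## The quantification pipeline

Given co-registered FITC image $F$ and TRITC image $T$:

1. $F_n = (F - \min F)/(\max F - \min F)$, likewise $T_n$ — per-channel
   min–max normalisation. This makes the two channels commensurable and
   the result invariant to detector gain; an optional percentile clip
   (`clip_percentiles`) is available but off by default.
2. $M = (F_n + T_n)/2$ — the mean image; everything fluorescent.
3. $B = \max(M - F_n, 0) = \max((T_n - F_n)/2, 0)$ — the blood-enhanced
   image, positive exactly where red emission exceeds green. Negative
   values are physically meaningless and clipped.
4. $B' = B - \mathrm{opening}(B, \mathrm{disk}(r))$, clipped at 0 —
   rolling-ball-style background subtraction by grey-scale morphological
   opening; default radius $r = 50$ px, far larger than an erythrocyte, so
   only smooth large-scale background is removed. The radius is exposed in
   the configuration.
5. Tissue mask = Huang threshold of $M$; blood mask = Huang threshold of
   $B'$. The tissue mask is taken from the mean image as-is, so blood
   pixels count toward the tissue denominator.
6. $\text{blood\%} = 100 \cdot |{\rm blood\ mask}| / |{\rm tissue\ mask}|$;
   areas are also reported in µm² when the pixel size is known.

Float intermediates are re-quantised to 256 grey levels (per-image
min–max, nearest-level rounding) before histogramming, so thresholds are
integer grey levels and runs are bit-reproducible. Foreground is the
strict inequality `level > t` — one convention, stated and tested. If the
blood-enhanced image is flat (range below 1e-9 on the unit scale of the
normalised channels — i.e. pure floating-point residue), the blood mask is
empty and the recorded blood threshold is null rather than a number
obtained by thresholding rounding noise.

## Huang thresholding

Implemented from the fuzzy-entropy definition. For threshold candidate
$t$, class means $\mu_0$ (levels $\le t$) and $\mu_1$ (levels $> t$) are
computed from the histogram; level $g$ receives membership
$u(g) = 1/(1 + |g-\mu_{class}|/C)$ with $C = g_{max} - g_{min}$, so
$u \in [1/2, 1]$. The index of fuzziness is
$E(t) = \frac{1}{N}\sum_g h(g)\, S(u(g))$ with
$S(u) = -u\ln u - (1-u)\ln(1-u)$ and $S(1) = 0$. Candidates run over
$[g_{min}, g_{max}-1]$ so both classes are non-empty.

$E(t)$ depends only on which occupied levels lie below the split, so it is
piecewise constant between occupied levels. The implementation evaluates
one representative per stretch and broadcasts, which makes the
smallest-$t$ tie-break exact instead of hostage to float rounding order.
The natural log is cosmetic (the minimiser is base-invariant). The test
suite checks the vectorised implementation against an independent
brute-force minimiser on hundreds of seeded histograms; this oracle
equivalence is the primary correctness surface. A trivial mean threshold
ships alongside for cross-checks; no other threshold families are
included.

## The phantom generator

The generator emulates the features of eosin-stained lung that the method
relies on; it is the package's validation instrument.

**Scene.** A smooth seeded random field thresholded at the
`tissue_fill_fraction` quantile gives the tissue mask (default 0.45 —
lung parenchyma is mostly alveolar air space, and the dark background
fraction is what anchors the automatic tissue threshold), unioned with
elliptical vessel regions. Erythrocytes are placed uniformly at random
inside the vessels (centres kept one cell-radius inside the vessel edge),
optionally with a minimum separation (`rbc_min_separation_um`, default 0;
rejection sampling, hard error if the packing is infeasible). Each cell is
a donut: outer diameter 5 µm, dark core at 40% of the diameter and 30% of
the ring intensity, with a per-cell brightness factor drawn uniformly from
[0.75, 1.0] — real cells take up eosin unevenly, and without this spread
the blood grey levels form an isolated histogram mode no real image has.

**Spectra.** Emission curves are single Gaussians — the simplest unimodal
shape reproducing the observed peaks and 20-nm shift: tissue
(peak 550 nm, σ 30 nm, amplitude 1.0) and blood (peak 570 nm, σ 30 nm,
amplitude 2.0; "brighter" is reported without a factor, so 2× is a
configurable stand-in). Erythrocytes *displace* the tissue fluorophore in
their footprint, so blood pixels carry a pure blood spectrum; with
additive mixing the grid argmax over blood would sit at 560 nm rather than
the observed 570 nm. Tissue intensity is textured by a smooth random field
rescaled to [0.7, 1.2]; the range straddles 1 so the brightest tissue
outshines the blood tail that leaks into the FITC band, as in real
sections where the green channel is tissue-dominated.

**Sampling and noise.** The lambda stack samples 480–690 nm at 10-nm
steps (22 bands); FITC/TRITC channels are band integrals over 520–540 and
570–610 nm. Noise is scaled Poisson (default 100 expected photons per
unit intensity, emulating a photon-counting detector) followed by
additive Gaussian read noise (σ 0.005) and a clip at 0. Masks and the
true blood percentage are fixed before noise is drawn, so ground truth is
noise-invariant. All randomness flows through the mandatory integer seed;
identical specs render bit-identical phantoms.

**What the phantom does not model.** No optical PSF or diffraction blur,
no 3-D sectioning, no haematoxylin channel or other fluorophores, no
collagen/SHG signal, no spatially correlated illumination drift, no
partial-volume softening of object edges. Passing recovery tests on
phantoms therefore demonstrates the algebra, thresholding and geometry of
the pipeline — not robustness to optical blur or to stains and artefacts
outside the model. On real slides the blood/tissue spectral contrast is
empirical, not Gaussian, and recovery error cannot be measured because
truth is unknown.

## Numerical and design choices

- Peak wavelength is the grid argmax (no sub-band interpolation — peaks
  are reported on the 10-nm grid); ties break to the lowest wavelength.
  Optional Gaussian smoothing acts along the wavelength axis only, never
  spatially, to avoid blurring 5-µm objects.
- The peak map's validity cut defaults to the Huang threshold of the
  λ-maximum-projection image; dim pixels carry NaN.
- Coordinates are row-major with the origin top-left; masks are 0/255 in
  files and boolean in memory; multi-page TIFF is the only raster format.
  Lambda-stack pages record their band centre in the page description, and
  OME-TIFF channel emission metadata is honoured; otherwise wavelengths
  must be given explicitly — never guessed.
- Stacks are stored as float64, so write/read round trips are bit-exact
  and re-running the spectral analysis on a saved stack reproduces the
  in-memory result.
- `quantify_blood` raises if the tissue mask is empty rather than return
  a division by zero; a constant input channel is an error at
  normalisation.

## Problem sizes

Reference scenes are 512 × 512 px (the acquisition size the method
targets after downsampling) with 22 spectral bands. The recovery study
spans ~2–30% true blood over 20 seeded phantoms per noise condition; unit
tests use 160 × 160 px scenes. Recovery on noise-free phantoms is exact
to well under a percentage point; with default noise the mean absolute
error is about 2 points, dominated by donut cores falling below the blood
threshold at high blood fractions.

## Known limitations

- The Huang threshold of the mean image assumes a visible dark background
  mode; fields with no background (tissue wall to wall) can flip the
  tissue threshold to the blood/tissue valley. This is a property of
  single-threshold fuzzy entropy, not of the implementation.
- Blood percentage is an area fraction; no per-object erythrocyte
  counting, no vessel-vs-haemorrhage discrimination, no whole-slide
  tiling.
- The background-subtraction radius (50 px) and the normalisation variant
  (plain min–max, no percentile clip) are defaults exposed in the
  configuration, not measured constants.
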