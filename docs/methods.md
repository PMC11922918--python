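# Methods

## Scope and data model

`leafvi` operates on a co-registered pair: an 8-bit RGB frame and an
ENVI-format reflectance cube (text header + raw binary in BSQ/BIL/BIP
interleave, float32 or uint16 samples). In memory the cube is a
`(lines, samples, bands)` array with a strictly increasing wavelength axis
in nm; all coordinates are 0-based `(row, col)` and all rectangles are
half-open `[x1, x2) × [y1, y2)` with x = col, y = row. Cubes are assumed
already calibrated to reflectance (white-reference correction is upstream
of this package). When a header carries no wavelength list the package
refuses to compute wavelength-addressed indices instead of assuming a
400–1000 nm axis: a silently wrong axis corrupts every index.

## Segmentation and ROI placement

**Greenness window.** Default HSV bounds are lower (60°, 0.15, 0.25), upper
(170°, 1.0, 1.0). Hue separates foliage from amber soil; the V lower bound
separates lit leaf from shadow. The bounds are fully configurable (CLI flags
and config file); on scenes with unusual illumination they are the first
thing to adjust.

**Grayscale and threshold.** The thresholded quantity is the green channel
of the masked image (background zeroed). After masking, the image is
essentially two populations — zeros and leaf green — so any monotone channel
works; green maximizes leaf contrast. Both Otsu (between-class variance
maximization over all 256 candidate levels) and the triangle method
(maximum perpendicular distance to the peak→farthest-occupied-bin line, bin
axis normalized by the peak–tail span, count axis by the peak count) are
implemented over an explicit 256-bin histogram. Binarization keeps
intensities *strictly greater* than the level. All ties resolve to the
lowest level/bin, so results are bit-reproducible.

**Component selection and midpoint.** Filled connected components
(8-connectivity by default) stand in for filled contours — identical areas
for solid blobs and a simpler correctness oracle. The largest component
wins; area ties go to the centroid nearest the image center, then to the
smallest top-left pixel in row-major order. The midpoint is the centroid
rounded to the nearest pixel (exact .5 rounds toward the lower index); if
the rounded pixel is not a member (concave leaf), the member pixel nearest
the centroid is used (ties: smaller row, then smaller col). A bounding-box
center mode exists behind the `midpoint="bbox"` flag for users who read
"midpoint" geometrically rather than as a mass center.

**ROI.** Default 10×10 px, minimum 2×2. An even size cannot be centered
exactly; the rectangle is placed as `x1 = c − size//2, x2 = x1 + size`
(and likewise for rows), which matches the reference placement
(center (256,256), size 10 → (251, 251, 261, 261)). The rectangle is
clamped to the frame; if any ROI pixel leaves the segmented mask the size
shrinks by 2 per dimension until contained or at minimum, at which point the
ROI is returned anyway with a logged warning and its mask-coverage fraction
— small leaves degrade gracefully rather than aborting a batch. Larger ROIs
average more pixels and hence carry less noise; 10×10 is the default
because it is the largest size whose VI values are still interchangeable
with smaller ones on homogeneous leaf tissue.

## Spectrum extraction and indices

The ROI mean is the arithmetic mean of **all** rectangle pixels per band
(parity with rectangle annotation in standard hyperspectral software); a
mask-restricted mean is available via the `mask` argument. Wavelengths
resolve to the nearest band center with no spectral interpolation; ties take
the lower band, out-of-range targets clamp, and a residual above 10 nm logs
a warning. ARI/CRI raise on non-positive reflectance (a loud flag for
calibration failures) rather than returning infinities; NDVI/PRI raise on a
zero denominator. The registry ships exactly NDVI, PRI, ARI and CRI;
`register_vi` adds new indices as (name, wavelengths, formula) triples.

## Validation statistics

Per-sample agreement uses the unsigned percent error |A − B|/|A| × 100 with
A the reference value, averaged arithmetically over samples (no signed or
median variant). The OLS layer (statsmodels) reports slope, intercept, the
correlation r *and* R² (they are often conflated in agreement plots), the
residual standard error, and evaluators for the t-based 95% confidence band
of the mean response and 95% prediction band of a new observation (the
prediction band always contains the confidence band). Reference and
candidate tables must carry identical id sequences — same ids, same order;
the module refuses to realign shuffled tables silently.

**Conditioning caveat.** Percent error is scale-invariant but ill-conditioned
near zero: if the ROI mean of each band carries noise σ_m = σ/√N (σ the
per-pixel reflectance noise, N the ROI pixel count), the absolute
uncertainty of PRI is ≈ √2·σ_m/(R531+R570) and of ARI ≈
√2·σ_m/R², independent of the index's true value. For an index whose true
value is comparable to that floor (PRI of healthy leaves is a few 0.01,
ARI crosses zero), |Δ|/|truth| can be arbitrarily large even when the
absolute agreement is excellent. Mean-percent-error summaries over batches
that include near-zero true values are therefore dominated by those
samples; R² and slope, which weight by variance rather than by reciprocal
magnitude, are the robust agreement measures in that regime.

## The phantom generator

The generator emulates the camera output the pipeline consumes: a 512×512
(128×128 in tests) canvas, 204 bands at λ_i = 400 + i·600/203 nm (even
spacing is an assumption; real sensors are close to but not exactly even),
an elliptical leaf with random center/axes/rotation, a shadow covering the
leaf on one side of a random half-plane, and a soil background.

**Spectral model.** The lit-leaf spectrum linearly interpolates anchor
reflectances at 400, 450, 510, 531, 550, 570, 650, 700, 715, 750, 860,
1000 nm. Anchors are drawn as: ρ_NIR ∈ [0.40, 0.55] (shared by
R750/R860/R1000), R650 ∈ [0.03, 0.12], R550 ∈ [0.08, 0.20], R400 = R450 ∈
[0.03, 0.05], R570 ∈ [0.8·R550, R550], R715 = (R700 + R750)/2; then drawn
index targets CRI* ∈ [3, 9], ARI* ∈ [−0.7, 0.7], PRI* ∈ [−0.03, 0.05] are
inverted exactly into the remaining anchors (R510 = 1/(CRI* + 1/R550),
R700 = 1/(1/R550 − ARI*), R531 = R570·(1+PRI*)/(1−PRI*)). This
anchor-and-invert design — rather than a radiative-transfer model like
PROSPECT — yields closed-form ground truth for precisely the four indices
under test, spanning the ranges observed on real leaves (the implied NDVI
lies in (0.54, 0.90)).

**Shadow and background.** Shadow multiplies the leaf spectrum by
s0 + s1·(λ−400)/600 (defaults s0 = 0.25, s1 = 0.10). The weak wavelength
dependence makes shaded normalized-difference indices genuinely differ from
lit ones; with s1 = 0 the model degenerates to gray attenuation, under
which NDVI/PRI are invariant and ARI/CRI scale by 1/s0 — both regimes are
asserted in tests. Background is the ramp 0.15 + 0.15·(λ−400)/600 (dim
amber). Gaussian noise of sd σ (default 0.005 reflectance units) is added
per pixel per band and the cube is clipped to ≥ 1e-4 so reciprocal indices
stay defined. The cube is stored float32 (camera parity); ground-truth
indices are computed from the float32-quantized lit spectrum at the nearest
bands, so a noiseless scene reproduces the truth to ~1e-12 through the full
pipeline.

**RGB render and self-consistency.** The RGB frame is rendered from the
cube: channel means over 620–680 (R), 520–580 (G), 430–490 nm (B), gain
1/0.6, clamped to [0, 1], quantized to 8 bits. Because the anchor ranges
admit draws whose rendering is too dark or insufficiently green for the
default greenness window, a draw is accepted only if the noiseless lit-leaf
rendering has hue in [63°, 167°], V ≥ 0.27 and S ≥ 0.20 and the shadow
rendering has V ≤ 0.23 (margins sized for per-pixel render noise against
the 60–170°/0.25 window); otherwise the generator redraws, up to 100
attempts. This keeps the generator consistent with the scene semantics it
advertises — a lit leaf the default pipeline accepts over a shadow it
rejects — while leaving the index-target inversion untouched.

**What the phantom does not emulate.** Real leaf optics (veins, petiole,
specular highlights, curvature), multi-leaf scenes, illumination geometry,
sensor smile/keystone, spatially correlated noise, and RGB/HSI
mis-registration. Passing phantom tests therefore demonstrates the
correctness of the algorithmic chain under its stated model, not
field robustness; on real images the HSV window and ROI size remain the
user-facing controls.

## Surrogate validation study

`scripts/acceptance.py` (and the session-scoped test fixture) builds 20
scenes at 128×128 / 204 bands / σ = 0.005 / shadow on — sized so the whole
study runs in seconds on one CPU while each ROI still averages 100 pixels —
pairs the automatic ROI with a same-size reference ROI jittered by up to
5 px (seeded, constrained to the lit-leaf mask), and reports the per-index
mean percent error (maximum over indices) and OLS R² (minimum over
indices). R² comes out ≈ 0.99 with slope ≈ 1 for all four indices. The
percent-error summary is faithful to its definition and therefore inherits
the near-zero conditioning problem above: NDVI and CRI sit well under 1–2%,
while batches containing near-zero PRI/ARI draws produce large
percent-error means despite absolute errors at the noise floor
(|ΔPRI| ≈ 2×10⁻³, |ΔARI| ≈ 0.02 under these conditions). This is a known
limitation of the error metric, reported as computed, not smoothed over.

## Numerical and degenerate-input choices

* Exact tie-breaks everywhere (lowest threshold level, lower wavelength
  band, centered-then-row-major component, lower-index rounding) — the
  pipeline is deterministic given inputs, config and seed.
* Histograms with fewer than two occupied bins raise a degenerate-histogram
  error; an empty greenness mask or empty thresholded mask raises an
  empty-segmentation error with the remediation hint (adjust the HSV
  window); both map to distinct CLI exit codes (3 for empty segmentation,
  2 for frame misalignment, 4 for invalid ROI coordinates, 5 for I/O).
* OLS with constant y reports slope 0 and R² 0; constant x or n < 3 raise.
* ENVI writing uses `repr()` for wavelengths, so header round trips are
  bit-exact; float32 cubes round-trip bit-exactly through all three
  interleaves.
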