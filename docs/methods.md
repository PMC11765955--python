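# Methods

## Scope and model

`vesselseg` segments bright tubular structures (contrast-filled blood
vessels) in 2-D grayscale angiographic images by classical filtering: no
learning, every step a deterministic function of the image and the
configuration. The pipeline assumes vessels are *brighter than their
surroundings* (the on-ridge cross-section curves downward, so the dominant
Hessian eigenvalue λ₂ is negative) and that their caliber falls inside the
chosen scale range. Images with dark vessels on bright background must be
inverted first.

## Vesselness filter

At scale σ the image is smoothed with a normalized Gaussian (reflect
boundary) and the Hessian is formed by exact central differences of the
smoothed image ([1, −2, 1] second differences and two-sided first
differences for the mixed term). Central differences after smoothing are
polynomially exact — a quadratic ramp yields its true constant second
derivative — which a sampled Gaussian-derivative kernel is not: the
sampled order-2 kernel's discrete sum is ≈ −8.7·10⁻⁵ rather than 0 at
σ = 2, producing a drift proportional to the local signal value. The two
routes agree to a few percent on smooth images and the Gaussian-derivative
convolution is kept in the test suite as an independent oracle.

Eigenvalues come from the closed form for symmetric 2×2 matrices,
λ± = (h₁₁+h₂₂)/2 ± √(((h₁₁−h₂₂)/2)² + h₁₂²), ordered by magnitude.
When the magnitudes tie (zero trace), λ₁ takes the smaller signed value so
the sign test on λ₂ is deterministic. The per-pixel response is

    V_σ = exp(−R_B² / 2α²) · (1 − exp(−S² / 2β²)),   λ₂ < 0
    V_σ = 0,                                          λ₂ ≥ 0

with R_B = |λ₁|/|λ₂| and S = √(λ₁²+λ₂²). λ₂ = 0 is folded into the zero
branch: R_B would be 0/0 there and a flat pixel carries no vessel
evidence. A squared-structuredness variant (S = λ₁²+λ₂²) is available
behind `structuredness_squared` for comparison studies. V is strictly
below 1 mathematically; at extreme S/β ratios the value rounds to 1.0 in
double precision.

### Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `sigma_min..sigma_max`, step | 1..8 px, 1 | scale set, inclusive of the endpoint; should bracket expected vessel half-widths |
| `alpha` | 0.5 | blobness sensitivity; smaller suppresses isotropic structures harder |
| `beta` | auto | structuredness sensitivity; auto = half the maximum S over the image, recomputed at each scale (the standard choice) |
| `gamma_normalize` | on | multiply second derivatives by σ²; without it the scale maximum is dominated by the smallest σ |
| `t_vesselness` | 0.15 | threshold on V |

With per-scale auto-β, each scale's structuredness term is renormalized by
that scale's own maximum. A consequence worth knowing: scales larger than
the vessel half-width still respond strongly in a broad band around the
vessel, so the thresholded vesselness mask is systematically wider than
the true tube — about 2 px per side at these defaults, identical to what
`skimage.filters.frangi` produces at the same threshold. See
"Performance envelope" below.

## Pipeline composition

Normalization maps min→0, max→1 (constant images map to all zeros rather
than failing). The global threshold (default 0.47, inclusive ≥) detects
the bright vessel body. On the vesselness branch, connected components
(8-neighbor rule by default) smaller than `min_size` = 64 px are discarded
as noise and the survivors closed with a 3×3 square structuring element.
The branches combine by pixelwise OR — so no later stage can delete a
threshold detection — followed by one optional closing pass
(`post_process`, on by default) to smooth edges.

Seeded region growing is the interactive alternative: the maximal
connected set containing the seed in which every pixel's intensity is
within `tolerance` of the *seed pixel's* intensity. The seed-relative rule
(rather than a running mean) is the simplest model of "similar intensity"
and makes the result independent of visit order, hence exactly
reproducible; the region is monotone in the tolerance.

## Morphological refinement chain

`morpho_refine` = Gaussian blur (σ 1.0) → threshold (0.5, ≥) → opening →
closing (both 3×3 square). The order is fixed: opening first removes
foreground noise that closing would otherwise weld to the vessel. The
chain accepts any [0, 1] map — a raw image, a vesselness map, or an
external model's probability output. Opening/closing use padded-border
definitions so the algebraic laws (anti-extensivity/extensivity,
idempotence) hold exactly including at image borders.

## Metrics

Dice = 2|X∩Y|/(|X|+|Y|) = 2TP/(2TP+FP+FN); the set and confusion forms
agree identically. Degenerate conventions: both masks empty → 1.0 (a
correctly predicted vessel-free image is perfect), exactly one empty →
0.0; precision/recall with zero denominator → 0.0. Percentiles use linear
interpolation. The annotation-round comparison scores a prediction against
two annotation rounds of the same images ("old", "new") and the rounds
against each other ("human"), the human series quantifying intra-observer
variability as a ceiling for model evaluation.

## Phantom generator

The phantom emulates what matters to this pipeline in a coronary CTA
slice: tubes of varying caliber with curvature and branching, non-tubular
bright distractors, and additive noise. Centerlines are unit-step random
walks whose per-step turn is a clipped Gaussian (bound `max_turn`,
default 0.08 rad/px) — tortuous but smooth; sinusoid and straight
families exist for controlled tests. Each tube has a flat bright core
(half the half-width) and a Gaussian shoulder (scale `cross_profile` ×
half-width, default 0.5), so the ground truth needs no arbitrary
iso-contour: the mask is exactly the pixels within the half-width of the
centerline. Distance to the centerline is the exact Euclidean distance
transform of the rasterized centerline, used for both the intensity
profile and the mask, making image and truth mutually consistent by
construction.

Defaults (background 0.10, vessel intensity 0.85, half-width 3–5 px at
256×256, noise σ 0.02) put the tube edge at intensity ≈ 0.55, above the
0.47 operating threshold, and give vessel-to-background contrast typical
of contrast-enhanced CTA. What the phantom does *not* model: CT
reconstruction artifacts, beam hardening, partial-volume blur that varies
with orientation, anatomical context (myocardium, chambers), or
calcifications abutting the lumen. Passing phantom tests therefore
demonstrates the geometry of the method — tube detection, blob
suppression, rotation invariance — not clinical-grade accuracy.

## Performance envelope

Numbers below are recomputed by `scripts/acceptance.py` (ten 256×256
single-tube phantoms per condition; all randomness seeded):

* The pipeline's recall on phantom tubes is ≈ 1.0 and its Dice ≈ 0.80 at
  noise σ of both 0 and 0.05. The gap to 1 is almost entirely the ~2 px
  vesselness-mask fattening described above, not noise sensitivity; on a
  W-px-wide vessel the achievable Dice is roughly 2W/(2W+4).
* Tube-centerline vesselness exceeds the response at an equal-brightness
  blob's center by ~7×.
* Mean interior response of a straight tube changes by ~5% under 45°
  rotation (discretization only; the eigenvalue analysis itself is
  rotation-invariant).
* Refining a mask with 1% flipped pixels raises Dice from ≈ 0.86 to
  ≈ 0.998.
* Seeded region growing with tolerance 0.3 recovers noise-free phantom
  tubes exactly (Dice 1.0): the tolerance cut at intensity 0.55 coincides
  with the mask-boundary intensity by the phantom's construction. This is
  a property of the noise-free phantom, not a general claim.

## Numerical and degenerate-case decisions

* Scale grid: closed interval; σ_max included whenever it lies on the grid.
* Eigenvalue tie-break at zero trace: λ₁ = min signed value.
* Auto-β on a perfectly flat scale (max S = 0): the scale contributes zero
  response instead of dividing by zero.
* All thresholds are inclusive (≥), including mask re-reading (≥ 128 for
  non-binary files).
* COCO polygons are rasterized by the pixel-center-inside rule (centers at
  x = c + 0.5, y = r + 0.5), vertices clipped to the image rectangle;
  overlapping polygons merge by union.
* Masks on disk are 0/255 8-bit PNG; images 16-bit PNG; soft maps 32-bit
  float TIFF; scores CSV at 4 decimals.

## Known limitations

* 2-D only; no 3-D vesselness.
* The thresholded vesselness mask over-segments vessel walls by ~σ/4 of
  the largest scale; applications needing tight walls should lower
  σ_max toward the expected half-width, raise `t_vesselness`, or refine
  with a wall-aware post-process.
* Region growing uses a single seed and global tolerance; intensity drift
  along a long vessel can truncate the region.
* The global threshold presumes the normalization basis of the target
  data; on images whose histogram differs strongly from the phantoms',
  `t_global` must be re-tuned.
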