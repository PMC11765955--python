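# vesselseg

Classical multi-scale blood-vessel segmentation for 2-D angiographic
images, with synthetic vascular phantoms and evaluation tooling.

Coronary CT angiography (CTA) slices show contrast-filled vessels as
bright, curved, branching tubes on a darker noisy background. Before (or
instead of) training a neural segmenter, a classical pipeline can extract
these tubes directly from the intensity structure. `vesselseg` implements
that pipeline as a library with a thin CLI, for researchers building vessel
segmentation or annotation-quality studies who need a reproducible,
parameter-transparent baseline — and, because clinical CTA datasets are
rarely shareable, a phantom generator that produces angiogram-like images
with exact ground truth.

## The method

The pipeline fuses two complementary detections of bright vessels:

1. **Global thresholding.** The image is normalized to [0, 1] and
   thresholded at `T = 0.47`: `Tmask = I_norm ≥ T`.
2. **Multi-scale Frangi vesselness.** At each scale σ ∈ {1, …, 8} px the
   Hessian of the Gaussian-smoothed image is computed, its eigenvalues
   ordered by magnitude (|λ₁| ≤ |λ₂|), and the response

       V_σ = 0                                           if λ₂ ≥ 0
       V_σ = exp(−R_B²/2α²) · (1 − exp(−S²/2β²))         otherwise

   with blobness ratio `R_B = |λ₁|/|λ₂|` (≈0 on tubes, ≈1 on blobs) and
   structuredness `S = √(λ₁²+λ₂²)` (small in flat noise). The multi-scale
   map is `V = max_σ V_σ`, thresholded at 0.15, cleaned of connected
   components smaller than 64 px, and gap-filled by morphological closing
   (`Fmask`).

The final mask is `Tmask ∨ Fmask` with one more closing pass. Also
provided: seeded region growing (segment a vessel from one reference pixel
by intensity similarity), the standalone refinement chain Gaussian blur →
threshold → opening → closing for any soft map, Dice / precision / recall
with percentile summaries, intra-observer annotation-round comparison, and
COCO-polygon-to-mask conversion.

## Worked example

```python
from vesselseg import PhantomSpec, generate_phantom, preprocess_pipeline, score_pair

image, truth = generate_phantom(PhantomSpec(noise_sigma=0.0, rng_seed=0))
pred = preprocess_pipeline(image)          # default PipelineConfig
print(score_pair(pred, truth))
```

prints

```
{'dice': 0.8093, 'precision': 0.6798, 'recall': 1.0000}
```

Recall 1.0 means every true vessel pixel was found; precision 0.68 means
the mask is wider than the true tube — the thresholded vesselness map
extends a couple of pixels past the vessel wall, the classical filter's
trade of boundary sharpness for robust detection. The same filter is
sharply selective for *shape*: on a phantom with an equal-brightness
isotropic blob (`examples/02_vesselness_filter.py`),

```
mean response on tube centerline: 0.8584
response at blob center:          0.1209
suppression ratio: 7.1x
```

Each script in `examples/` demonstrates one capability end to end
(phantom generation, vesselness, full pipeline, region growing,
morphological refinement, annotation-round comparison). The same stages
are reachable from the shell:

```sh
vesselseg phantom --seed 7 --out-image img.png --out-mask truth.png
vesselseg preprocess img.png --mode combined --out pred.png
vesselseg evaluate --pred-dir preds/ --truth-dir truths/ --out scores.csv
```

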