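"""Generate a synthetic angiogram-like phantom with exact ground truth.

The phantom emulates a 2-D coronary CTA slice: bright curved tubes (the
contrast-filled vessels) on a darker noisy background, plus an isotropic
bright blob standing in for non-tubular structures such as bone
cross-sections.  The returned mask is the exact set of pixels within the
tube half-width of the centerline — the ground truth later stages are
scored against.
"""

from vesselseg import PhantomSpec, generate_phantom

spec = PhantomSpec(
    image_size=(256, 256),
    n_vessels=2,
    branch_probability=0.5,
    n_distractor_blobs=1,
    noise_sigma=0.02,
    rng_seed=42,
)
image, mask = generate_phantom(spec)

print(f"image intensity range: [{image.min():.3f}, {image.max():.3f}]")
print(f"vessel pixels: {int(mask.sum())} of {mask.size} "
      f"({100 * mask.mean():.1f}% of the image)")
print(f"mean intensity on vessels:  {image[mask].mean():.3f}")
print(f"mean intensity off vessels: {image[~mask].mean():.3f}")
# Vessels are markedly brighter than the background — the bright-vessel
# condition the vesselness filter and the global threshold both rely on.
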