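"""Binary-mask operations and the end-to-end pre-processing pipeline.

The pipeline combines two complementary detections of bright vessels:

1. a global intensity threshold T on the normalized image (the bulk of a
   contrast-filled vessel is simply bright), and
2. the multi-scale Frangi vesselness map, thresholded, cleaned of small
   connected components ("region filling": components below ``min_size``
   pixels are discarded as noise) and gap-filled by morphological closing.

The two binary masks are merged by pixelwise logical OR, optionally
followed by one more closing pass to smooth edges.  A seeded
region-growing segmenter is provided as the interactive alternative: from
a user-chosen reference pixel inside a vessel it floods to all connected
pixels of similar intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import closing as _closing
from skimage.morphology import disk, footprint_rectangle

from .frangi import (
    FrangiParams,
    multiscale_vesselness,
    normalize_intensity,
    threshold_vesselness,
)

__all__ = [
    "PipelineConfig",
    "ComponentLabeling",
    "global_threshold",
    "label_components",
    "filter_components",
    "morphological_closing",
    "combine_masks",
    "region_grow",
    "preprocess_pipeline",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def structuring_element(shape: str, size: int) -> np.ndarray:
    """Square or disk footprint of odd side length ``size``."""
    if size < 1 or size % 2 == 0:
        raise ValueError("structuring element size must be odd and >= 1")
    if shape == "square":
        return footprint_rectangle((size, size))
    if shape == "disk":
        return disk(size // 2)
    raise ValueError(f"unknown structuring element shape {shape!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the pre-processing pipeline.

    ``t_global`` defaults to 0.47, the operating point used on normalized
    coronary CTA slices.  ``min_size`` and the structuring element govern
    the region-filling step on the vesselness branch; ``post_process``
    adds one closing pass on the combined mask.
    """

    t_global: float = 0.47
    frangi: FrangiParams = field(default_factory=FrangiParams)
    min_size: int = 64
    connectivity: int = 8
    closing_se_shape: str = "square"
    closing_se_size: int = 3
    post_process: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.t_global <= 1:
            raise ValueError("t_global must lie in [0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        structuring_element(self.closing_se_shape, self.closing_se_size)


@dataclass(frozen=True)
class ComponentLabeling:
    """Connected-component labels (0 = background) and per-label sizes."""

    labels: np.ndarray
    sizes: np.ndarray  # sizes[k] is the pixel count of label k+1

    @property
    def n_components(self) -> int:
        return len(self.sizes)


def global_threshold(image_norm: np.ndarray, t: float) -> np.ndarray:
    """Foreground where the normalized intensity reaches ``t`` (inclusive)."""
    if not 0 <= t <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(image_norm) >= t


def label_components(mask: np.ndarray, connectivity: int = 8) -> ComponentLabeling:
    """Label connected components under the 4- or 8-neighbor rule."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndi.label(np.asarray(mask, dtype=bool), structure=_STRUCTURES[connectivity])
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return ComponentLabeling(labels=labels, sizes=sizes)


def filter_components(
    mask: np.ndarray, min_size: int, connectivity: int = 8
) -> np.ndarray:
    """Keep components of at least ``min_size`` pixels; drop smaller ones as noise."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    lab = label_components(mask, connectivity)
    if lab.n_components == 0:
        return np.zeros_like(np.asarray(mask, dtype=bool))
    keep = np.concatenate([[False], lab.sizes >= min_size])
    return keep[lab.labels]


def morphological_closing(mask: np.ndarray, se_shape: str = "square", se_size: int = 3) -> np.ndarray:
    """Dilation then erosion; fills gaps smaller than the structuring element."""
    se = structuring_element(se_shape, se_size)
    return _closing(np.asarray(mask, dtype=bool), se)


def combine_masks(tmask: np.ndarray, fmask: np.ndarray) -> np.ndarray:
    """Pixelwise logical OR of the threshold and Frangi branches."""
    tmask = np.asarray(tmask, dtype=bool)
    fmask = np.asarray(fmask, dtype=bool)
    if tmask.shape != fmask.shape:
        raise ValueError("mask shapes differ")
    return tmask | fmask


def region_grow(
    image: np.ndarray,
    seed: tuple[int, int],
    tolerance: float,
    connectivity: int = 8,
) -> np.ndarray:
    """Grow a region of similar intensity from a seed pixel.

    Returns the maximal connected set containing ``seed`` in which every
    pixel's intensity differs from the seed pixel's intensity by at most
    ``tolerance``.  Coordinates are (row, col), origin top-left.
    """
    image = np.asarray(image, dtype=float)
    r, c = seed
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError(f"seed {seed} outside image bounds {image.shape}")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    similar = np.abs(image - image[r, c]) <= tolerance
    labels, _ = ndi.label(similar, structure=_STRUCTURES[connectivity])
    return labels == labels[r, c]


def preprocess_pipeline(image: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Run the full classical segmentation pipeline on a raw grayscale image.

    Normalize -> global threshold (Tmask) in parallel with multi-scale
    vesselness -> vesselness threshold (Vmask) -> small-component removal
    -> closing (Fmask); combine Tmask OR Fmask (Cmask); optionally one more
    closing pass.  Deterministic for fixed input and config.
    """
    if config is None:
        config = PipelineConfig()
    inorm = normalize_intensity(image)
    tmask = global_threshold(inorm, config.t_global)
    v = multiscale_vesselness(inorm, config.frangi)
    vmask = threshold_vesselness(v, config.frangi.t_vesselness)
    filled = filter_components(vmask, config.min_size, config.connectivity)
    fmask = morphological_closing(filled, config.closing_se_shape, config.closing_se_size)
    cmask = combine_masks(tmask, fmask)
    if config.post_process:
        cmask = morphological_closing(cmask, config.closing_se_shape, config.closing_se_size)
    return cmask
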