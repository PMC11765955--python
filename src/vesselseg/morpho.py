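"""Morphological refinement chain for soft segmentation maps.

A four-stage post-processor applicable to any [0, 1] map — a raw image, a
vesselness map, or a network's probability output: Gaussian blur, binarize
at a threshold, morphological opening (erosion then dilation, removing
small foreground noise), then morphological closing (dilation then
erosion, filling gaps so vessels stay continuous).  The stage order is
fixed; every stage's parameters are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing as _closing
from skimage.morphology import opening as _opening

from .frangi import gaussian_smooth
from .maskops import morphological_closing, structuring_element

__all__ = ["MorphoParams", "morphological_opening", "morpho_refine"]


@dataclass(frozen=True)
class MorphoParams:
    blur_sigma: float = 1.0
    threshold: float = 0.5
    open_se_shape: str = "square"
    open_se_size: int = 3
    close_se_shape: str = "square"
    close_se_size: int = 3

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        structuring_element(self.open_se_shape, self.open_se_size)
        structuring_element(self.close_se_shape, self.close_se_size)


def morphological_opening(mask: np.ndarray, se_shape: str = "square", se_size: int = 3) -> np.ndarray:
    """Erosion then dilation; removes foreground detail smaller than the SE."""
    se = structuring_element(se_shape, se_size)
    return _opening(np.asarray(mask, dtype=bool), se)


def morpho_refine(soft_map: np.ndarray, params: MorphoParams | None = None) -> np.ndarray:
    """Blur -> threshold (>=) -> opening -> closing, in that fixed order."""
    if params is None:
        params = MorphoParams()
    blurred = gaussian_smooth(np.asarray(soft_map, dtype=float), params.blur_sigma)
    mask = blurred >= params.threshold
    mask = morphological_opening(mask, params.open_se_shape, params.open_se_size)
    return morphological_closing(mask, params.close_se_shape, params.close_se_size)
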