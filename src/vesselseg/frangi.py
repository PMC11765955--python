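"""Multi-scale Frangi vesselness filtering for 2-D images.

The vesselness filter scores every pixel by how tube-like the local
second-order intensity structure is.  At each smoothing scale sigma the
Hessian matrix of the Gaussian-smoothed image is built, its eigenvalues
(lambda1, lambda2, ordered |lambda1| <= |lambda2|) are computed in closed
form, and two geometric measures follow:

* blobness ratio  R_B = |lambda1| / |lambda2|  — near 0 on elongated
  ridges, near 1 on isotropic blobs;
* structuredness  S = sqrt(lambda1^2 + lambda2^2) — the Frobenius norm of
  the eigenvalue vector, small in flat/noisy regions.

For bright vessels on a dark background the ridge cross-section curves
downward, so lambda2 < 0 on-vessel; pixels with lambda2 >= 0 get zero
response.  Elsewhere

    V_sigma = exp(-R_B^2 / (2 alpha^2)) * (1 - exp(-S^2 / (2 beta^2)))

and the multi-scale map is the pixelwise maximum of V_sigma over the scale
set.  The response always lies in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "FrangiParams",
    "HessianField",
    "EigenPair",
    "normalize_intensity",
    "gaussian_smooth",
    "hessian_at_scale",
    "eigenvalues_2x2",
    "vesselness_response",
    "multiscale_vesselness",
    "threshold_vesselness",
]


@dataclass(frozen=True)
class FrangiParams:
    """Parameters of the multi-scale vesselness filter.

    Attributes
    ----------
    sigma_min, sigma_max, sigma_step : float
        Gaussian scale set in pixels: ``{sigma_min, sigma_min + step, ...}``
        up to and including ``sigma_max`` when the grid reaches it.
    alpha : float
        Sensitivity of the blobness term; smaller alpha punishes blob-like
        structures harder.
    beta : float or None
        Sensitivity of the structuredness term.  ``None`` selects the
        standard automatic choice: half the maximum structuredness over the
        image, recomputed at each scale.
    t_vesselness : float
        Threshold in [0, 1] applied by :func:`threshold_vesselness`.
    gamma_normalize : bool
        Multiply second derivatives by sigma^2 so responses are comparable
        across scales (without it the scale maximum is dominated by the
        smallest sigma).
    structuredness_squared : bool
        Use S^2 = lambda1^2 + lambda2^2 instead of its square root.
    """

    sigma_min: float = 1.0
    sigma_max: float = 8.0
    sigma_step: float = 1.0
    alpha: float = 0.5
    beta: float | None = None
    t_vesselness: float = 0.15
    gamma_normalize: bool = True
    structuredness_squared: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.sigma_min <= self.sigma_max):
            raise ValueError("require 0 < sigma_min <= sigma_max")
        if self.sigma_step <= 0:
            raise ValueError("sigma_step must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive (or None for auto)")
        if not 0 <= self.t_vesselness <= 1:
            raise ValueError("t_vesselness must lie in [0, 1]")

    @property
    def scales(self) -> np.ndarray:
        """The scale grid, inclusive of sigma_max when it lies on the grid."""
        n = int(np.floor((self.sigma_max - self.sigma_min) / self.sigma_step + 1e-9)) + 1
        return self.sigma_min + self.sigma_step * np.arange(n)


@dataclass(frozen=True)
class HessianField:
    """Second-order partial derivatives of a smoothed image at one scale."""

    ixx: np.ndarray
    ixy: np.ndarray
    iyy: np.ndarray

    def __post_init__(self) -> None:
        if not (self.ixx.shape == self.ixy.shape == self.iyy.shape):
            raise ValueError("Hessian component shapes differ")


@dataclass(frozen=True)
class EigenPair:
    """Per-pixel Hessian eigenvalues ordered by magnitude, |lambda1| <= |lambda2|."""

    lambda1: np.ndarray
    lambda2: np.ndarray


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Linearly rescale intensities to [0, 1].

    A constant image maps to all zeros rather than failing on the zero
    intensity range.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with a normalized 2-D Gaussian, reflecting at the borders."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndi.gaussian_filter(np.asarray(image, dtype=float), sigma, mode="reflect")


def hessian_at_scale(
    image: np.ndarray, sigma: float, gamma_normalize: bool = True
) -> HessianField:
    """Hessian of the sigma-smoothed image: smooth, then central differences.

    Derivatives are taken along axis 1 (x = columns) and axis 0 (y = rows).
    Central differences after Gaussian smoothing are polynomially exact
    (a quadratic ramp yields its true constant second derivative), which a
    sampled Gaussian-derivative kernel is not.  With ``gamma_normalize``
    each component is multiplied by sigma^2 (scale-normalized derivatives).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    smoothed = gaussian_smooth(image, sigma)
    d2 = np.array([1.0, -2.0, 1.0])
    d1 = np.array([-0.5, 0.0, 0.5])
    ixx = ndi.correlate1d(smoothed, d2, axis=1, mode="reflect")
    iyy = ndi.correlate1d(smoothed, d2, axis=0, mode="reflect")
    ixy = ndi.correlate1d(
        ndi.correlate1d(smoothed, d1, axis=1, mode="reflect"), d1, axis=0, mode="reflect"
    )
    if gamma_normalize:
        s2 = sigma * sigma
        ixx, ixy, iyy = ixx * s2, ixy * s2, iyy * s2
    return HessianField(ixx=ixx, ixy=ixy, iyy=iyy)


def eigenvalues_2x2(h: HessianField) -> EigenPair:
    """Closed-form eigenvalues of the symmetric 2x2 Hessian, per pixel.

    lambda_pm = (ixx+iyy)/2 +- sqrt(((ixx-iyy)/2)^2 + ixy^2), assigned so
    that |lambda1| <= |lambda2|.  When the magnitudes tie (trace zero),
    lambda1 takes the smaller signed value so the sign test on lambda2 is
    deterministic.
    """
    half_trace = (h.ixx + h.iyy) / 2.0
    disc = np.sqrt(((h.ixx - h.iyy) / 2.0) ** 2 + h.ixy**2)
    lo = half_trace - disc
    hi = half_trace + disc
    # |hi| >= |lo| iff half_trace >= 0; tie (half_trace == 0) keeps lo first.
    swap = np.abs(lo) > np.abs(hi)
    lambda1 = np.where(swap, hi, lo)
    lambda2 = np.where(swap, lo, hi)
    return EigenPair(lambda1=lambda1, lambda2=lambda2)


def vesselness_response(
    lambda1: np.ndarray | float,
    lambda2: np.ndarray | float,
    alpha: float,
    beta: float,
    structuredness_squared: bool = False,
) -> np.ndarray | float:
    """Single-scale vesselness from the ordered eigenvalues.

    Zero wherever lambda2 >= 0 (including the degenerate flat case
    lambda2 = 0, which carries no vessel evidence); otherwise the product of
    the blobness and structuredness terms.  Never divides by zero; the
    result lies in [0, 1).
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    on_ridge = l2 < 0
    safe_l2 = np.where(on_ridge, l2, -1.0)
    rb2 = (l1 / safe_l2) ** 2
    s2 = l1 * l1 + l2 * l2
    if structuredness_squared:
        s2 = s2 * s2  # S = lambda1^2 + lambda2^2 variant; the term uses S^2
    v = np.exp(-rb2 / (2.0 * alpha**2)) * (1.0 - np.exp(-s2 / (2.0 * beta**2)))
    out = np.where(on_ridge, v, 0.0)
    return out if out.ndim else float(out)


def _single_scale(image: np.ndarray, sigma: float, params: FrangiParams) -> np.ndarray:
    h = hessian_at_scale(image, sigma, params.gamma_normalize)
    eig = eigenvalues_2x2(h)
    beta = params.beta
    if beta is None:
        s = np.sqrt(eig.lambda1**2 + eig.lambda2**2)
        if params.structuredness_squared:
            s = s * s
        smax = float(s.max())
        if smax == 0.0:  # perfectly flat image at this scale: no response
            return np.zeros(image.shape)
        beta = smax / 2.0
    return np.asarray(
        vesselness_response(
            eig.lambda1, eig.lambda2, params.alpha, beta, params.structuredness_squared
        )
    )


def multiscale_vesselness(image: np.ndarray, params: FrangiParams) -> np.ndarray:
    """Pixelwise maximum of single-scale vesselness over the scale set."""
    image = np.asarray(image, dtype=float)
    v = np.zeros(image.shape)
    for sigma in params.scales:
        np.maximum(v, _single_scale(image, float(sigma), params), out=v)
    return v


def threshold_vesselness(v: np.ndarray, t: float) -> np.ndarray:
    """Binary mask of pixels whose vesselness reaches the threshold (>=)."""
    if not 0 <= t <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(v) >= t
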