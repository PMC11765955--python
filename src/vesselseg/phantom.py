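"""Synthetic 2-D angiogram-like phantoms with exact ground-truth vessel masks.

Real coronary CTA slices show bright, curved, occasionally branching tubular
vessels of varying caliber on a darker, noisy background, together with
bright non-tubular structures (bone cross-sections, calcifications) that a
tubularity filter must suppress.  The phantom emulates exactly those
features:

* centerlines are smooth random walks with a bounded turn rate (tortuous
  "curves and bends"), or sinusoids / straight lines for controlled tests;
* each tube has a flat bright core and a Gaussian shoulder; the ground
  truth is unambiguous — every pixel within the half-width of the
  centerline, shoulder included;
* optional isotropic Gaussian blobs act as non-tubular distractors;
* additive Gaussian noise is applied after compositing and the image is
  clipped to [0, 1].

The generator is a pure function of (spec, seed): identical inputs yield
bit-identical image and mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["PhantomSpec", "generate_phantom"]

#: fraction of the half-width occupied by the flat bright core
CORE_FRACTION = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic angiogram.

    Attributes
    ----------
    image_size : (rows, cols)
        Output shape in pixels; each dimension must be at least 32.
    n_vessels : int
        Number of independent tubes.
    centerline_model : str
        ``"random_walk"`` (smooth, curvature-bounded), ``"sinusoid"``, or
        ``"straight"`` (horizontal through the image center; for tests).
    max_turn : float
        Curvature bound for the random walk, radians per unit arc length.
    width_range : (float, float)
        Tube half-width bounds in pixels; sampled uniformly per vessel.
    branch_probability : float
        Chance in [0, 1] that a vessel spawns one side branch.
    vessel_intensity : float
        Peak tube brightness on the [0, 1] scale.
    cross_profile : float
        Gaussian falloff scale of the tube shoulder, relative to the
        half-width.
    n_distractor_blobs : int
        Number of isotropic Gaussian blobs (non-tubular distractors).
    blob_intensity : float
        Peak blob brightness.
    noise_sigma : float
        Standard deviation of additive Gaussian noise on the [0, 1] scale.
    background_level : float
        Base intensity of the background.
    rng_seed : int
        Seed of the private random generator.
    """

    image_size: tuple[int, int] = (256, 256)
    n_vessels: int = 1
    centerline_model: str = "random_walk"
    max_turn: float = 0.08
    width_range: tuple[float, float] = (3.0, 5.0)
    branch_probability: float = 0.0
    vessel_intensity: float = 0.85
    cross_profile: float = 0.5
    n_distractor_blobs: int = 0
    blob_intensity: float = 0.85
    noise_sigma: float = 0.02
    background_level: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.image_size
        if r < 32 or c < 32:
            raise ValueError("image_size must be at least 32 in each dimension")
        lo, hi = self.width_range
        if not (0 < lo <= hi) or hi >= min(r, c) / 2:
            raise ValueError("width_range must be positive and fit the image")
        if self.n_vessels < 0 or self.n_distractor_blobs < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.branch_probability <= 1:
            raise ValueError("branch_probability must lie in [0, 1]")
        if self.centerline_model not in ("random_walk", "sinusoid", "straight"):
            raise ValueError(f"unknown centerline model {self.centerline_model!r}")


def _walk(
    start: np.ndarray,
    heading: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
    max_turn: float,
    max_len: float,
) -> np.ndarray:
    """Unit-step random walk with clipped Gaussian turns; stops at the border."""
    pts = [start.copy()]
    p = start.copy()
    h = heading
    margin = 1.0
    for _ in range(int(max_len)):
        h += float(np.clip(rng.normal(0.0, max_turn / 2.0), -max_turn, max_turn))
        p = p + np.array([np.sin(h), np.cos(h)])
        if not (margin <= p[0] < shape[0] - margin and margin <= p[1] < shape[1] - margin):
            break
        pts.append(p.copy())
    return np.array(pts)


def _centerline(
    spec: PhantomSpec, rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    """Sample one centerline as an (n, 2) array of (row, col) points."""
    r, c = shape
    diag = float(np.hypot(r, c))
    if spec.centerline_model == "straight":
        cols = np.arange(0, c - 0.5, 0.5)  # spans the full width, both borders
        return np.column_stack([np.full_like(cols, np.floor(r / 2.0)), cols])
    if spec.centerline_model == "sinusoid":
        cols = np.arange(1, c - 1, 0.5)
        amp = rng.uniform(0.05, 0.15) * r
        period = rng.uniform(0.5, 1.5) * c
        phase = rng.uniform(0, 2 * np.pi)
        rows = r / 2.0 + amp * np.sin(2 * np.pi * cols / period + phase)
        keep = (rows >= 1) & (rows < r - 1)
        return np.column_stack([rows[keep], cols[keep]])
    # random walk: start on a random border region heading inward
    start = np.array([rng.uniform(0.2, 0.8) * r, 1.0])
    heading = rng.uniform(-0.4, 0.4)  # roughly +col direction
    return _walk(start, heading, shape, rng, spec.max_turn, 2 * diag)


def _distance_to_curve(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Exact Euclidean distance from each pixel to the rasterized curve."""
    raster = np.ones(shape, dtype=bool)
    rr = np.clip(np.round(points[:, 0]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(points[:, 1]).astype(int), 0, shape[1] - 1)
    raster[rr, cc] = False
    return ndi.distance_transform_edt(raster)


def _tube_fields(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Brightness field (relative to background) and exact mask of all tubes."""
    shape = spec.image_size
    bright = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    amplitude = spec.vessel_intensity - spec.background_level
    curves: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.n_vessels):
        pts = _centerline(spec, rng, shape)
        w = float(rng.uniform(*spec.width_range))
        curves.append((pts, w))
        if len(pts) > 10 and rng.random() < spec.branch_probability:
            i = rng.integers(len(pts) // 4, 3 * len(pts) // 4)
            d = pts[min(i + 1, len(pts) - 1)] - pts[i - 1]
            heading = float(np.arctan2(d[0], d[1]))
            heading += float(rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 0.8))
            branch = _walk(
                pts[i].copy(), heading, shape, rng, spec.max_turn, np.hypot(*shape)
            )
            curves.append((branch, 0.8 * w))
    for pts, w in curves:
        if len(pts) < 2:
            continue
        d = _distance_to_curve(pts, shape)
        core = CORE_FRACTION * w
        shoulder = max(spec.cross_profile * w, 1e-6)
        profile = np.where(
            d <= core, 1.0, np.exp(-((d - core) ** 2) / (2.0 * shoulder**2))
        )
        tube_mask = d <= w
        np.maximum(bright, amplitude * profile * tube_mask, out=bright)
        mask |= tube_mask
    return bright, mask


def _blob_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = spec.image_size
    bright = np.zeros(shape)
    amplitude = spec.blob_intensity - spec.background_level
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    for _ in range(spec.n_distractor_blobs):
        cr = rng.uniform(0.15, 0.85) * shape[0]
        cc = rng.uniform(0.15, 0.85) * shape[1]
        radius = rng.uniform(3.0, 6.0)
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        np.maximum(bright, amplitude * np.exp(-d2 / (2.0 * radius**2)), out=bright)
    return bright


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom image and its exact ground-truth vessel mask.

    Returns
    -------
    image : ndarray of float in [0, 1]
        Background + tubes + blobs + Gaussian noise, clipped.
    mask : ndarray of bool
        Pixels within the tube half-width of any centerline.  Blobs and
        noise never enter the mask.
    """
    rng = np.random.default_rng(spec.rng_seed)
    tubes, mask = _tube_fields(spec, rng)
    blobs = _blob_field(spec, rng)
    image = spec.background_level + np.maximum(tubes, blobs)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.image_size)
    return np.clip(image, 0.0, 1.0), mask
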