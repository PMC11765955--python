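"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (pure-Python flood fill, direct
convolution, scanline rasterization) and shares no code with the package,
so agreement is evidence of correctness rather than self-consistency.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Breadth-first flood fill; returns the set of pixels of each component."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    pr, pc = stack.pop()
                    comp.add((pr, pc))
                    for dr, dc in nbrs:
                        nr, nc = pr + dr, pc + dc
                        if (
                            0 <= nr < mask.shape[0]
                            and 0 <= nc < mask.shape[1]
                            and mask[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def direct_gaussian_convolve(image: np.ndarray, sigma: float) -> np.ndarray:
    """Direct (non-separable) convolution with a truncated normalized Gaussian,
    reflect boundary, radius 4 sigma — the definition, evaluated literally.
    numpy's "symmetric" pad is the edge-including reflection."""
    image = np.asarray(image, dtype=float)
    rad = int(4 * sigma + 0.5)
    ax = np.arange(-rad, rad + 1)
    kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    kernel /= kernel.sum()
    padded = np.pad(image, rad, mode="symmetric")
    out = np.zeros_like(image)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = np.sum(padded[r : r + 2 * rad + 1, c : c + 2 * rad + 1] * kernel)
    return out


def scanline_rasterize(xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd scanline polygon fill testing each pixel center (c+0.5, r+0.5)."""
    xy = np.asarray(xy, dtype=float)
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    n = len(xy)
    for r in range(h):
        y = r + 0.5
        xs = []
        for i in range(n):
            x1, y1 = xy[i]
            x2, y2 = xy[(i + 1) % n]
            if (y1 <= y < y2) or (y2 <= y < y1):
                xs.append(x1 + (y - y1) * (x2 - x1) / (y2 - y1))
        xs.sort()
        for j in range(0, len(xs) - 1, 2):
            lo = int(np.ceil(xs[j] - 0.5))
            hi = int(np.floor(xs[j + 1] - 0.5 - 1e-12))
            lo, hi = max(lo, 0), min(hi, w - 1)
            if lo <= hi:
                out[r, lo : hi + 1] = True
    return out
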