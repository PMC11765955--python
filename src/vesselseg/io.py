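"""Image, mask, and annotation I/O.

Conventions: grayscale images are read into float arrays on the [0, 1]
scale by bit depth (8-bit / 255, 16-bit / 65535); binary masks on disk are
8-bit PNG with values {0, 255} and any nonzero pixel reads as foreground;
soft maps (vesselness) are written as 32-bit float TIFF.  COCO polygon
annotations are rasterized with a pixel-center-inside rule: a pixel (r, c)
belongs to a polygon when its center (x = c + 0.5, y = r + 0.5 in
continuous image coordinates, x right, y down) falls inside; multiple
polygons per image merge by union.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from matplotlib.path import Path as MplPath

__all__ = [
    "read_gray_image",
    "write_gray_image",
    "read_mask",
    "write_mask",
    "write_float_tiff",
    "read_float_tiff",
    "rasterize_polygon",
    "coco_to_masks",
]


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as float intensities in [0, 1].

    Color images are converted by Rec.-601 luminance with a warning.
    """
    arr = iio.imread(Path(path))
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        scale = 1.0
    if arr.ndim == 3:
        warnings.warn(f"{path}: multi-channel image converted by luminance")
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    return arr.astype(float) / scale


def write_gray_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; nonzero is foreground.

    Genuinely grayscale files (values other than one foreground level)
    are thresholded at 128 with a warning.
    """
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    values = np.unique(arr)
    nonzero = values[values != 0]
    if len(nonzero) > 1:
        warnings.warn(f"{path}: non-binary mask thresholded at 128")
        return arr >= 128
    return arr != 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG with values {0, 255}."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_float_tiff(path: str | Path, data: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(data, dtype=np.float32))


def read_float_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def rasterize_polygon(
    xy: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize one polygon by the pixel-center-inside rule.

    ``xy`` is an (n, 2) array of continuous (x, y) vertices; out-of-bounds
    vertices are clipped to the image rectangle.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    h, w = shape
    xy = np.column_stack([np.clip(xy[:, 0], 0, w), np.clip(xy[:, 1], 0, h)])
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    centers = np.column_stack([cols.ravel(), rows.ravel()])
    inside = MplPath(xy).contains_points(centers)
    return inside.reshape(h, w)


def coco_to_masks(annotations: dict | str | Path) -> dict[str, np.ndarray]:
    """Convert a COCO-style polygon annotation set to per-image binary masks.

    Accepts a loaded COCO dict or a path to a COCO JSON file with the
    standard ``images`` (id, file_name, width, height) and ``annotations``
    (image_id, segmentation as flat [x1, y1, x2, y2, ...] polygon lists)
    sections.  Polygons with fewer than 3 vertices are skipped with a
    warning; an annotation referencing an unknown image id is an error.
    Returns masks keyed by image file name.
    """
    if not isinstance(annotations, dict):
        with open(annotations) as fh:
            annotations = json.load(fh)
    images = {img["id"]: img for img in annotations.get("images", [])}
    masks = {
        img["file_name"]: np.zeros((img["height"], img["width"]), dtype=bool)
        for img in images.values()
    }
    for ann in annotations.get("annotations", []):
        img = images.get(ann["image_id"])
        if img is None:
            raise ValueError(f"annotation references unknown image id {ann['image_id']}")
        shape = (img["height"], img["width"])
        segs = ann.get("segmentation", [])
        for seg in segs:
            xy = np.asarray(seg, dtype=float).reshape(-1, 2)
            if len(xy) < 3:
                warnings.warn("skipping degenerate polygon with < 3 vertices")
                continue
            masks[img["file_name"]] |= rasterize_polygon(xy, shape)
    return masks
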