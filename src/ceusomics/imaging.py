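"""Image I/O, ROI polygon rasterization, and grey-level quantization.

Coordinate convention (used everywhere in this package): arrays are indexed
``[row, col]``; polygons are sequences of ``(x, y)`` vertices with ``x``
being the column and ``y`` the row, 0-based, origin at the top-left *corner*
of the top-left pixel.  The center of pixel ``(r, c)`` is therefore at
``(x, y) = (c + 0.5, r + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from ceusomics._dicom import read_single_frame_dicom

PHASES = ("baseline", "arterial", "portal")

#: minimum number of in-mask pixels below which texture statistics are refused
MIN_ROI_PIXELS = 16


class RoiError(ValueError):
    """Raised for invalid ROI polygons or masks that are too small."""


def _as_polygon_array(polygon: Sequence) -> np.ndarray:
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise RoiError("polygon must be an (n>=3, 2) array of (x, y) vertices")
    # drop an explicitly repeated closing vertex
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if poly.shape[0] < 3:
        raise RoiError("polygon must have at least 3 distinct vertices")
    return poly


def _check_simple(poly: np.ndarray) -> None:
    if not _ShapelyPolygon(poly).is_simple:
        raise RoiError("polygon is self-intersecting")


@dataclass
class ImageWithROI:
    """One 2D grayscale image with its ROI polygon and rasterized mask."""

    pixels: np.ndarray
    roi_polygon: np.ndarray
    mask: np.ndarray
    phase: str
    spacing: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if np.any(np.asarray(self.pixels, dtype=float) < 0):
            raise ValueError("pixel intensities must be non-negative")
        self.roi_polygon = _as_polygon_array(self.roi_polygon)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape must equal pixel shape")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        n = int(self.mask.sum())
        if n < MIN_ROI_PIXELS:
            raise RoiError(
                f"ROI mask has {n} pixels; at least {MIN_ROI_PIXELS} are required "
                "for stable texture statistics"
            )
        _check_simple(self.roi_polygon)

    @property
    def n_roi_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class QuantizedROI:
    """ROI intensities discretized to ``levels`` grey levels.

    ``quantized`` holds values in ``1..levels`` inside the mask and 0 outside.
    """

    levels: int
    quantized: np.ndarray
    mask: np.ndarray
    n_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        self.quantized = np.asarray(self.quantized, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.n_pixels = int(self.mask.sum())
        inside = self.quantized[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.levels):
            raise ValueError("in-mask levels must lie in 1..levels")
        if np.any(self.quantized[~self.mask] != 0):
            raise ValueError("out-of-mask pixels must be 0")


def read_image(path, format: Optional[str] = None):
    """Read a single-frame grayscale image from DICOM, PNG, or TIFF.

    RGB inputs are collapsed by the Rec. 601 luminance transform; DICOM
    rescale slope/intercept are applied when the tags are present.

    Returns
    -------
    (pixels, spacing)
        ``pixels`` is a 2D float array, ``spacing`` the pixel size in mm
        (``None`` when the file does not carry one).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".dcm": "dicom",
            ".dicom": "dicom",
            ".png": "png",
            ".tif": "tiff",
            ".tiff": "tiff",
        }.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer image format from suffix {suffix!r}")
    if format == "dicom":
        return read_single_frame_dicom(path)
    if format == "png":
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im)
    elif format == "tiff":
        import tifffile

        arr = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported format {format!r}")
    return _to_mono(arr), None


def _to_mono(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3]
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"cannot interpret image with shape {arr.shape} as 2D grayscale")


def rasterize_roi(polygon: Sequence, shape) -> np.ndarray:
    """Rasterize a closed simple polygon to a boolean mask.

    A pixel belongs to the mask iff its center lies inside the polygon under
    the even-odd rule.  Centers exactly on an edge follow a half-open
    "top-left in" rule: each non-horizontal edge covers the half-open y
    interval ``[y_min, y_max)`` and crossings strictly to the right of the
    center toggle membership, so centers on a left/top boundary are inside
    and centers on a right/bottom boundary are outside.
    """
    poly = _as_polygon_array(polygon)
    _check_simple(poly)
    rows, cols = int(shape[0]), int(shape[1])
    if poly[:, 0].min() < 0 or poly[:, 1].min() < 0 or poly[:, 0].max() > cols or poly[:, 1].max() > rows:
        raise RoiError("polygon vertices must lie within the image bounds")

    yc = np.arange(rows) + 0.5  # pixel-center y per row
    xc = np.arange(cols) + 0.5  # pixel-center x per col
    crossings = np.zeros((rows, cols), dtype=np.int64)
    x0s, y0s = poly[:, 0], poly[:, 1]
    x1s, y1s = np.roll(x0s, -1), np.roll(y0s, -1)
    for x0, y0, x1, y1 in zip(x0s, y0s, x1s, y1s):
        if y0 == y1:  # horizontal edges never cross a horizontal ray
            continue
        hit = (np.minimum(y0, y1) <= yc) & (yc < np.maximum(y0, y1))
        if not hit.any():
            continue
        xi = x0 + (yc[hit] - y0) * (x1 - x0) / (y1 - y0)
        crossings[hit] += xi[:, None] > xc[None, :]
    return (crossings % 2).astype(bool)


def quantize(image: np.ndarray, mask: np.ndarray, levels: int) -> QuantizedROI:
    """Quantize in-mask intensities to ``levels`` equal-width grey levels.

    Bins span ``[min, max]`` of the in-mask intensities; level ``k`` covers
    ``[min + (k-1)w, min + kw)`` with the maximum mapped to ``levels``.  A
    constant ROI quantizes to all 1s.  Binning is ROI-relative, so the result
    is invariant to intensity shift and positive scaling.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must equal image shape")
    if int(mask.sum()) < MIN_ROI_PIXELS:
        raise RoiError(f"mask must contain at least {MIN_ROI_PIXELS} pixels")
    inside = image[mask]
    lo, hi = inside.min(), inside.max()
    q = np.zeros(image.shape, dtype=np.int64)
    if hi == lo:
        q[mask] = 1
    else:
        w = (hi - lo) / levels
        lv = np.floor((image[mask] - lo) / w).astype(np.int64) + 1
        np.clip(lv, 1, levels, out=lv)
        q[mask] = lv
    return QuantizedROI(levels=levels, quantized=q, mask=mask)
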