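"""Leaf segmentation and automatic ROI placement on the RGB frame.

The pipeline mirrors manual practice in leaf phenotyping: convert the RGB
frame to HSV, keep only pixels whose hue/saturation/value fall inside a
"greenness" window (shaded leaf areas are dark — low V — and soil background
is amber — low hue — so both drop out), threshold the masked green channel
(Otsu or triangle method), take the largest connected component as the leaf,
and center a small rectangular ROI on its midpoint. A manual-ROI path exists
for multi-plant scenes where the user wants to pick the rectangle.

Coordinates are (row, col), 0-based; ROIs are half-open rectangles
``[x1, x2) x [y1, y2)`` with x = col, y = row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor

from .errors import (
    DegenerateHistogram,
    EmptySegmentation,
    InvalidROI,
)

log = logging.getLogger(__name__)


# --- domain types -----------------------------------------------------------

@dataclass(frozen=True)
class HSVBounds:
    """Inclusive lower/upper HSV window; h in degrees [0, 360), s and v in [0, 1].

    The hue interval may wrap around 0° (lower.h > upper.h), although the
    greenness defaults do not.
    """

    lower: Tuple[float, float, float]
    upper: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.lower[1] > self.upper[1] or self.lower[2] > self.upper[2]:
            raise ValueError("lower s/v bound exceeds upper bound")


#: Default greenness window: nominal green foliage passes; shadow fails on V,
#: soil background fails on hue.
DEFAULT_HSV_BOUNDS = HSVBounds(lower=(60.0, 0.15, 0.25), upper=(170.0, 1.0, 1.0))

DEFAULT_ROI_SIZE = (10, 10)
MIN_ROI_SIZE = (2, 2)


@dataclass(frozen=True)
class Component:
    """A connected set of mask pixels."""

    pixels: np.ndarray  # (N, 2) int array of (row, col), row-major sorted
    area: int
    centroid: Tuple[float, float]

    def bbox(self) -> Tuple[int, int, int, int]:
        """(row_min, col_min, row_max, col_max), inclusive."""
        rows = self.pixels[:, 0]
        cols = self.pixels[:, 1]
        return int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())


@dataclass(frozen=True)
class ROI:
    """Axis-aligned half-open pixel rectangle shared by RGB and cube frames."""

    x1: int
    y1: int
    x2: int
    y2: int

    def __post_init__(self) -> None:
        if not (0 <= self.x1 < self.x2 and 0 <= self.y1 < self.y2):
            raise InvalidROI(f"degenerate ROI ({self.x1},{self.y1},{self.x2},{self.y2})")

    @property
    def width(self) -> int:
        return self.x2 - self.x1

    @property
    def height(self) -> int:
        return self.y2 - self.y1

    @property
    def slices(self) -> Tuple[slice, slice]:
        """(row slice, col slice) for numpy indexing."""
        return slice(self.y1, self.y2), slice(self.x1, self.x2)

    def validate(self, image_shape: Tuple[int, ...]) -> "ROI":
        h, w = image_shape[:2]
        if self.x2 > w or self.y2 > h:
            raise InvalidROI(
                f"ROI ({self.x1},{self.y1},{self.x2},{self.y2}) exceeds {w}x{h} frame"
            )
        return self

    def shifted(self, drow: int, dcol: int) -> "ROI":
        return ROI(self.x1 + dcol, self.y1 + drow, self.x2 + dcol, self.y2 + drow)


@dataclass
class AutoRoiDiagnostics:
    """Intermediates of :func:`auto_roi`, for inspection and logging."""

    green_mask: np.ndarray
    threshold: int
    thresholded: np.ndarray
    n_components: int
    component_area: int
    midpoint: Tuple[int, int]
    roi_contained: bool
    roi_coverage: float


# --- color ------------------------------------------------------------------

def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Standard hexcone RGB→HSV; returns float grid with h in degrees, s, v in [0,1].

    Hue is undefined for achromatic pixels (s = 0) and reported as 0.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    hsv = _skcolor.rgb2hsv(image)
    hsv[..., 0] *= 360.0
    return hsv


def greenness_mask(hsv: np.ndarray, bounds: HSVBounds = DEFAULT_HSV_BOUNDS) -> np.ndarray:
    """Boolean mask of pixels whose h, s, v all lie inside ``bounds`` (inclusive).

    Because the default lower V bound exceeds typical shadow brightness, this
    one test removes both the dark shaded leaf areas and the non-green
    background in a single pass.
    """
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    lo, hi = bounds.lower, bounds.upper
    if lo[0] <= hi[0]:
        hue_ok = (h >= lo[0]) & (h <= hi[0])
    else:  # wrapping hue interval
        hue_ok = (h >= lo[0]) | (h <= hi[0])
    return hue_ok & (s >= lo[1]) & (s <= hi[1]) & (v >= lo[2]) & (v <= hi[2])


# --- thresholding -----------------------------------------------------------

def _check_histogram(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if hist.sum() < 2 or np.count_nonzero(hist) < 2:
        raise DegenerateHistogram("histogram needs >= 2 counts in >= 2 distinct bins")
    return hist


def otsu_level(histogram: Sequence[int]) -> int:
    """Otsu threshold of a 256-bin histogram.

    Returns the level t maximizing the between-class variance of the split
    {bins <= t} vs {bins > t}; exact ties resolve to the lowest level.
    """
    hist = _check_histogram(histogram)
    p = hist / hist.sum()
    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)
    mu = np.cumsum(p * bins)
    mu_total = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_total * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    sigma_b[(w0 <= 0) | (w0 >= 1)] = -np.inf
    return int(np.argmax(sigma_b[:255]))  # first max = lowest level on ties


def triangle_level(histogram: Sequence[int]) -> int:
    """Triangle-method threshold of a 256-bin histogram.

    Draws the line from the histogram peak to the farthest non-empty tail
    bin (bin axis normalized by the peak-tail span, count axis by the peak
    count) and returns the bin of maximum perpendicular distance to that
    line; ties resolve to the lowest bin.
    """
    hist = _check_histogram(histogram)
    peak = int(np.argmax(hist))  # lowest bin on count ties
    occupied = np.flatnonzero(hist)
    tail = int(occupied[np.argmax(np.abs(occupied - peak))])
    if tail == peak:  # cannot happen after the degeneracy check, but be safe
        raise DegenerateHistogram("peak and tail coincide")
    lo, hi = (peak, tail) if peak < tail else (tail, peak)
    candidates = np.arange(lo + 1, hi)
    if candidates.size == 0:
        return lo
    span = tail - peak
    xp = (candidates - peak) / span
    yp = hist[candidates] / hist[peak]
    y_tail = hist[tail] / hist[peak]
    # perpendicular distance from (xp, yp) to the line (0, 1) -> (1, y_tail)
    num = np.abs(1.0 * (yp - 1.0) - (y_tail - 1.0) * xp)
    dist = num / np.hypot(1.0, y_tail - 1.0)
    return int(candidates[np.argmax(dist)])


def binarize(gray: np.ndarray, level: int) -> np.ndarray:
    """Boolean mask: intensity strictly greater than ``level``."""
    return np.asarray(gray) > level


# --- connected components ---------------------------------------------------

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def connected_components(mask: np.ndarray, connectivity: int = 8) -> List[Component]:
    """Partition the true pixels of ``mask`` into maximal connected sets.

    Components stand in for the filled contours of classical contour-area
    selection: for filled blobs the areas coincide.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT_4 if connectivity == 4 else _STRUCT_8)
    out: List[Component] = []
    for i in range(1, n + 1):
        pixels = np.argwhere(labels == i)  # row-major sorted
        centroid = (float(pixels[:, 0].mean()), float(pixels[:, 1].mean()))
        out.append(Component(pixels=pixels, area=int(pixels.shape[0]), centroid=centroid))
    return out


def largest_component(components: Sequence[Component], image_shape: Tuple[int, ...]) -> Component:
    """Component of maximal area.

    Ties resolve first to the centroid nearest the image center, then to the
    smallest top-left member pixel in row-major order — fixed so the pipeline
    is bit-reproducible.
    """
    if not components:
        raise EmptySegmentation(
            "no connected components — the greenness bounds removed everything; "
            "consider relaxing the HSV window"
        )
    h, w = image_shape[:2]
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    def key(comp: Component):
        d2 = (comp.centroid[0] - center[0]) ** 2 + (comp.centroid[1] - center[1]) ** 2
        first_pixel = (int(comp.pixels[0, 0]), int(comp.pixels[0, 1]))
        return (-comp.area, d2, first_pixel)

    return min(components, key=key)


def _round_half_down(value: float) -> int:
    """Round to nearest integer, exact .5 ties toward the lower index."""
    return int(np.ceil(value - 0.5))


def component_midpoint(component: Component, mask: Optional[np.ndarray] = None) -> Tuple[int, int]:
    """Integer midpoint of a component.

    The centroid is rounded to the nearest pixel (ties toward lower indices);
    if that pixel is not a member (concave shapes), the member pixel nearest
    the centroid is returned (Euclidean distance, ties to smaller row then
    smaller col).
    """
    cr, cc = component.centroid
    r, c = _round_half_down(cr), _round_half_down(cc)
    pixels = component.pixels
    # membership check against the component itself
    hit = np.any((pixels[:, 0] == r) & (pixels[:, 1] == c))
    if hit:
        return r, c
    d2 = (pixels[:, 0] - cr) ** 2 + (pixels[:, 1] - cc) ** 2
    best = int(np.argmin(d2))  # first minimum = row-major smallest on ties
    return int(pixels[best, 0]), int(pixels[best, 1])


def bbox_midpoint(component: Component, mask: Optional[np.ndarray] = None) -> Tuple[int, int]:
    """Bounding-box center alternative to the centroid midpoint."""
    r0, c0, r1, c1 = component.bbox()
    r, c = _round_half_down((r0 + r1) / 2.0), _round_half_down((c0 + c1) / 2.0)
    pixels = component.pixels
    if np.any((pixels[:, 0] == r) & (pixels[:, 1] == c)):
        return r, c
    d2 = (pixels[:, 0] - r) ** 2 + (pixels[:, 1] - c) ** 2
    best = int(np.argmin(d2))
    return int(pixels[best, 0]), int(pixels[best, 1])


# --- ROI placement ----------------------------------------------------------

def _centered_roi(center: Tuple[int, int], size: Tuple[int, int],
                  image_shape: Tuple[int, ...]) -> ROI:
    r, c = center
    h, w = size
    rows, cols = image_shape[:2]
    y1, x1 = r - h // 2, c - w // 2
    y2, x2 = y1 + h, x1 + w
    return ROI(max(0, x1), max(0, y1), min(cols, x2), min(rows, y2))


def place_roi(
    center: Tuple[int, int],
    image_shape: Tuple[int, ...],
    size: Tuple[int, int] = DEFAULT_ROI_SIZE,
    mask: Optional[np.ndarray] = None,
    min_size: Tuple[int, int] = MIN_ROI_SIZE,
) -> Tuple[ROI, Dict[str, object]]:
    """Center a rectangle of ``size`` on ``center``, clamped to the frame.

    If a mask is given and the rectangle sticks out of it, the size shrinks
    two pixels per dimension at a time until the ROI is fully inside the mask
    or ``min_size`` is reached. Failure to fit at minimum size is signalled
    (warning + coverage fraction in the info dict), not fatal: tiny leaves
    degrade gracefully instead of aborting the run.
    """
    rows, cols = image_shape[:2]
    if not (0 <= center[0] < rows and 0 <= center[1] < cols):
        raise InvalidROI(f"center {center} outside {cols}x{rows} frame")
    h, w = size
    while True:
        roi = _centered_roi(center, (h, w), image_shape)
        if mask is None:
            contained, coverage = True, 1.0
            break
        inside = mask[roi.slices]
        contained = bool(inside.all())
        coverage = float(inside.mean())
        if contained or (h <= min_size[0] and w <= min_size[1]):
            break
        h = max(min_size[0], h - 2)
        w = max(min_size[1], w - 2)
    if not contained:
        log.warning(
            "ROI %s not fully inside mask even at minimum size; coverage %.2f",
            roi, coverage,
        )
    return roi, {"contained": contained, "coverage": coverage, "size": (h, w)}


def manual_roi(x1: int, y1: int, x2: int, y2: int, image_shape: Tuple[int, ...]) -> ROI:
    """Validate user-supplied rectangle coordinates against the frame."""
    return ROI(x1, y1, x2, y2).validate(image_shape)


# --- end-to-end automatic ROI ----------------------------------------------

def auto_roi(
    image: np.ndarray,
    bounds: HSVBounds = DEFAULT_HSV_BOUNDS,
    method: str = "otsu",
    size: Tuple[int, int] = DEFAULT_ROI_SIZE,
    min_size: Tuple[int, int] = MIN_ROI_SIZE,
    connectivity: int = 8,
    midpoint: str = "centroid",
) -> Tuple[ROI, AutoRoiDiagnostics]:
    """Automatic ROI on an RGB leaf image.

    Composition: greenness mask → masked green channel → Otsu or triangle
    threshold → connected components → largest component → midpoint →
    centered ROI constrained to the thresholded mask.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got {image.shape}")
    if method not in ("otsu", "triangle"):
        raise ValueError(f"unknown threshold method {method!r}")
    if midpoint not in ("centroid", "bbox"):
        raise ValueError(f"unknown midpoint mode {midpoint!r}")

    hsv = rgb_to_hsv(image)
    gmask = greenness_mask(hsv, bounds)
    if not gmask.any():
        raise EmptySegmentation(
            "greenness mask is empty — every pixel fell outside the HSV window; "
            "adjust the HSV bounds"
        )
    gray = np.where(gmask, image[:, :, 1], 0).astype(np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256)[:256]
    level = otsu_level(hist) if method == "otsu" else triangle_level(hist)
    thresholded = binarize(gray, level)
    components = connected_components(thresholded, connectivity=connectivity)
    if not components:
        raise EmptySegmentation(
            "thresholding removed every masked pixel; adjust the HSV bounds"
        )
    comp = largest_component(components, image.shape)
    mid = component_midpoint(comp) if midpoint == "centroid" else bbox_midpoint(comp)
    roi, info = place_roi(mid, image.shape, size=size, mask=thresholded, min_size=min_size)
    diag = AutoRoiDiagnostics(
        green_mask=gmask,
        threshold=level,
        thresholded=thresholded,
        n_components=len(components),
        component_area=comp.area,
        midpoint=mid,
        roi_contained=bool(info["contained"]),
        roi_coverage=float(info["coverage"]),
    )
    return roi, diag
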