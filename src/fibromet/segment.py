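"""Automated thresholding, discrete-object (ROI) detection and intensity-surface export.

The segmentation contract mirrors a classical fluorescence workflow: a global
automated threshold (Otsu's between-class-variance criterion on the 256-level
intensity histogram) separates signal from background, 8-connected components
above a calibrated minimum pixel size become regions of interest, and the raw
intensity grid doubles as a height field for 3-D surface reconstruction.

Conventions
-----------
* Images are 8-bit: integer intensities in [0, 255].
* Coordinates are 0-based, row-major, origin top-left; pixel centers sit at
  integer (row, col) coordinates.
* Pixels *equal* to the threshold level are background (strict ``> level``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from .errors import DegenerateHistogramError, ParameterError

__all__ = [
    "CalibratedImage",
    "RoiObject",
    "SurfaceGrid",
    "auto_threshold",
    "otsu_level",
    "calibrate_min_size",
    "detect_objects",
    "surface_plot",
]


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit intensity grid plus the physical size of one pixel.

    Parameters
    ----------
    intensity : ndarray of shape (rows, cols)
        Integer intensities on the 256-level scale, values in [0, 255].
    pixel_size : float
        Physical edge length of one pixel in micrometres (μm/pixel). Every
        downstream length and area converts through this value.
    """

    intensity: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity)
        if arr.ndim != 2 or arr.size == 0:
            raise ParameterError("intensity must be a nonempty 2-D array")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ParameterError("intensities must be integers on the 0-255 scale")
            arr = np.round(arr).astype(np.uint8)
        if arr.min() < 0 or arr.max() > 255:
            raise ParameterError("intensities must lie in [0, 255]")
        object.__setattr__(self, "intensity", arr.astype(np.uint8))
        if not (self.pixel_size > 0):
            raise ParameterError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape  # type: ignore[return-value]


@dataclass
class RoiObject:
    """One detected discrete fluorescent object.

    Attributes
    ----------
    label : int
        1-based identifier, unique within the image, assigned in raster-scan
        order of each component's first pixel.
    pixels : ndarray of shape (n, 2)
        Integer (row, col) coordinates of the component's pixels.
    boundary : ndarray of shape (m, 2)
        Closed sub-pixel iso-contour of the component at level 0.5
        (marching-squares convention), in (row, col) pixel coordinates.
    bbox : tuple
        (row0, col0, row1, col1) half-open bounding box.
    """

    label: int
    pixels: np.ndarray
    boundary: np.ndarray
    bbox: tuple[int, int, int, int]
    _centroid: tuple[float, float] | None = field(default=None, repr=False)

    @property
    def area_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def centroid(self) -> tuple[float, float]:
        """Unweighted centroid in (row, col) pixel coordinates."""
        if self._centroid is None:
            self._centroid = (
                float(self.pixels[:, 0].mean()),
                float(self.pixels[:, 1].mean()),
            )
        return self._centroid


@dataclass(frozen=True)
class SurfaceGrid:
    """Height field for 3-D surface reconstruction of an intensity image."""

    heights: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape  # type: ignore[return-value]


def otsu_level(counts: np.ndarray) -> int:
    """Between-class-variance-maximizing threshold for a 256-bin histogram.

    Evaluates every candidate level ``t`` in [0, 254], splitting intensities
    into background ``<= t`` and foreground ``> t``, and returns the first
    level attaining the maximal between-class variance.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size != 256:
        raise ParameterError("expected a 256-bin histogram")
    total = counts.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(counts)[:-1]                     # weight of class <= t
    w1 = total - w0
    m0 = np.cumsum(counts * levels)[:-1]            # first moment of class <= t
    m1 = counts @ levels - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = m1 / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def auto_threshold(image: CalibratedImage) -> tuple[int, np.ndarray]:
    """Global automated threshold (Otsu) and the resulting foreground mask.

    Returns
    -------
    level : int in [0, 254]
        The chosen threshold on the 0-255 scale.
    mask : bool ndarray
        Pixels strictly above ``level``.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant (fewer than two distinct intensities).
    """
    grid = image.intensity
    counts = np.bincount(grid.ravel(), minlength=256)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "automatic thresholding requires at least two distinct intensity levels"
        )
    level = otsu_level(counts)
    return level, grid > level


def calibrate_min_size(reference_areas: Sequence[float], factor: float = 0.5) -> int:
    """Minimum object size (pixels) from reference cell areas.

    The minimum size gate is calibrated from the measured pixel areas of a set
    of representative cells (canonically twelve): ``floor(factor * min(areas))``,
    so that every reference cell comfortably clears the gate while debris well
    below the smallest genuine cell is rejected.
    """
    if len(reference_areas) == 0:
        raise ParameterError("reference area list must be nonempty")
    areas = [float(a) for a in reference_areas]
    if any(a <= 0 for a in areas):
        raise ParameterError("reference areas must be positive")
    if not (0 < factor <= 1):
        raise ParameterError("calibration factor must be in (0, 1]")
    return max(1, math.floor(factor * min(areas)))


def _component_boundary(pixels: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Closed marching-squares contour (level 0.5) of one component.

    ``bbox`` is half-open (row0, col0, row1, col1); the component is embedded
    in a zero-padded local grid so the contour always closes.
    """
    r0, c0, r1, c1 = bbox
    local = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=np.float64)
    local[pixels[:, 0] - r0 + 1, pixels[:, 1] - c0 + 1] = 1.0
    contours = measure.find_contours(local, 0.5)
    # The outer contour is the longest one; inner contours are holes.
    outer = max(contours, key=lambda c: c.shape[0])
    return outer + np.array([r0 - 1, c0 - 1], dtype=np.float64)


def detect_objects(mask: np.ndarray, min_size: int) -> list[RoiObject]:
    """Size-gated connected-component ROI detection.

    8-connected components of ``mask`` with at least ``min_size`` pixels are
    returned as :class:`RoiObject` instances, labelled 1..k in raster-scan
    order of each component's first pixel. Smaller components are excluded
    from the analysis. An empty result is valid.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ParameterError("mask must be binary")
        mask = mask.astype(bool)
    if min_size < 1:
        raise ParameterError("min_size must be >= 1")
    labelled = measure.label(mask, connectivity=2)
    objects: list[RoiObject] = []
    next_label = 1
    for region in measure.regionprops(labelled):
        if region.area < min_size:
            continue
        pixels = region.coords.astype(np.intp)
        r0, c0, r1, c1 = region.bbox
        boundary = _component_boundary(pixels, (r0, c0, r1, c1))
        objects.append(
            RoiObject(
                label=next_label,
                pixels=pixels,
                boundary=boundary,
                bbox=(r0, c0, r1, c1),
            )
        )
        next_label += 1
    return objects


def surface_plot(image: CalibratedImage) -> SurfaceGrid:
    """Height field of the image on the 256-level scale (identity map).

    The reconstructed 3-D surface assigns each pixel a height equal to its
    intensity (0-255); the grid keeps the image dimensions and is suitable
    for any surface renderer.
    """
    return SurfaceGrid(heights=image.intensity.copy())
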