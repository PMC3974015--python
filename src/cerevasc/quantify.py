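"""ROI statistics and the negative-contrast vessel attenuation estimators.

A blood vessel seen against diffuse Cerenkov backlighting removes light
instead of emitting it, so the measurand is a ratio: the mean radiance inside
a vessel ROI divided by the mean of two congruent ROIs placed immediately to
its left and right.  The attenuation fraction is one minus that ratio.
The same local-reference convention, with a free choice of reference region,
gives the necrotic-core radiance reduction.

Pixel membership everywhere uses the pixel-center-in-region, half-open
rectangle convention [x, x + w).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np
import shapely
from scipy import ndimage

from .errors import (
    EmptyROIError,
    NonPositiveReferenceError,
    OutOfBoundsError,
)
from .image import LuminescenceImage, as_array

logger = logging.getLogger("cerevasc")

__all__ = [
    "ROI",
    "PolygonROI",
    "VesselMeasurement",
    "roi_mean",
    "subtract_background",
    "despike",
    "flanking_rois",
    "vessel_attenuation",
    "region_reduction",
]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular ROI in pixel units, half-open [x, x+w) x [y, y+h)."""

    x: float
    y: float
    width: float
    height: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be >= 1 pixel")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the rectangle."""
        h, w = shape
        ys = np.arange(h) + 0.5
        xs = np.arange(w) + 0.5
        inside_y = (ys >= self.y) & (ys < self.y + self.height)
        inside_x = (xs >= self.x) & (xs < self.x + self.width)
        return inside_y[:, None] & inside_x[None, :]

    def translated(self, dx: float, dy: float, label: str | None = None) -> "ROI":
        return replace(
            self, x=self.x + dx, y=self.y + dy,
            label=self.label if label is None else label,
        )

    def is_clipped_by(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return self.x < 0 or self.y < 0 or self.x + self.width > w or self.y + self.height > h

    def to_dict(self) -> dict:
        return {"type": "rect", "x": self.x, "y": self.y,
                "w": self.width, "h": self.height, "label": self.label}


@dataclass(frozen=True)
class PolygonROI:
    """Polygonal ROI; membership is pixel-center-inside-polygon (shapely)."""

    vertices: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        poly = shapely.Polygon(self.vertices)
        h, w = shape
        jj, ii = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
        inside = shapely.contains_xy(poly, jj.ravel(), ii.ravel())
        return inside.reshape(h, w)

    def to_dict(self) -> dict:
        return {"type": "polygon", "vertices": [list(v) for v in self.vertices],
                "label": self.label}


AnyROI = Union[ROI, PolygonROI]


@dataclass(frozen=True)
class VesselMeasurement:
    """One vessel ROI, its two flanking ROIs and the attenuation fraction.

    ``attenuation = 1 - vessel_mean / flank_mean``.  Negative values (vessel
    brighter than its flanks) are retained and flagged, never clipped:
    clipping would bias cohort means upward.
    """

    vessel_roi: ROI
    left_roi: ROI
    right_roi: ROI
    vessel_mean: float
    flank_mean: float
    attenuation: float
    negative_flagged: bool = False

    @property
    def label(self) -> str:
        return self.vessel_roi.label

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "vessel_mean": self.vessel_mean,
            "flank_mean": self.flank_mean,
            "attenuation": self.attenuation,
            "negative_flagged": self.negative_flagged,
        }


def roi_mean(image, roi: AnyROI) -> float:
    """Arithmetic mean of pixel radiances whose centers fall inside the ROI.

    An ROI straddling the image edge is averaged over its in-bounds pixels
    only (with a logged warning); an ROI with no in-bounds pixels raises
    :class:`EmptyROIError`.
    """
    arr = as_array(image)
    mask = roi.mask(arr.shape)
    n = int(mask.sum())
    if n == 0:
        raise EmptyROIError(f"ROI {roi!r} contains no pixels of a {arr.shape} image")
    if isinstance(roi, ROI) and roi.is_clipped_by(arr.shape):
        logger.warning("ROI %r straddles the image edge; averaging %d in-bounds pixels",
                       roi, n)
    return float(arr[mask].mean())


def subtract_background(image, background_roi: AnyROI):
    """Subtract the scalar mean of a source-free background ROI.

    Removes a uniform dark/cosmic floor.  Values may go slightly negative
    after subtraction; they are preserved (clipping would bias ROI means).
    """
    arr = as_array(image)
    level = roi_mean(arr, background_roi)
    out = arr - level
    if isinstance(image, LuminescenceImage):
        return image.with_data(out)
    return out


def despike(image, window: int = 5, k: float = 10.0):
    """Replace isolated hot pixels (cosmic-ray hits) by the local median.

    A pixel is replaced when it exceeds the local median by more than
    ``k`` times the scaled local MAD (1.4826 x median absolute deviation,
    a robust sigma).  Flat images pass through unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    arr = as_array(image)
    med = ndimage.median_filter(arr, size=window, mode="nearest")
    mad = ndimage.median_filter(np.abs(arr - med), size=window, mode="nearest")
    thresh = med + k * 1.4826 * mad
    out = np.where(arr > thresh, med, arr)
    if isinstance(image, LuminescenceImage):
        return image.with_data(out)
    return out


def flanking_rois(
    vessel_roi: ROI,
    gap_px: int = 0,
    image_shape: tuple[int, int] | None = None,
) -> tuple[ROI, ROI]:
    """Two ROIs congruent to the vessel ROI, immediately to each side.

    The vessel ROI's long axis is taken as the vessel direction; the flanks
    are translated perpendicular to it by (short-axis width + gap_px) so
    that with ``gap_px=0`` they abut the vessel ROI ("immediate right and
    left ... using the same ROI").
    """
    if gap_px < 0:
        raise ValueError("gap_px must be >= 0")
    if vessel_roi.height >= vessel_roi.width:  # vessel runs vertically
        shift = vessel_roi.width + gap_px
        left = vessel_roi.translated(-shift, 0, label=vessel_roi.label + ":left")
        right = vessel_roi.translated(shift, 0, label=vessel_roi.label + ":right")
    else:  # vessel runs horizontally
        shift = vessel_roi.height + gap_px
        left = vessel_roi.translated(0, -shift, label=vessel_roi.label + ":left")
        right = vessel_roi.translated(0, shift, label=vessel_roi.label + ":right")
    if image_shape is not None:
        for flank in (left, right):
            if not flank.mask(image_shape).any():
                raise OutOfBoundsError(
                    f"flanking ROI {flank!r} falls entirely outside image {image_shape}"
                )
    return left, right


def vessel_attenuation(
    image,
    vessel_roi: ROI,
    gap_px: int = 0,
    *,
    pooled_flanks: bool = False,
) -> VesselMeasurement:
    """Negative-contrast attenuation of a vessel against its local background.

    flank_mean is the mean of the two flank ROI means (so unequal edge
    clipping cannot weight one side); set ``pooled_flanks=True`` to pool
    pixels instead.  attenuation = 1 - vessel_mean / flank_mean.
    """
    arr = as_array(image)
    left, right = flanking_rois(vessel_roi, gap_px, image_shape=arr.shape)
    vessel_mean = roi_mean(arr, vessel_roi)
    if pooled_flanks:
        mask = left.mask(arr.shape) | right.mask(arr.shape)
        flank_mean = float(arr[mask].mean())
    else:
        flank_mean = (roi_mean(arr, left) + roi_mean(arr, right)) / 2.0
    if flank_mean <= 0:
        raise NonPositiveReferenceError(
            f"flank mean must be > 0 to form an attenuation ratio, got {flank_mean}"
        )
    attenuation = 1.0 - vessel_mean / flank_mean
    if attenuation < 0:
        logger.warning("vessel ROI %r brighter than flanks (attenuation %.4f)",
                       vessel_roi, attenuation)
    return VesselMeasurement(
        vessel_roi=vessel_roi,
        left_roi=left,
        right_roi=right,
        vessel_mean=vessel_mean,
        flank_mean=flank_mean,
        attenuation=attenuation,
        negative_flagged=attenuation < 0,
    )


def region_reduction(
    image,
    target_roi: AnyROI,
    reference_roi: AnyROI | Sequence[AnyROI],
) -> float:
    """Fractional radiance reduction of a target region vs a reference.

    Used for the necrotic-core statistic: target = core ROI, reference =
    viable tumor rim.  The reference may be a single ROI or a sequence of
    ROIs surrounding the target, in which case the mean of their means is
    used (a symmetric reference cancels smooth backlight gradients).
    """
    arr = as_array(image)
    target_mean = roi_mean(arr, target_roi)
    if isinstance(reference_roi, (ROI, PolygonROI)):
        reference_rois: Sequence[AnyROI] = [reference_roi]
    else:
        reference_rois = list(reference_roi)
        if not reference_rois:
            raise ValueError("need at least one reference ROI")
    ref_mean = float(np.mean([roi_mean(arr, r) for r in reference_rois]))
    if ref_mean <= 0:
        raise NonPositiveReferenceError(
            f"reference mean must be > 0, got {ref_mean}"
        )
    return 1.0 - target_mean / ref_mean
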