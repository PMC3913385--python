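"""Disclosed-plaque coverage by red/green channel ratio.

Disclosing agents stain plaque so that, under fluorescence imaging, stained
regions become red-dominant while clean enamel stays green-dominant. The
measurement is an integer ratio image (red divided by green, 8-bit
arithmetic), a >= 1 threshold marking plaque, and a histogram count inside
the tooth ROI giving percentage coverage.

With floor division the observed ratio values on real frames are small
integers (typically 0-3), and "plaque" at the default threshold of 1 is
exactly the set of pixels where red >= green.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import GeometryError, ParameterError
from .image_model import (
    BinaryMask,
    FluorescenceImage,
    PolygonROI,
    deinterlace,
    rasterize_polygon,
)

__all__ = ["RatioImage", "CoverageResult", "ratio_image", "classify_plaque", "coverage"]

Rounding = Literal["floor", "round"]


@dataclass
class RatioImage:
    """Integer red/green ratio raster (uint8; saturated pixels are 255)."""

    pixels: np.ndarray
    origin_image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ratio image must be 2-D")


@dataclass
class CoverageResult:
    """Per-tooth plaque coverage.

    ``coverage_pct`` is 100 * plaque_pixels / roi_pixels;
    ``plaque_area_mm2`` is filled only when the image carries a
    mm-per-pixel calibration.
    """

    tooth_id: str
    roi_pixels: int
    plaque_pixels: int
    coverage_pct: float
    plaque_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.plaque_pixels <= self.roi_pixels:
            raise ValueError("plaque_pixels must lie in [0, roi_pixels]")


def ratio_image(img: FluorescenceImage, rounding: Rounding = "floor") -> RatioImage:
    """Divide the red channel by the green channel, pixel by pixel.

    Division is integer-valued: ``floor(R/G)`` by default, or nearest
    integer with ``rounding="round"`` for sensitivity analysis. Where the
    green signal is zero: a pixel with red > 0 saturates to 255 (no green
    reference, maximally plaque-like); a fully dark pixel maps to 0 (no
    evidence of plaque).
    """
    r = img.red.astype(np.int64)
    g = img.green.astype(np.int64)
    out = np.zeros(r.shape, dtype=np.int64)
    pos = g > 0
    if rounding == "floor":
        out[pos] = r[pos] // g[pos]
    elif rounding == "round":
        out[pos] = np.rint(r[pos] / g[pos]).astype(np.int64)
    else:
        raise ParameterError(f"rounding must be 'floor' or 'round', got {rounding!r}")
    out[(~pos) & (r > 0)] = 255
    return RatioImage(np.minimum(out, 255).astype(np.uint8), img.image_id)


def classify_plaque(ratio: RatioImage, threshold: int = 1) -> BinaryMask:
    """Mark as plaque every pixel whose ratio value is >= ``threshold``."""
    if threshold < 1:
        raise ParameterError(f"threshold must be >= 1, got {threshold}")
    return BinaryMask(ratio.pixels >= threshold, ratio.origin_image_id)


def coverage(
    img: FluorescenceImage,
    roi: PolygonROI,
    threshold: int = 1,
    deinterlace_first: bool = True,
    field: str = "odd_rows",
    rounding: Rounding = "floor",
) -> CoverageResult:
    """Percentage plaque coverage within a tooth ROI.

    Pipeline order: optional deinterlace, ratio image, threshold
    classification, intersection with the rasterized ROI, histogram count.
    """
    h, w = img.height, img.width
    verts = np.asarray(roi.vertices)
    if (
        verts[:, 0].min() < 0
        or verts[:, 1].min() < 0
        or verts[:, 0].max() > w
        or verts[:, 1].max() > h
    ):
        raise GeometryError(f"ROI {roi.tooth_id!r} exceeds {w}x{h} image bounds")
    work = deinterlace(img, field) if deinterlace_first else img  # type: ignore[arg-type]
    roi_mask = rasterize_polygon(roi, h, w)
    n_roi = roi_mask.count
    if n_roi == 0:
        raise GeometryError(f"ROI {roi.tooth_id!r} rasterizes to an empty mask")
    plaque = classify_plaque(ratio_image(work, rounding), threshold)
    n_plaque = int((plaque.pixels & roi_mask.pixels).sum())
    area = None
    if img.mm_per_pixel is not None:
        area = n_plaque * img.mm_per_pixel**2
    return CoverageResult(
        tooth_id=roi.tooth_id,
        roi_pixels=n_roi,
        plaque_pixels=n_plaque,
        coverage_pct=100.0 * n_plaque / n_roi,
        plaque_area_mm2=area,
    )
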