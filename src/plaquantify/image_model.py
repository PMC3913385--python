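"""Image and ROI primitives for intraoral fluorescence analysis.

Under 405 nm excitation sound enamel fluoresces green while porphyrins in
mature plaque fluoresce red, so an 8-bit RGB frame carries the whole
measurement. This module holds the raster and region-of-interest types,
file I/O, the deinterlacing pre-filter applied to frames captured by an
interlaced video sensor, and deterministic rasterization of polygon and
ellipse ROIs.

Coordinate convention: pixel (row ``i``, column ``j``) occupies the
half-open square ``[j, j+1) x [i, i+1)`` with centre ``(j + 0.5, i + 0.5)``;
``x`` is the column axis, ``y`` the row axis, origin at the top-left.
A pixel belongs to a region iff its *centre* does, so rasterized areas are
exact for integer-aligned shapes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from PIL import Image
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import FormatError, GeometryError

__all__ = [
    "FluorescenceImage",
    "PolygonROI",
    "EllipseROI",
    "BinaryMask",
    "read_image",
    "write_image",
    "deinterlace",
    "rasterize_polygon",
    "rasterize_ellipse",
    "load_rois",
    "save_rois",
]


@dataclass
class FluorescenceImage:
    """An 8-bit RGB fluorescence frame.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, channels ordered red, green, blue.
    mm_per_pixel
        Physical calibration; areas are reported in mm^2 only when set.
    image_id
        Identifier used to join measurements back to subjects.
    """

    pixels: np.ndarray
    mm_per_pixel: float | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"expected an (H, W, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if not np.issubdtype(self.pixels.dtype, np.integer):
                raise FormatError(
                    f"channel values must be 8-bit integers, got dtype {self.pixels.dtype}"
                )
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise FormatError("channel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        h, w = self.pixels.shape[:2]
        if h < 2 or w < 2:
            raise FormatError(f"image too small ({h}x{w}); need at least 2x2")
        if self.mm_per_pixel is not None and not self.mm_per_pixel > 0:
            raise FormatError("mm_per_pixel must be positive when given")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def red(self) -> np.ndarray:
        return self.pixels[:, :, 0]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1]

    @property
    def blue(self) -> np.ndarray:
        return self.pixels[:, :, 2]


@dataclass
class PolygonROI:
    """Closed simple polygon outlining a tooth, vertices in pixel units.

    The polygon closes implicitly (last vertex connects to the first).
    ``tooth_id`` uses FDI two-digit notation, e.g. ``"13"`` or ``"43"``.
    """

    vertices: list[tuple[float, float]]
    tooth_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise GeometryError(
                f"polygon needs at least 3 vertices, got {len(self.vertices)}"
            )

    def is_simple(self) -> bool:
        """True when edges meet only at shared endpoints.

        Zero-area (fully collinear) rings are degenerate but not
        self-intersecting; they rasterize to an empty mask.
        """
        poly = _ShapelyPolygon(self.vertices)
        if poly.area == 0.0:
            # shapely flags collinear rings as non-simple; we accept them.
            xs = np.array([v[0] for v in self.vertices])
            ys = np.array([v[1] for v in self.vertices])
            cross = (xs[1] - xs[0]) * (ys - ys[0]) - (ys[1] - ys[0]) * (xs - xs[0])
            return bool(np.allclose(cross, 0.0))
        return bool(poly.is_simple)


@dataclass
class EllipseROI:
    """Plaque-free reference region: a rotatable ellipse in pixel units."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0  # degrees, counter-clockwise in (x, y)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise GeometryError(f"semi-axes must be positive, got {self.semi_axes}")


@dataclass
class BinaryMask:
    """Boolean raster aligned with its source image."""

    pixels: np.ndarray
    origin_image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise FormatError("mask must be 2-D")

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


# ---------------------------------------------------------------------------
# File I/O


def read_image(
    path: str | Path, mm_per_pixel: float | None = None
) -> FluorescenceImage:
    """Read an 8-bit RGB PNG/TIFF/BMP frame.

    Non-8-bit or non-RGB inputs (grayscale, 16-bit, palette, RGBA) are
    rejected with a :class:`FormatError` naming the offending property —
    silent conversion could corrupt the channel-ratio measurement.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode != "RGB":
                raise FormatError(
                    f"{path.name}: expected 8-bit RGB, got mode {mode!r}"
                )
            arr = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return FluorescenceImage(arr, mm_per_pixel=mm_per_pixel, image_id=path.stem)


def write_image(img: FluorescenceImage, path: str | Path) -> None:
    """Write the frame losslessly (PNG or TIFF inferred from the suffix)."""
    Image.fromarray(img.pixels, mode="RGB").save(Path(path))


# ---------------------------------------------------------------------------
# Deinterlacing

Field = Literal["odd_rows", "even_rows"]


def deinterlace(img: FluorescenceImage, field: Field = "odd_rows") -> FluorescenceImage:
    """Suppress horizontal interlacing artefacts from a video sensor.

    Every row of the selected parity is replaced, channel by channel, with
    the rounded mean of its two vertical neighbours (round half up); a
    boundary row of that parity takes its single existing neighbour.
    Rows of the other parity pass through untouched, so the output has the
    same dimensions and a constant image is a fixed point.
    """
    if field not in ("odd_rows", "even_rows"):
        raise ValueError(f"field must be 'odd_rows' or 'even_rows', got {field!r}")
    h = img.height
    if h < 3:
        raise FormatError(f"deinterlace needs at least 3 rows, got {h}")
    parity = 1 if field == "odd_rows" else 0
    out = img.pixels.astype(np.int32).copy()
    src = img.pixels.astype(np.int32)
    rows = np.arange(parity, h, 2)
    interior = rows[(rows > 0) & (rows < h - 1)]
    if interior.size:
        out[interior] = (src[interior - 1] + src[interior + 1] + 1) // 2
    if parity == 0:
        out[0] = src[1]
    if (h - 1) % 2 == parity:
        out[h - 1] = src[h - 2]
    return FluorescenceImage(
        out.astype(np.uint8), mm_per_pixel=img.mm_per_pixel, image_id=img.image_id
    )


# ---------------------------------------------------------------------------
# Rasterization


def rasterize_polygon(roi: PolygonROI, height: int, width: int) -> BinaryMask:
    """Rasterize a simple polygon with the pixel-centre even-odd rule.

    A pixel is set iff its centre lies strictly inside the polygon under
    even-odd (ray-crossing) parity; centres exactly on an edge are
    excluded. Deterministic and exactly checkable against a per-pixel
    point-in-polygon loop.
    """
    if not roi.is_simple():
        raise GeometryError(f"polygon ROI {roi.tooth_id!r} is self-intersecting")
    verts = np.asarray(roi.vertices, dtype=float)
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)

    cx = np.arange(width) + 0.5
    cy = np.arange(height) + 0.5
    px = cx[None, :, None]  # broadcast: (1, W, E)
    py = cy[:, None, None]  # (H, 1, E)

    # Even-odd ray casting: horizontal ray towards +x. An edge contributes
    # a crossing when it spans py vertically (half-open to handle shared
    # vertices once) and its intersection lies strictly right of the point.
    spans = (y1[None, None, :] > py) != (y2[None, None, :] > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    crossings = spans & (px < xint)
    inside = crossings.sum(axis=2) % 2 == 1
    return BinaryMask(inside)


def rasterize_ellipse(roi: EllipseROI, height: int, width: int) -> BinaryMask:
    """Rasterize an ellipse: pixel set iff its centre satisfies the
    rotated-ellipse inequality ``(u/a)^2 + (v/b)^2 <= 1``."""
    cx0, cy0 = roi.center
    if not (0 <= cx0 <= width and 0 <= cy0 <= height):
        raise GeometryError(
            f"ellipse centre {roi.center} outside {width}x{height} image"
        )
    a, b = roi.semi_axes
    theta = np.deg2rad(roi.rotation)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    cx = np.arange(width) + 0.5
    cy = np.arange(height) + 0.5
    dx = cx[None, :] - cx0
    dy = cy[:, None] - cy0
    u = dx * cos_t + dy * sin_t
    v = -dx * sin_t + dy * cos_t
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return BinaryMask(inside)


# ---------------------------------------------------------------------------
# ROI file format: a JSON array of polygon / ellipse records


def load_rois(path: str | Path) -> list[dict]:
    """Load ROI records from JSON.

    Each record is a dict with ``image_id``, ``type`` (``"polygon"`` or
    ``"ellipse"``) and a ``roi`` object (:class:`PolygonROI` or
    :class:`EllipseROI`); polygon records also carry ``tooth_id``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise FormatError("ROI file must contain a JSON array")
    records = []
    for i, item in enumerate(raw):
        kind = item.get("type")
        if kind == "polygon":
            roi: PolygonROI | EllipseROI = PolygonROI(
                [(v[0], v[1]) for v in item["vertices"]],
                tooth_id=item.get("tooth_id", ""),
            )
        elif kind == "ellipse":
            roi = EllipseROI(
                center=tuple(item["center"]),
                semi_axes=tuple(item["semi_axes"]),
                rotation=float(item.get("rotation_deg", 0.0)),
            )
        else:
            raise FormatError(f"ROI record {i}: unknown type {kind!r}")
        records.append(
            {
                "image_id": item.get("image_id", ""),
                "tooth_id": item.get("tooth_id", ""),
                "type": kind,
                "roi": roi,
            }
        )
    return records


def save_rois(records: Iterable[dict], path: str | Path) -> None:
    """Inverse of :func:`load_rois`."""
    out = []
    for rec in records:
        roi = rec["roi"]
        item: dict = {"image_id": rec.get("image_id", ""), "type": rec["type"]}
        if isinstance(roi, PolygonROI):
            item["tooth_id"] = roi.tooth_id or rec.get("tooth_id", "")
            item["vertices"] = [[x, y] for x, y in roi.vertices]
        elif isinstance(roi, EllipseROI):
            item["tooth_id"] = rec.get("tooth_id", "")
            item["center"] = list(roi.center)
            item["semi_axes"] = list(roi.semi_axes)
            item["rotation_deg"] = roi.rotation
        else:
            raise FormatError(f"cannot serialize ROI of type {type(roi)}")
        out.append(item)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
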