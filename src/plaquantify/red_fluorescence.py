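"""Red-fluorescent (undisclosed) plaque: dR% against a plaque-free reference.

Mature plaque fluoresces red without any disclosing agent. The measure used
here is the percentage elevation of the red/green ratio over a plaque-free
reference ellipse on the same tooth: per pixel

    dR = 100 * (r - r0) / r0,    r = R / G (real-valued),

with r0 the mean ratio over the reference region. Pixels whose dR reaches a
detection threshold (default 20%) count as red-fluorescent; the reported
dR% is the mean over detected pixels. Being ratio-of-ratios, the statistic
is invariant to global multiplicative illumination changes up to 8-bit
quantization.

Unlike the disclosed-coverage path this works in real arithmetic: dR% is a
continuous measure, not a pixel classification artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateReferenceError, GeometryError
from .image_model import (
    EllipseROI,
    FluorescenceImage,
    PolygonROI,
    rasterize_ellipse,
    rasterize_polygon,
)

__all__ = ["DeltaRResult", "delta_r"]


@dataclass
class DeltaRResult:
    """Per-tooth red-fluorescence summary.

    ``delta_r_pct`` is 0 with ``detected_pixels`` 0 when nothing within
    the ROI reaches the detection threshold.
    """

    tooth_id: str
    reference_ratio: float
    delta_r_pct: float
    detected_pixels: int
    red_area_mm2: float | None = None


def delta_r(
    img: FluorescenceImage,
    roi: PolygonROI,
    reference: EllipseROI,
    detection_threshold_pct: float = 20.0,
) -> DeltaRResult:
    """Quantify red fluorescence in ``roi`` relative to a reference ellipse.

    The reference must lie inside the tooth ROI and carry green signal.
    G = 0 pixels carry no usable ratio and are excluded from both the
    reference mean and detection.
    """
    h, w = img.height, img.width
    roi_mask = rasterize_polygon(roi, h, w).pixels
    ref_mask = rasterize_ellipse(reference, h, w).pixels
    if not ref_mask.any():
        raise GeometryError("reference ellipse rasterizes to an empty mask")
    if (ref_mask & ~roi_mask).any():
        raise GeometryError("reference ellipse extends outside the tooth ROI")

    r_chan = img.red.astype(float)
    g_chan = img.green.astype(float)
    valid = g_chan > 0

    ref_valid = ref_mask & valid
    if not ref_valid.any():
        raise DegenerateReferenceError("reference region has zero mean green signal")
    r0 = float((r_chan[ref_valid] / g_chan[ref_valid]).mean())
    if r0 <= 0:
        raise DegenerateReferenceError("reference mean red/green ratio is zero")

    sel = roi_mask & valid
    ratios = r_chan[sel] / g_chan[sel]
    dr = 100.0 * (ratios - r0) / r0
    # tolerance keeps pixels sitting exactly at the threshold detected
    # despite float round-off in the ratio
    detected = dr >= detection_threshold_pct - 1e-9
    n_det = int(detected.sum())
    mean_dr = float(dr[detected].mean()) if n_det else 0.0
    area = None
    if img.mm_per_pixel is not None:
        area = n_det * img.mm_per_pixel**2
    return DeltaRResult(
        tooth_id=roi.tooth_id,
        reference_ratio=r0,
        delta_r_pct=mean_dr,
        detected_pixels=n_det,
        red_area_mm2=area,
    )
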