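"""Intensity summaries of preprocessed Cherenkov images.

Two summaries are used to characterise signal strength: the mean grayscale
value (MGV) of a rectangular region covering the field, and the row-averaged
grayscale profile of the region along the superior-inferior axis (GPVCI).
MGV rises with electron energy (superficial dose is roughly linear in
energy) and with photon dose rate (FFF beams deposit more light per frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matching import IntensityProfile, RectROI, extract_profile
from .calibrate import PixelScale
from .specs import FieldImage

__all__ = ["IntensityMetrics", "mean_grayscale", "grayscale_profile",
           "default_metric_roi", "compute_metrics"]

#: default metric regions: 50 x 100 mm for photon fields, 50 x 75 mm for
#: electron fields, centred on the nominal field centre
PHOTON_MGV_ROI_MM = (50.0, 100.0)
ELECTRON_MGV_ROI_MM = (50.0, 75.0)


@dataclass
class IntensityMetrics:
    mgv: float
    gpvci: IntensityProfile
    roi: RectROI
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mgv < 0:
            raise ValueError("mgv must be >= 0")


def default_metric_roi(modality: str, field_center_x_mm: float | None = None) -> RectROI:
    """Default MGV/profile region for a modality, centred on the field.

    With the standard layout the photon field centre sits at X = -25 mm and
    the electron field centre at X = +25 mm.
    """
    if modality == "photon":
        w, h = PHOTON_MGV_ROI_MM
        cx = -25.0 if field_center_x_mm is None else field_center_x_mm
    elif modality == "electron":
        w, h = ELECTRON_MGV_ROI_MM
        cx = 25.0 if field_center_x_mm is None else field_center_x_mm
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return RectROI.centered(cx, 0.0, w, h)


def mean_grayscale(image: FieldImage, roi: RectROI, scale: PixelScale | None = None) -> float:
    """Arithmetic mean of the pixel values inside the region."""
    rows, cols = roi.to_pixel_bounds(image, scale)
    return float(image.pixels[rows, cols].mean())


def grayscale_profile(
    image: FieldImage, roi: RectROI, scale: PixelScale | None = None
) -> IntensityProfile:
    """Row-averaged intensity profile of the region along X (same contract
    as the matching module's profile extraction)."""
    return extract_profile(image, roi, scale)


def compute_metrics(
    image: FieldImage, roi: RectROI, scale: PixelScale | None = None
) -> IntensityMetrics:
    return IntensityMetrics(
        mgv=mean_grayscale(image, roi, scale),
        gpvci=grayscale_profile(image, roi, scale),
        roi=roi,
        metadata=dict(image.metadata),
    )
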