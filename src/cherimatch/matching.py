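"""Field-junction matching from composite difference images.

The procedure: preprocess the photon and electron stacks; sum the two
zero-shift images into a reference composite; sum the shifted field's image
with the other field's zero-shift image into a shifted composite; take the
absolute pixel difference, which leaves a bright band at the junction whose
width equals the field displacement; average the band over a rectangular
region of interest into a 1-D profile along the superior-inferior (X) axis;
measure the profile's full width at half maximum; and convert that width to
millimetres with the calibrated pixel scale.  The FWHM in millimetres is the
measured matching value; its difference from the introduced couch shift is
the matching error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import PixelScale
from .preprocess import preprocess_stack
from .specs import FieldImage, ImageStack

__all__ = [
    "RectROI",
    "IntensityProfile",
    "MatchResult",
    "MatchingConfig",
    "FlatProfileError",
    "compose_reference",
    "compose_shifted",
    "difference_image",
    "extract_profile",
    "profile_fwhm",
    "measure_matching",
]


class FlatProfileError(ValueError):
    """Raised when a profile has no measurable band above its baseline."""


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle in isocenter-plane millimetre coordinates.

    The origin sits at the image centre; X increases toward inferior.
    """

    x_min_mm: float
    y_min_mm: float
    width_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("ROI must have positive extent")

    @classmethod
    def centered(cls, cx_mm: float, cy_mm: float, width_mm: float, height_mm: float) -> "RectROI":
        return cls(cx_mm - width_mm / 2.0, cy_mm - height_mm / 2.0, width_mm, height_mm)

    def to_pixel_bounds(
        self, image: FieldImage, scale: PixelScale | None = None
    ) -> tuple[slice, slice]:
        """Resolve to (row_slice, col_slice) on the image grid.

        Raises ``ValueError`` with a clipped suggestion if the rectangle
        falls outside the image.
        """
        px_per_mm = scale.px_per_mm if scale is not None else image.pixel_scale
        ny, nx = image.shape
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        c0 = int(round(cx + self.x_min_mm * px_per_mm))
        c1 = int(round(cx + (self.x_min_mm + self.width_mm) * px_per_mm))
        r0 = int(round(cy + self.y_min_mm * px_per_mm))
        r1 = int(round(cy + (self.y_min_mm + self.height_mm) * px_per_mm))
        if c0 < 0 or r0 < 0 or c1 > nx or r1 > ny:
            clipped = (max(r0, 0), min(r1, ny), max(c0, 0), min(c1, nx))
            raise ValueError(
                f"ROI pixel bounds rows [{r0}, {r1}), cols [{c0}, {c1}) fall outside the "
                f"{ny}x{nx} image; nearest valid bounds: rows [{clipped[0]}, {clipped[1]}), "
                f"cols [{clipped[2]}, {clipped[3]})"
            )
        if c1 <= c0 or r1 <= r0:
            raise ValueError("ROI resolves to an empty pixel rectangle")
        return slice(r0, r1), slice(c0, c1)


@dataclass
class IntensityProfile:
    """Column-averaged intensity along X within an ROI."""

    positions_px: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_px.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        if np.any(np.diff(self.positions_px) <= 0):
            raise ValueError("positions_px must be strictly increasing")


@dataclass
class MatchingConfig:
    """Knobs of the matching measurement."""

    detect_threshold: float = 2.0
    apply_offset_correction: bool = False
    systematic_offset_mm: float = 0.55
    smooth_kernel: tuple[int, int] = (10, 10)


@dataclass
class MatchResult:
    """Outcome of one matching measurement.

    When the difference band is not detectable above the background noise
    (``detectable`` False), the measured value and discrepancy are ``None``
    unless the introduced shift was declared zero, in which case the
    measurement correctly reports zero.
    """

    introduced_shift_mm: float
    measured_matching_mm: float | None
    discrepancy_mm: float | None
    detectable: bool
    snr: float
    peak_value: float | None = None
    half_max_value: float | None = None
    roi: RectROI | None = None
    scale: PixelScale | None = None
    metadata: dict = field(default_factory=dict)


# junction window: the difference band spans [0, k] mm on one side of the
# match line, so the window must cover the largest tested shift (10 mm) plus
# penumbra on either side
DEFAULT_MATCH_ROI = RectROI.centered(0.0, 0.0, 30.0, 30.0)


def _check_compatible(a: FieldImage, b: FieldImage) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.pixel_scale != b.pixel_scale:
        raise ValueError(f"pixel scales differ: {a.pixel_scale} vs {b.pixel_scale}")


def _compose(a: FieldImage, b: FieldImage, max_value: float | None) -> FieldImage:
    _check_compatible(a, b)
    total = a.pixels + b.pixels
    clip_fraction = 0.0
    if max_value is not None:
        clipped = total > max_value
        clip_fraction = float(clipped.mean())
        total = np.minimum(total, max_value)
    return a.with_pixels(total, kind="composite", clip_fraction=clip_fraction)


def compose_reference(
    photon_ref: FieldImage, electron_ref: FieldImage, max_value: float | None = 65535.0
) -> FieldImage:
    """Sum the zero-shift photon and electron images into the reference
    composite, clipping at the bit-depth maximum (clipped fraction recorded
    in metadata)."""
    out = _compose(photon_ref, electron_ref, max_value)
    out.metadata["shifted_field"] = None
    return out


def compose_shifted(
    shifted_img: FieldImage,
    unshifted_other: FieldImage,
    max_value: float | None = 65535.0,
    shifted_field: str | None = None,
) -> FieldImage:
    """Sum a shifted field's image with the other field's zero-shift image."""
    out = _compose(shifted_img, unshifted_other, max_value)
    if shifted_field is None:
        shifted_field = (shifted_img.metadata.get("beam") or {}).get("modality")
    out.metadata["shifted_field"] = shifted_field
    return out


def difference_image(shifted_composite: FieldImage, reference: FieldImage) -> FieldImage:
    """Absolute pixel difference between the shifted composite and the
    reference: both gap and overlap mismatches produce a positive band."""
    _check_compatible(shifted_composite, reference)
    return shifted_composite.with_pixels(
        np.abs(shifted_composite.pixels - reference.pixels), kind="difference"
    )


def extract_profile(
    image: FieldImage, roi: RectROI, scale: PixelScale | None = None
) -> IntensityProfile:
    """Mean over the ROI's rows for each X column inside the ROI."""
    rows, cols = roi.to_pixel_bounds(image, scale)
    values = image.pixels[rows, cols].mean(axis=0)
    positions = np.arange(cols.start, cols.stop, dtype=float)
    return IntensityProfile(positions_px=positions, values=values)


def profile_fwhm(profile: IntensityProfile) -> tuple[float, float, float]:
    """Full width at half maximum of a profile, in pixels.

    The baseline is the median of the lowest quartile of profile values; the
    half level sits midway between baseline and the global maximum.  The
    width is the distance between the outermost crossings of the half level
    on either side of the global peak, linearly interpolated between
    adjacent samples.

    Returns ``(width_px, peak_value, half_level)``.  Raises
    :class:`FlatProfileError` if the peak does not rise above the baseline.
    """
    v = profile.values
    x = profile.positions_px
    n = v.size
    if n < 3:
        raise FlatProfileError("profile too short to measure a width")
    baseline = float(np.median(np.sort(v)[: max(1, n // 4)]))
    peak_idx = int(np.argmax(v))
    peak = float(v[peak_idx])
    if peak <= baseline:
        raise FlatProfileError("no measurable band: profile peak does not exceed the baseline")
    half = baseline + (peak - baseline) / 2.0

    def interp_crossing(i: int, j: int) -> float:
        # linear interpolation of the half-level crossing between samples i, j
        if v[j] == v[i]:
            return float(x[j])
        t = (half - v[i]) / (v[j] - v[i])
        return float(x[i] + t * (x[j] - x[i]))

    # outermost crossings: the first rise through the half level scanning in
    # from the left end, and the last fall scanning out to the right end
    trans_left = np.flatnonzero((v[:peak_idx] < half) & (v[1 : peak_idx + 1] >= half))
    if trans_left.size:
        i = int(trans_left[0])
        left = interp_crossing(i, i + 1)
    else:
        left = float(x[0])
    trans_right = np.flatnonzero((v[peak_idx:-1] >= half) & (v[peak_idx + 1 :] < half))
    if trans_right.size:
        j = peak_idx + int(trans_right[-1])
        right = interp_crossing(j, j + 1)
    else:
        right = float(x[-1])
    return right - left, peak, half


def background_sd_in_roi(
    stacks: list[ImageStack], roi: RectROI, scale: PixelScale | None = None
) -> float:
    """Background noise level inside the ROI.

    Standard deviation of the per-pixel temporal median of each stack's
    background frames (the same aggregate subtracted from the signal path),
    pooled over stacks; the temporal median rejects sparkle impulses that
    would otherwise inflate the estimate.
    """
    samples = []
    for st in stacks:
        rows, cols = roi.to_pixel_bounds(st.background_frames[0], scale)
        med = np.median(st.background_array()[:, rows, cols], axis=0)
        samples.append(med.ravel())
    return float(np.std(np.concatenate(samples)))


def measure_from_preprocessed(
    photon_ref: FieldImage,
    electron_ref: FieldImage,
    shifted_img: FieldImage | None,
    shifted_field: str | None,
    introduced_shift_mm: float,
    background_sd: float,
    roi: RectROI = DEFAULT_MATCH_ROI,
    scale: PixelScale | None = None,
    config: MatchingConfig | None = None,
    max_value: float = 65535.0,
) -> MatchResult:
    """Matching measurement from already-preprocessed single images.

    ``shifted_img`` is the preprocessed image of the displaced field (or an
    independent zero-shift realization for the null control); the other
    field's zero-shift image is taken from the references.  This is the
    computational core of :func:`measure_matching`, split out so batch
    runners can reuse preprocessed reference images across scenarios.
    """
    config = config or MatchingConfig()
    reference = compose_reference(photon_ref, electron_ref, max_value=max_value)
    if shifted_img is None:
        shifted = compose_reference(photon_ref, electron_ref, max_value=max_value)
    elif shifted_field == "photon":
        shifted = compose_shifted(shifted_img, electron_ref, max_value=max_value,
                                  shifted_field="photon")
    elif shifted_field == "electron":
        shifted = compose_shifted(photon_ref, shifted_img, max_value=max_value,
                                  shifted_field="electron")
    else:
        raise ValueError("shifted_field must be 'photon' or 'electron' when a shifted image is given")
    introduced = introduced_shift_mm

    diff = difference_image(shifted, reference)
    profile = extract_profile(diff, roi, scale)
    bg_sd = background_sd

    baseline = float(np.median(np.sort(profile.values)[: max(1, profile.values.size // 4)]))
    peak = float(profile.values.max())
    snr = (peak - baseline) / bg_sd if bg_sd > 0 else np.inf

    result_meta = {
        "shifted_field": shifted.metadata.get("shifted_field"),
        "clip_fraction": shifted.metadata.get("clip_fraction", 0.0),
    }
    if snr < config.detect_threshold:
        if abs(introduced) == 0.0:
            # declared zero shift: no band is the correct answer
            return MatchResult(introduced, 0.0, 0.0, True, snr,
                               roi=roi, scale=scale, metadata=result_meta)
        return MatchResult(introduced, None, None, False, snr,
                           roi=roi, scale=scale, metadata=result_meta)

    try:
        width_px, peak_value, half = profile_fwhm(profile)
    except FlatProfileError:
        if abs(introduced) == 0.0:
            return MatchResult(introduced, 0.0, 0.0, True, snr,
                               roi=roi, scale=scale, metadata=result_meta)
        return MatchResult(introduced, None, None, False, snr,
                           roi=roi, scale=scale, metadata=result_meta)
    px_per_mm = scale.px_per_mm if scale is not None else diff.pixel_scale
    measured = width_px / px_per_mm
    if config.apply_offset_correction:
        measured = max(measured - config.systematic_offset_mm, 0.0)
    discrepancy = measured - abs(introduced)
    return MatchResult(
        introduced_shift_mm=introduced,
        measured_matching_mm=measured,
        discrepancy_mm=discrepancy,
        detectable=True,
        snr=snr,
        peak_value=peak_value,
        half_max_value=half,
        roi=roi,
        scale=scale,
        metadata=result_meta,
    )


def signed_introduced_shift(stack: ImageStack | None) -> float:
    """Signed introduced shift (mm, + = inferior) recorded in a stack's
    scenario metadata; 0 when absent."""
    if stack is None:
        return 0.0
    shift_meta = stack.metadata.get("shift")
    if not shift_meta:
        return 0.0
    sign = 1.0 if shift_meta.get("direction", "inferior") == "inferior" else -1.0
    return sign * float(shift_meta.get("magnitude_mm", 0.0))


def measure_matching(
    photon_stack: ImageStack,
    electron_stack: ImageStack,
    photon_stack_shifted: ImageStack | None = None,
    electron_stack_shifted: ImageStack | None = None,
    roi: RectROI = DEFAULT_MATCH_ROI,
    scale: PixelScale | None = None,
    config: MatchingConfig | None = None,
) -> MatchResult:
    """Run the full matching measurement for one condition from raw stacks.

    Preprocesses every stack, composes the reference (zero-shift photon +
    electron) and the shifted composite (the shifted stack summed with the
    other field's reference), and measures the difference-band FWHM.  At
    most one shifted stack may be given; with neither, the zero-shift
    control path is evaluated (the difference of identical composites is
    identically zero, so independent stacks should be passed as "shifted"
    zero-shift acquisitions to exercise the null against real noise).

    The band's signal-to-noise ratio is the profile peak minus baseline
    over the per-pixel standard deviation of the raw background frames
    inside the ROI; below ``config.detect_threshold`` the band is declared
    undetectable.
    """
    if photon_stack_shifted is not None and electron_stack_shifted is not None:
        raise ValueError("provide at most one shifted stack")
    config = config or MatchingConfig()

    photon_ref = preprocess_stack(photon_stack, kernel=config.smooth_kernel)
    electron_ref = preprocess_stack(electron_stack, kernel=config.smooth_kernel)
    bit_depth = (photon_stack.metadata.get("acquisition") or {}).get("bit_depth", 16)
    max_value = float(2**bit_depth - 1)

    shifted_stack = photon_stack_shifted or electron_stack_shifted
    if shifted_stack is None:
        shifted_img, shifted_field = None, None
    else:
        shifted_img = preprocess_stack(shifted_stack, kernel=config.smooth_kernel)
        shifted_field = "photon" if photon_stack_shifted is not None else "electron"

    noise_stacks = [photon_stack, electron_stack]
    if shifted_stack is not None:
        noise_stacks.append(shifted_stack)
    bg_sd = background_sd_in_roi(noise_stacks, roi, scale)

    return measure_from_preprocessed(
        photon_ref,
        electron_ref,
        shifted_img,
        shifted_field,
        signed_introduced_shift(shifted_stack),
        bg_sd,
        roi=roi,
        scale=scale,
        config=config,
        max_value=max_value,
    )
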