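"""Scenario descriptions for simulated Cherenkov luminescence acquisitions.

A scenario is the combination of a treatment beam (:class:`BeamSpec`), the
optical properties of the irradiated tissue (:class:`TissueSpec`), the camera
settings (:class:`AcquisitionSpec`) and an introduced couch shift
(:class:`ShiftSpec`).  Images produced under a scenario are carried around as
:class:`FieldImage` / :class:`ImageStack` objects which keep the pixel data
together with the pixel scale and provenance metadata.

Coordinate convention
---------------------
Image arrays are indexed ``pixels[row, col]``.  The column axis is the
superior--inferior match axis (called X throughout); X increases toward
inferior, so a "superior" couch shift is a negative X translation.  Physical
(millimetre) coordinates place the origin at the image centre, i.e. at the
accelerator isocenter projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "PHOTON_ENERGIES_MV",
    "ELECTRON_ENERGIES_MEV",
    "DOSE_RATES",
    "BeamSpec",
    "TissueSpec",
    "AcquisitionSpec",
    "ShiftSpec",
    "FieldImage",
    "ImageStack",
]

PHOTON_ENERGIES_MV = (6.0, 10.0)
ELECTRON_ENERGIES_MEV = (4.0, 6.0, 8.0, 10.0, 12.0, 15.0)
DOSE_RATES = (600.0, 1200.0, 2400.0)

#: Obliquity (degrees off normal incidence) assigned to the tangential
#: gantry angles used for chest-wall fields.  Both 330 and 150 deg are 30 deg
#: off the AP axis.
OBLIQUE_GANTRY_ANGLES = (330.0, 150.0)


@dataclass(frozen=True)
class BeamSpec:
    """A treatment beam: modality, energy, dose rate and incidence geometry.

    Photon beams are either conventional (flattened, 600 MU/min) or
    flattening-filter-free (FFF; 1200 MU/min for 6 FFF, 2400 MU/min for
    10 FFF).  Electron beams run at 600 MU/min.  ``gantry_angle_deg`` is 0
    for anterior-posterior (AP) incidence or 330/150 deg for the tangential
    oblique fields.
    """

    modality: Literal["photon", "electron"]
    nominal_energy: float
    dose_rate: float = 600.0
    fff_flag: bool = False
    gantry_angle_deg: float = 0.0
    field_size_mm: tuple[float, float] = (50.0, 50.0)
    ssd_mm: float = 1017.0

    def __post_init__(self) -> None:
        if self.modality not in ("photon", "electron"):
            raise ValueError(f"modality must be 'photon' or 'electron', got {self.modality!r}")
        supported = PHOTON_ENERGIES_MV if self.modality == "photon" else ELECTRON_ENERGIES_MEV
        if float(self.nominal_energy) not in supported:
            unit = "MV" if self.modality == "photon" else "MeV"
            raise ValueError(
                f"unsupported {self.modality} energy {self.nominal_energy} {unit}; "
                f"supported values: {', '.join(str(e) for e in supported)} {unit}"
            )
        if float(self.dose_rate) not in DOSE_RATES:
            raise ValueError(f"dose_rate must be one of {DOSE_RATES}, got {self.dose_rate}")
        if self.fff_flag and self.modality != "photon":
            raise ValueError("fff_flag applies to photon beams only")
        if self.dose_rate > 600.0 and not self.fff_flag:
            raise ValueError("dose rates above 600 MU/min require an FFF photon beam")
        if self.gantry_angle_deg not in (0.0,) + OBLIQUE_GANTRY_ANGLES:
            raise ValueError(
                f"gantry_angle_deg must be 0 (AP) or one of {OBLIQUE_GANTRY_ANGLES}, "
                f"got {self.gantry_angle_deg}"
            )
        if min(self.field_size_mm) <= 0:
            raise ValueError("field_size_mm entries must be positive")

    @property
    def obliquity_deg(self) -> float:
        """Angle off normal incidence: 0 for AP, 30 for gantry 330/150."""
        return 0.0 if self.gantry_angle_deg == 0.0 else 30.0

    @property
    def is_exit_side(self) -> bool:
        """True for the gantry-150 field imaged from the radiation exit side."""
        return self.gantry_angle_deg == 150.0


@dataclass(frozen=True)
class TissueSpec:
    """Optical properties of the tissue phantom surface.

    ``absorption_factor`` multiplies every emitted intensity; dark tissue
    absorbs most of the visible Cherenkov light, so its factor is far below
    the light (yellow) tissue's.
    """

    color: Literal["yellow", "black"] = "yellow"
    absorption_factor: float = None  # type: ignore[assignment]
    surface_roughness_mm: float = 0.0

    _DEFAULT_ABSORPTION = {"yellow": 1.0, "black": 0.05}

    def __post_init__(self) -> None:
        if self.color not in ("yellow", "black"):
            raise ValueError(f"color must be 'yellow' or 'black', got {self.color!r}")
        if self.absorption_factor is None:
            object.__setattr__(self, "absorption_factor", self._DEFAULT_ABSORPTION[self.color])
        if not 0.0 < self.absorption_factor <= 1.0:
            raise ValueError("absorption_factor must lie in (0, 1]")
        if self.surface_roughness_mm < 0:
            raise ValueError("surface_roughness_mm must be >= 0")


@dataclass(frozen=True)
class AcquisitionSpec:
    """CCD camera settings and noise levels for one acquisition series.

    Integration times follow the experimental protocol: 1 s for photon and
    1.2 s for electron irradiation of light tissue; doubled-plus for dark
    tissue (2 s / 2.5 s), which barely emits in the camera's sensitive band.
    Background offset and read-noise accumulate with integration time, so
    ``background_mean``/``background_sd`` are stored per acquisition (already
    scaled by integration time when built via :meth:`default_for`).
    """

    gain_db: float = 36.0
    integration_time_s: float = 1.0
    pixel_scale_true: float = 3.6
    background_mean: float = 200.0
    background_sd: float = 300.0
    sparkle_rate: float = 30.0
    frames_per_condition: int = 3
    bit_depth: int = 16
    shot_noise: bool = True
    rng_seed: Optional[int] = None

    #: baseline background levels per second of integration
    BACKGROUND_MEAN_PER_S = 200.0
    BACKGROUND_SD_PER_S = 300.0

    def __post_init__(self) -> None:
        if self.frames_per_condition < 3:
            raise ValueError("frames_per_condition must be >= 3")
        if self.integration_time_s <= 0:
            raise ValueError("integration_time_s must be positive")
        for name in ("background_mean", "background_sd", "sparkle_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_scale_true <= 0:
            raise ValueError("pixel_scale_true must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @classmethod
    def default_for(cls, beam: BeamSpec, tissue: TissueSpec, **overrides) -> "AcquisitionSpec":
        """Protocol integration time for the beam/tissue pair, with background
        statistics scaled by the integration time."""
        if tissue.color == "black":
            t = 2.0 if beam.modality == "photon" else 2.5
        else:
            t = 1.0 if beam.modality == "photon" else 1.2
        base = dict(
            integration_time_s=t,
            background_mean=cls.BACKGROUND_MEAN_PER_S * t,
            background_sd=cls.BACKGROUND_SD_PER_S * t,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ShiftSpec:
    """A deliberate couch shift used as ground truth for matching validation."""

    magnitude_mm: float = 0.0
    direction: Literal["superior", "inferior"] = "inferior"
    shifted_field: Literal["photon", "electron"] = "photon"

    def __post_init__(self) -> None:
        if self.magnitude_mm < 0:
            raise ValueError("magnitude_mm must be >= 0")
        if self.direction not in ("superior", "inferior"):
            raise ValueError(f"direction must be 'superior' or 'inferior', got {self.direction!r}")
        if self.shifted_field not in ("photon", "electron"):
            raise ValueError("shifted_field must be 'photon' or 'electron'")

    @property
    def signed_mm(self) -> float:
        """Signed displacement along X (+ = inferior)."""
        sign = 1.0 if self.direction == "inferior" else -1.0
        return sign * self.magnitude_mm


@dataclass
class FieldImage:
    """One 2-D grayscale frame with its pixel scale and provenance metadata."""

    pixels: np.ndarray
    pixel_scale: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **meta_updates) -> "FieldImage":
        md = dict(self.metadata)
        md.update(meta_updates)
        return FieldImage(pixels=pixels, pixel_scale=self.pixel_scale, metadata=md)

    def x_mm(self) -> np.ndarray:
        """Millimetre coordinate of each column, origin at image centre."""
        n = self.pixels.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) / self.pixel_scale

    def y_mm(self) -> np.ndarray:
        n = self.pixels.shape[0]
        return (np.arange(n) - (n - 1) / 2.0) / self.pixel_scale


@dataclass
class ImageStack:
    """Repeated irradiation frames plus radiation-off background frames."""

    frames: list
    background_frames: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("stack must contain at least one frame")
        shape = self.frames[0].shape
        scale = self.frames[0].pixel_scale
        for f in list(self.frames) + list(self.background_frames):
            if f.shape != shape:
                raise ValueError(f"all frames must share shape {shape}, got {f.shape}")
            if f.pixel_scale != scale:
                raise ValueError("all frames must share the same pixel_scale")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def pixel_scale(self) -> float:
        return self.frames[0].pixel_scale

    def frame_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])

    def background_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.background_frames])

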