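"""Reading and writing frame stacks and scenario configurations.

Stacks are stored as multi-page 16-bit grayscale TIFF files (irradiation
frames followed by background frames) with a JSON sidecar holding the
scenario metadata and pixel scale.  Scenario configurations are YAML files
with keys mirroring the beam / tissue / acquisition / shift dataclasses.
8-bit input images are accepted and promoted to the internal float
representation on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .specs import (
    AcquisitionSpec,
    BeamSpec,
    FieldImage,
    ImageStack,
    ShiftSpec,
    TissueSpec,
)

__all__ = [
    "write_stack",
    "read_stack",
    "write_image",
    "read_image",
    "load_scenario_yaml",
    "scenario_to_dict",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: FieldImage, path: str | Path) -> Path:
    """Write a single frame as 16-bit TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16))
    sidecar = {"pixel_scale": image.pixel_scale, "metadata": _jsonable(image.metadata)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image(path: str | Path) -> FieldImage:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        raise ValueError(f"{path} is a multi-page stack; use read_stack")
    sidecar = _read_sidecar(path)
    return FieldImage(
        pixels=np.asarray(data, dtype=float),
        pixel_scale=float(sidecar.get("pixel_scale", 1.0)),
        metadata=sidecar.get("metadata", {}),
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write irradiation + background frames as one multi-page 16-bit TIFF.

    Page order: the N irradiation frames, then the N background frames; the
    sidecar records the split point, pixel scale and full scenario metadata.
    """
    path = Path(path)
    pages = [f.pixels for f in stack.frames] + [f.pixels for f in stack.background_frames]
    arr = np.clip(np.round(np.stack(pages)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)
    sidecar = {
        "pixel_scale": stack.pixel_scale,
        "n_frames": len(stack.frames),
        "n_background": len(stack.background_frames),
        "metadata": _jsonable(stack.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    sidecar = _read_sidecar(path)
    n = int(sidecar.get("n_frames", arr.shape[0]))
    scale = float(sidecar.get("pixel_scale", 1.0))
    meta = sidecar.get("metadata", {})
    frames = [FieldImage(a, scale, dict(meta)) for a in arr[:n]]
    backgrounds = [FieldImage(a, scale, dict(meta)) for a in arr[n:]]
    if not backgrounds:
        # allow stacks without stored backgrounds; preprocessing will reject
        backgrounds = []
    return ImageStack(frames=frames, background_frames=backgrounds, metadata=meta)


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_scenario_yaml(path: str | Path) -> dict:
    """Load a scenario configuration: beam / tissue / acquisition / shift
    sections mapped onto the corresponding spec dataclasses.

    Returns a dict with keys ``beam``, ``tissue``, ``acq``, ``shift``
    (``shift`` may be None) plus any extra top-level keys (e.g. ``seed``).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    beam = BeamSpec(**{**{"modality": "photon", "nominal_energy": 6.0}, **raw.get("beam", {})})
    tissue = TissueSpec(**raw.get("tissue", {}))
    acq_kwargs = raw.get("acquisition", {})
    acq = (AcquisitionSpec(**acq_kwargs) if acq_kwargs
           else AcquisitionSpec.default_for(beam, tissue))
    shift = ShiftSpec(**raw["shift"]) if raw.get("shift") else None
    extras = {k: v for k, v in raw.items()
              if k not in ("beam", "tissue", "acquisition", "shift")}
    return {"beam": beam, "tissue": tissue, "acq": acq, "shift": shift, **extras}


def scenario_to_dict(beam, tissue, acq, shift=None) -> dict:
    from dataclasses import asdict

    out = {"beam": asdict(beam), "tissue": asdict(tissue), "acquisition": asdict(acq)}
    if shift is not None:
        out["shift"] = asdict(shift)
    return out
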