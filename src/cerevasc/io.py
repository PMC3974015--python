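"""On-disk formats: float TIFF images with JSON metadata sidecars, CSV tables,
JSON fit/report/provenance records and YAML run configuration."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import FormatError
from .image import RADIANCE_UNITS, LuminescenceImage
from .physics import CalibrationFit, CameraSpec
from .quantify import ROI, PolygonROI, VesselMeasurement

__all__ = [
    "sidecar_path",
    "write_image",
    "read_image",
    "write_rois",
    "read_rois",
    "write_measurements_csv",
    "read_measurements_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "write_fit_json",
    "write_json",
    "write_provenance",
    "load_config",
]


def sidecar_path(image_path: str | Path) -> Path:
    """JSON metadata sidecar: identical basename, ``.json`` suffix."""
    return Path(image_path).with_suffix(".json")


def write_image(image: LuminescenceImage, path: str | Path) -> Path:
    """Write a 32-bit float single-channel TIFF plus its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.data.astype(np.float32))
    meta = {**image.camera.to_dict(), "units": image.units, **image.meta}
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_image(
    path: str | Path,
    camera: CameraSpec | None = None,
    units: str = RADIANCE_UNITS,
) -> LuminescenceImage:
    """Read a float TIFF and its sidecar back into a LuminescenceImage.

    ``camera`` supplies metadata for legacy images without a sidecar (a
    provenance note is recorded in ``image.meta``); otherwise a missing
    sidecar is an error naming the expected path.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if not np.issubdtype(data.dtype, np.floating):
        raise FormatError(f"{path}: expected a float TIFF, got dtype {data.dtype}")
    side = sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        file_units = meta.pop("units", None)
        if file_units != units:
            raise FormatError(
                f"{side}: units {file_units!r} do not match expected {units!r}"
            )
        cam = CameraSpec(
            fov_mm=meta.pop("fov_mm"), n_pixels=meta.pop("n_pixels"),
            f_stop=meta.pop("f_stop", 1.0), exposure_s=meta.pop("exposure_s", 300.0),
        )
        return LuminescenceImage(data.astype(float), cam, units=units, meta=meta)
    if camera is None:
        raise FormatError(f"{path}: missing metadata sidecar (expected {side})")
    img = LuminescenceImage(data.astype(float), camera, units=units)
    img.meta["provenance"] = "metadata supplied by caller; no sidecar on disk"
    return img


# --- ROIs -------------------------------------------------------------------

def write_rois(rois: Sequence, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"rois": [r.to_dict() for r in rois]}, indent=1))
    return path


def read_rois(path: str | Path) -> list:
    payload = json.loads(Path(path).read_text())
    out = []
    for entry in payload["rois"]:
        kind = entry.get("type", "rect")
        if kind == "rect":
            out.append(ROI(x=entry["x"], y=entry["y"], width=entry["w"],
                           height=entry["h"], label=entry.get("label", "")))
        elif kind == "polygon":
            out.append(PolygonROI(
                vertices=tuple(tuple(v) for v in entry["vertices"]),
                label=entry.get("label", ""),
            ))
        else:
            raise FormatError(f"{path}: unknown ROI type {kind!r}")
    return out


# --- tables -----------------------------------------------------------------

def write_measurements_csv(
    measurements: Iterable[VesselMeasurement], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([m.to_dict() for m in measurements])
    frame.to_csv(path, index=False)
    return path


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"label", "attenuation"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_calibration_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read (activity_mbq, radiance) pairs from a calibration table."""
    frame = pd.read_csv(path)
    missing = {"activity_mbq", "radiance"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return list(zip(frame["activity_mbq"].astype(float),
                    frame["radiance"].astype(float)))


def write_calibration_csv(
    pairs: Iterable[tuple[float, float]], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(pairs, columns=["activity_mbq", "radiance"]).to_csv(
        path, index=False
    )
    return path


def write_fit_json(fit: CalibrationFit, path: str | Path) -> Path:
    return write_json(fit.to_dict(), path)


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


# --- provenance and configuration -------------------------------------------

def config_digest(payload: dict) -> str:
    """Stable sha256 of a JSON-serializable configuration."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_provenance(
    path: str | Path, command: str, inputs: dict, seed: int | None
) -> Path:
    """Record what produced an output: command, inputs, seed, version, digest.

    Deliberately excludes timestamps so identical reruns produce identical
    provenance records.
    """
    record = {
        "command": command,
        "inputs": inputs,
        "seed": seed,
        "version": __version__,
    }
    record["config_digest"] = config_digest(record)
    return write_json(record, path)


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run configuration; CLI flags override these values."""
    if path is None:
        return {}
    payload = yaml.safe_load(Path(path).read_text())
    if payload is None:
        return {}
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return payload
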