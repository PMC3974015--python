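"""The in-memory image container shared by simulation, quantification and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

from .physics import CameraSpec

RADIANCE_UNITS = "p/s/cm2/sr"


@dataclass
class LuminescenceImage:
    """A 2-D radiance map with camera metadata.

    ``data`` is a float array in photons/s/cm^2/sr, row-major with the
    origin at the top-left; pixel centers sit at (i + 0.5, j + 0.5) in
    pixel units and physical mm = pixel * camera.pixel_size_mm.
    """

    data: np.ndarray
    camera: CameraSpec
    units: str = RADIANCE_UNITS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"image data must be 2-D, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_size_mm(self) -> float:
        return self.camera.pixel_size_mm

    def with_data(self, data: np.ndarray) -> "LuminescenceImage":
        """Copy of this image with new pixel data, same metadata."""
        return replace(self, data=np.asarray(data, dtype=float))


def as_array(image) -> np.ndarray:
    """Accept a LuminescenceImage or a bare 2-D array."""
    if isinstance(image, LuminescenceImage):
        return image.data
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image array")
    return arr
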