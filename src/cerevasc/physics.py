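"""Radioactive-decay arithmetic, radiance-activity calibration and camera geometry.

Cerenkov luminescence imaging (CLI) quantifies surface radiance in the IVIS
camera's calibrated unit, photons/s/cm^2/sr.  Every downstream stage of the
pipeline relies on three pieces of bookkeeping that live here:

* exponential decay of the injected nuclide (activities are only comparable
  after correction to a common reference time),
* the linear radiance-vs-activity calibration measured on a well-plate
  phantom, whose slope is the nuclide's effective light yield
  (radiance per MBq), and
* camera geometry: field of view, pixel pitch and the f-number's
  inverse-square effect on collected signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateFitError

__all__ = [
    "RadionuclideSpec",
    "ActivitySample",
    "CalibrationFit",
    "CameraSpec",
    "GA68",
    "F18",
    "NUCLIDES",
    "decay_factor",
    "decay_correct_activity",
    "fit_radiance_vs_activity",
    "light_yield_ratio",
    "fstop_signal_factor",
    "pixel_size_mm",
]


@dataclass(frozen=True)
class RadionuclideSpec:
    """Physical description of a beta-emitting nuclide.

    Parameters
    ----------
    name
        Display label, e.g. ``"Ga-68"``.
    half_life_min
        Physical half-life in minutes.  Must be positive.
    light_yield
        Effective surface radiance per unit activity, in
        photons/s/cm^2/sr per MBq.  This is an *empirical* calibration
        constant (the slope of the phantom regression), not a Frank-Tamm
        prediction; it is used by the forward simulator.
    """

    name: str
    half_life_min: float
    light_yield: float = 0.0

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError(f"half_life_min must be > 0, got {self.half_life_min}")
        if self.light_yield < 0:
            raise ValueError(f"light_yield must be >= 0, got {self.light_yield}")


#: Gallium-68 (nuclide-table half-life; light yield from phantom calibration).
GA68 = RadionuclideSpec("Ga-68", half_life_min=67.71, light_yield=1.52e6)
#: Fluorine-18.
F18 = RadionuclideSpec("F-18", half_life_min=109.77, light_yield=1.28e5)

NUCLIDES = {n.name: n for n in (GA68, F18)}


@dataclass(frozen=True)
class ActivitySample:
    """An activity measured (or injected) a known time before/after reference.

    ``elapsed_min`` is minutes since the reference time (e.g. injection).
    """

    activity_mbq: float
    elapsed_min: float

    def __post_init__(self) -> None:
        if self.activity_mbq < 0:
            raise ValueError(f"activity_mbq must be >= 0, got {self.activity_mbq}")
        if self.elapsed_min < 0:
            raise ValueError(f"elapsed_min must be >= 0, got {self.elapsed_min}")


@dataclass(frozen=True)
class CalibrationFit:
    """Result of the radiance-vs-activity linear regression.

    ``slope`` is the light yield in photons/s/cm^2/sr per MBq; ``intercept``
    absorbs any ambient/dark floor; ``r_squared`` is the OLS coefficient of
    determination.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a calibration fit needs at least 2 points")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class CameraSpec:
    """Square-detector camera geometry (IVIS-style).

    ``fov_mm`` is the edge length of the square field of view; ``n_pixels``
    the pixel count per edge.  Pixel pitch is ``fov_mm / n_pixels``.
    """

    fov_mm: float
    n_pixels: int
    f_stop: float = 1.0
    exposure_s: float = 300.0

    def __post_init__(self) -> None:
        for field in ("fov_mm", "n_pixels", "f_stop", "exposure_s"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be strictly positive")

    @property
    def pixel_size_mm(self) -> float:
        return pixel_size_mm(self.fov_mm, self.n_pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_pixels, self.n_pixels)

    def to_dict(self) -> dict:
        return {
            "fov_mm": self.fov_mm,
            "n_pixels": self.n_pixels,
            "f_stop": self.f_stop,
            "exposure_s": self.exposure_s,
        }


#: "View A" small-binning geometry: 4.0 x 4.0 cm, 480 x 480 px (0.083 mm pitch).
VIEW_A = CameraSpec(fov_mm=40.0, n_pixels=480, f_stop=1.0, exposure_s=300.0)
#: "View D" small-binning geometry: 21.7 x 21.7 cm, 480 x 480 px (0.45 mm pitch).
VIEW_D = CameraSpec(fov_mm=217.0, n_pixels=480, f_stop=1.0, exposure_s=300.0)


def decay_factor(elapsed_min: float, half_life_min: float) -> float:
    """Fraction of activity remaining after ``elapsed_min`` minutes.

    Returns ``2 ** (-elapsed_min / half_life_min)``, in (0, 1].
    """
    if half_life_min <= 0:
        raise ValueError(f"half_life_min must be > 0, got {half_life_min}")
    if elapsed_min < 0:
        raise ValueError(f"elapsed_min must be >= 0, got {elapsed_min}")
    return 2.0 ** (-elapsed_min / half_life_min)


def decay_correct_activity(
    sample: ActivitySample,
    nuclide: RadionuclideSpec,
    *,
    to_reference: bool = False,
) -> float:
    """Decay an activity forward in time, or correct it back to reference.

    With ``to_reference=False`` (default) the reference-time activity is
    decayed *forward* by ``sample.elapsed_min`` — e.g. injected activity to
    scan-time activity.  With ``to_reference=True`` the measured activity is
    corrected *back* to the reference time (the exact inverse).
    """
    factor = decay_factor(sample.elapsed_min, nuclide.half_life_min)
    if to_reference:
        return sample.activity_mbq / factor
    return sample.activity_mbq * factor


def fit_radiance_vs_activity(
    pairs: Iterable[tuple[float, float]],
) -> CalibrationFit:
    """Ordinary least-squares fit of radiance against activity.

    Parameters
    ----------
    pairs
        Iterable of ``(activity_mbq, radiance)`` tuples; at least two points
        with at least two distinct activities.

    Returns
    -------
    CalibrationFit
        Slope (radiance per MBq), intercept (ambient floor) and R^2.

    Notes
    -----
    The intercept is always estimated: a through-origin fit would bias the
    slope when a dark/cosmic floor is present, and on noiseless data the
    intercept is recovered as ~0 anyway.  For data with zero radiance
    variance the fit is the constant line (slope 0) and R^2 is taken as 1.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (activity, radiance) tuples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("all activities and radiances must be finite")
    x, y = arr[:, 0], arr[:, 1]
    if np.any(x < 0):
        raise ValueError("activities must be >= 0")
    if len(np.unique(x)) < 2:
        raise DegenerateFitError(
            "need at least 2 distinct activities to fit a line"
        )
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r_squared = 1.0  # constant response: the constant line is exact
    else:
        r_squared = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        n_points=len(x),
    )


def light_yield_ratio(fit_a, fit_b) -> float:
    """Ratio of two calibration slopes (light yield of a relative to b).

    Accepts :class:`CalibrationFit` objects or bare slopes.
    """
    slope_a = getattr(fit_a, "slope", fit_a)
    slope_b = getattr(fit_b, "slope", fit_b)
    if slope_b <= 0:
        raise ValueError(f"denominator slope must be > 0, got {slope_b}")
    return slope_a / slope_b


def fstop_signal_factor(f_from: float, f_to: float) -> float:
    """Multiplicative signal change when moving the aperture f_from -> f_to.

    Collected signal scales with the inverse square of the f-number, so
    stopping down from f/1 to f/2 costs a factor ``(2/1)**2 = 4``.
    """
    if f_from <= 0 or f_to <= 0:
        raise ValueError("f-numbers must be strictly positive")
    return (f_to / f_from) ** 2


def pixel_size_mm(fov_mm: float, n_pixels: int) -> float:
    """Pixel pitch in mm for a square field of view."""
    if fov_mm <= 0:
        raise ValueError(f"fov_mm must be > 0, got {fov_mm}")
    if n_pixels < 1:
        raise ValueError(f"n_pixels must be >= 1, got {n_pixels}")
    return fov_mm / n_pixels
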