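"""Forward simulation of Cerenkov luminescence scenes with exact ground truth.

The mouse model is deliberately 2-D: the distributed radiotracer produces a
smooth whole-body "backlight" radiance field at the skin surface, and
superficial absorbers (blood vessels, a necrotic tumor core) multiply that
field by a transmission factor < 1.  A vessel of diameter D absorbs in
proportion to the chord length the light crosses, giving the semicircular
transmission profile

    T(u) = 1 - a * sqrt(1 - (2 u / D)^2)   for |u| < D / 2,

where u is the perpendicular distance to the centerline and ``a`` the peak
(center-line) attenuation.  Under this thin-absorber linearization the mean
attenuation over a strip exactly one diameter wide is a * pi / 4, the
closed form used throughout the tests.

The camera model is: optional Gaussian point-spread blur, Poisson shot noise
on photon counts (``photons_per_radiance_unit`` converts the calibrated
radiance to expected counts), an additive dark floor, and rare single-pixel
cosmic-ray spikes.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .biodist import OrganRecord
from .errors import InvalidSceneError
from .image import LuminescenceImage
from .physics import GA68, CameraSpec, RadionuclideSpec, decay_factor
from .quantify import ROI, roi_mean, subtract_background

__all__ = [
    "NoiseSpec",
    "BodyEllipse",
    "VesselSpec",
    "CoreSpec",
    "TumorSpec",
    "SceneSpec",
    "GroundTruth",
    "COHORT_CAMERA",
    "vessel_transmission_map",
    "render_mouse",
    "render_phantom",
    "draw_attenuations",
    "sample_cohort",
    "vessel_measurement_roi",
    "phantom_vial_rois",
    "measure_phantom",
    "phantom_layout",
    "PHANTOM_ACTIVITIES_MBQ",
    "MuscleAnchor",
    "anchor_from_blood",
    "generate_biodistribution_truth",
    "DEFAULT_RELATIVE_ACTIVITY",
    "DEFAULT_LIGHT_TRANSMISSION",
    "DEFAULT_ORGAN_WEIGHTS",
]

#: Attenuation clip bounds used when sampling cohorts (generator convention:
#: keeps drawn attenuations physical).
ATTENUATION_CLIP = (0.005, 0.5)

#: Cosmic-ray spike amplitude, as a multiple of the scene's mean radiance.
COSMIC_AMPLITUDE = 100.0


@dataclass(frozen=True)
class NoiseSpec:
    """Camera noise model.

    photons_per_radiance_unit
        Conversion from radiance (p/s/cm^2/sr) to expected photon counts per
        pixel for the exposure; 0 disables shot noise.  The IVIS vendor
        calibration is not public, so the default is chosen to give ~2000
        counts per pixel on a typical in-vivo backlight (~1e6 p/s/cm^2/sr),
        i.e. ~2% single-pixel shot noise.
    psf_sigma_mm
        Gaussian blur scale.  The realistic default 0.17 mm makes a 40 um
        vessel render ~0.4 mm wide (the ~10x apparent widening seen on
        focused in-vivo scans); 0 disables blur.
    cosmic_rate
        Expected number of single-pixel cosmic-ray spikes per image.
    dark_offset
        Additive instrument floor in radiance units.
    """

    photons_per_radiance_unit: float = 2e-3
    psf_sigma_mm: float = 0.17
    cosmic_rate: float = 5.0
    dark_offset: float = 0.0

    def __post_init__(self) -> None:
        for name in ("photons_per_radiance_unit", "psf_sigma_mm",
                     "cosmic_rate", "dark_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0)

    @classmethod
    def low_noise(cls) -> "NoiseSpec":
        """Shot noise only, light blur: the regime used for cohort scenes."""
        return cls(photons_per_radiance_unit=2e-3, psf_sigma_mm=0.02,
                   cosmic_rate=0.0, dark_offset=0.0)


@dataclass(frozen=True)
class BodyEllipse:
    """Elliptical body support in mm coordinates."""

    center_mm: tuple[float, float]
    semi_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if self.semi_mm[0] <= 0 or self.semi_mm[1] <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class VesselSpec:
    """A straight or polyline vessel segment in mm coordinates.

    ``peak_attenuation`` is the center-line attenuation fraction; the
    strip-averaged (measured-scale) attenuation is peak * pi / 4.
    """

    centerline: tuple[tuple[float, float], ...]
    diameter_mm: float
    peak_attenuation: float
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")
        if not (0.0 <= self.peak_attenuation < 1.0):
            raise InvalidSceneError(
                f"peak_attenuation must be in [0, 1), got {self.peak_attenuation}"
            )

    @property
    def strip_attenuation(self) -> float:
        """Mean attenuation over a one-diameter-wide strip (analytic pi/4 factor)."""
        return self.peak_attenuation * math.pi / 4.0


@dataclass(frozen=True)
class CoreSpec:
    """Necrotic core: a disk with a fractional radiance reduction."""

    center_mm: tuple[float, float]
    radius_mm: float
    reduction: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("core radius must be > 0")
        if not (0.0 <= self.reduction < 1.0):
            raise ValueError("core reduction must be in [0, 1)")


@dataclass(frozen=True)
class TumorSpec:
    """Subcutaneous tumor disk with optional necrotic core."""

    center_mm: tuple[float, float]
    radius_mm: float
    rim_brightness: float = 1.0
    core: CoreSpec | None = None

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("tumor radius must be > 0")
        if self.rim_brightness <= 0:
            raise ValueError("rim_brightness must be > 0")


@dataclass(frozen=True)
class SceneSpec:
    """Complete ground-truth description of one synthetic mouse scene."""

    backlight_mean: float
    backlight_smoothness_mm: float = 3.0
    backlight_rel_sd: float = 0.03
    body: BodyEllipse | None = None  # None: inscribed ellipse, 0.3 mm margin
    vessels: tuple[VesselSpec, ...] = ()
    tumor: TumorSpec | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backlight_mean <= 0:
            raise ValueError("backlight_mean must be > 0")
        if self.backlight_smoothness_mm <= 0:
            raise ValueError("backlight_smoothness_mm must be > 0")
        if self.backlight_rel_sd < 0:
            raise ValueError("backlight_rel_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that an estimator must recover."""

    backlight: np.ndarray          # pre-blur vessel-free radiance field
    clean: np.ndarray              # post-blur noise-free image
    vessel_attenuations: dict = field(default_factory=dict)  # label -> strip avg
    vessel_peaks: dict = field(default_factory=dict)         # label -> peak
    core_reduction: float | None = None
    vial_activities: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(self.clean < -1e-9):
            raise InvalidSceneError("noise-free image must be >= 0 everywhere")


# -- default camera for cohort scenes: view-A pixel pitch on a 16 mm window --
COHORT_CAMERA = CameraSpec(fov_mm=16.0, n_pixels=192, f_stop=1.0, exposure_s=300.0)


def _fine_coords(camera: CameraSpec, oversample: int) -> tuple[np.ndarray, np.ndarray]:
    """Subpixel-center coordinates (x_mm, y_mm) on the oversampled grid."""
    p = camera.pixel_size_mm
    n = camera.n_pixels * oversample
    c = (np.arange(n) + 0.5) * (p / oversample)
    return c, c


def _block_mean(fine: np.ndarray, oversample: int) -> np.ndarray:
    if oversample == 1:
        return fine
    n = fine.shape[0] // oversample
    return fine.reshape(n, oversample, n, oversample).mean(axis=(1, 3))


def _min_distance_to_polyline(
    xs: np.ndarray, ys: np.ndarray, polyline: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Min distance from grid points (xs horizontal, ys vertical) to a polyline."""
    X, Y = np.meshgrid(xs, ys)
    best = np.full(X.shape, np.inf)
    pts = np.asarray(polyline, dtype=float)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        dx, dy = x1 - x0, y1 - y0
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            d = np.hypot(X - x0, Y - y0)
        else:
            t = np.clip(((X - x0) * dx + (Y - y0) * dy) / seg2, 0.0, 1.0)
            d = np.hypot(X - (x0 + t * dx), Y - (y0 + t * dy))
        np.minimum(best, d, out=best)
    return best


def vessel_transmission_map(
    vessel: VesselSpec, camera: CameraSpec, oversample: int = 4
) -> np.ndarray:
    """Multiplicative transmission field of one vessel on the camera grid.

    Each pixel value is the area-average (``oversample`` x ``oversample``
    subpixel midpoint rule) of the semicircular chord profile, so ROI means
    of the rendered field agree with the analytic strip integral.
    """
    xs, ys = _fine_coords(camera, oversample)
    u = _min_distance_to_polyline(xs, ys, vessel.centerline)
    half = vessel.diameter_mm / 2.0
    profile = np.zeros_like(u)
    inside = u < half
    profile[inside] = np.sqrt(1.0 - (u[inside] / half) ** 2)
    fine = 1.0 - vessel.peak_attenuation * profile
    return _block_mean(fine, oversample)


def _disk_coverage(
    center_mm: tuple[float, float],
    radius_mm: float,
    camera: CameraSpec,
    oversample: int = 4,
) -> np.ndarray:
    """Per-pixel area-coverage fraction of a disk (antialiased)."""
    xs, ys = _fine_coords(camera, oversample)
    X, Y = np.meshgrid(xs, ys)
    fine = (np.hypot(X - center_mm[0], Y - center_mm[1]) <= radius_mm).astype(float)
    return _block_mean(fine, oversample)


def _body_coverage(scene: SceneSpec, camera: CameraSpec, oversample: int = 4) -> np.ndarray:
    if scene.body is None:
        half = camera.fov_mm / 2.0
        body = BodyEllipse((half, half), (half - 0.3, half - 0.3))
    else:
        body = scene.body
    xs, ys = _fine_coords(camera, oversample)
    X, Y = np.meshgrid(xs, ys)
    (cx, cy), (a, b) = body.center_mm, body.semi_mm
    fine = ((((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2) <= 1.0).astype(float)
    cov = _block_mean(fine, oversample)
    if not cov.any():
        raise InvalidSceneError("body mask is empty within the field of view")
    return cov


def _backlight_field(
    scene: SceneSpec, camera: CameraSpec, rng: np.random.Generator
) -> np.ndarray:
    """Smooth band-limited backlight: mean x (1 + rel_sd * unit-sd GRF)."""
    shape = camera.shape
    field_ = np.full(shape, scene.backlight_mean, dtype=float)
    if scene.backlight_rel_sd > 0:
        sigma_px = scene.backlight_smoothness_mm / camera.pixel_size_mm
        white = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(white, sigma=sigma_px, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
        field_ *= np.clip(1.0 + scene.backlight_rel_sd * smooth, 0.0, None)
    return field_


def _apply_camera_noise(
    clean: np.ndarray,
    noise: NoiseSpec,
    camera: CameraSpec,
    rng: np.random.Generator,
    mean_radiance: float,
) -> np.ndarray:
    img = clean
    ppru = noise.photons_per_radiance_unit
    if ppru > 0:
        img = rng.poisson(np.clip(img, 0.0, None) * ppru).astype(float) / ppru
    else:
        img = img.copy()
    img += noise.dark_offset
    if noise.cosmic_rate > 0:
        n_spikes = rng.poisson(noise.cosmic_rate)
        if n_spikes:
            ii = rng.integers(0, camera.n_pixels, size=n_spikes)
            jj = rng.integers(0, camera.n_pixels, size=n_spikes)
            img[ii, jj] += COSMIC_AMPLITUDE * mean_radiance
    return img


def render_mouse(
    scene: SceneSpec, camera: CameraSpec = COHORT_CAMERA, oversample: int = 4
) -> tuple[LuminescenceImage, GroundTruth]:
    """Render one mouse scene; deterministic given ``scene.seed``.

    Pipeline: backlight x vessel transmissions x tumor factor, Gaussian PSF,
    Poisson shot noise, dark offset, cosmic spikes.
    """
    rng = np.random.default_rng(scene.seed)
    cov = _body_coverage(scene, camera, oversample)
    backlight = _backlight_field(scene, camera, rng) * cov
    field_ = backlight.copy()
    truth = GroundTruth(backlight=backlight, clean=backlight, seed=scene.seed)
    for idx, vessel in enumerate(scene.vessels):
        field_ *= vessel_transmission_map(vessel, camera, oversample)
        label = vessel.label or f"vessel_{idx}"
        truth.vessel_attenuations[label] = vessel.strip_attenuation
        truth.vessel_peaks[label] = vessel.peak_attenuation
    if scene.tumor is not None:
        t = scene.tumor
        tumor_cov = _disk_coverage(t.center_mm, t.radius_mm, camera, oversample)
        field_ *= 1.0 + (t.rim_brightness - 1.0) * tumor_cov
        if t.core is not None:
            core_cov = _disk_coverage(t.core.center_mm, t.core.radius_mm,
                                      camera, oversample)
            field_ *= 1.0 - t.core.reduction * core_cov
            truth.core_reduction = t.core.reduction
    if scene.noise.psf_sigma_mm > 0:
        field_ = ndimage.gaussian_filter(
            field_, sigma=scene.noise.psf_sigma_mm / camera.pixel_size_mm,
            mode="reflect",
        )
    truth.clean = field_
    img = _apply_camera_noise(field_, scene.noise, camera, rng,
                              mean_radiance=scene.backlight_mean)
    return (
        LuminescenceImage(img, camera, meta={"seed": scene.seed}),
        truth,
    )


def render_phantom(
    vials: Sequence[tuple[tuple[float, float], float]],
    nuclide: RadionuclideSpec = GA68,
    noise: NoiseSpec | None = None,
    camera: CameraSpec = CameraSpec(fov_mm=120.0, n_pixels=240),
    seed: int = 0,
    vial_radius_mm: float = 3.0,
    oversample: int = 4,
) -> tuple[LuminescenceImage, GroundTruth]:
    """Render a well-plate phantom: one disk per vial.

    Each vial's disk radiance is ``nuclide.light_yield * activity_mbq``;
    noise is applied exactly as in :func:`render_mouse`.
    """
    if noise is None:
        noise = NoiseSpec.noiseless()
    positions = [np.asarray(p, dtype=float) for p, _ in vials]
    activities = [a for _, a in vials]
    if any(a < 0 for a in activities):
        raise ValueError("vial activities must be >= 0")
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if np.hypot(*(positions[i] - positions[j])) < 2 * vial_radius_mm:
                raise InvalidSceneError(
                    f"vial footprints {i} and {j} overlap"
                )
    rng = np.random.default_rng(seed)
    field_ = np.zeros(camera.shape, dtype=float)
    for pos, act in vials:
        field_ += nuclide.light_yield * act * _disk_coverage(
            tuple(pos), vial_radius_mm, camera, oversample
        )
    if noise.psf_sigma_mm > 0:
        field_ = ndimage.gaussian_filter(
            field_, sigma=noise.psf_sigma_mm / camera.pixel_size_mm, mode="reflect"
        )
    max_radiance = nuclide.light_yield * max(activities) if activities else 0.0
    img = _apply_camera_noise(field_, noise, camera, rng,
                              mean_radiance=max(max_radiance, 1.0))
    truth = GroundTruth(
        backlight=np.zeros(camera.shape), clean=field_,
        vial_activities=tuple(activities), seed=seed,
    )
    return LuminescenceImage(img, camera, meta={"seed": seed}), truth


def draw_attenuations(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    n: int,
    bounds: tuple[float, float] = ATTENUATION_CLIP,
) -> np.ndarray:
    """Draw n true attenuation fractions from a clipped normal."""
    if not (0.0 < mean < 1.0):
        raise ValueError(f"mean attenuation must be in (0, 1), got {mean}")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return np.clip(rng.normal(mean, sd, size=n), bounds[0], bounds[1])


def sample_cohort(
    n_mice: int,
    tumor_attenuation: tuple[float, float] = (0.10, 0.04),
    nontumor_attenuation: tuple[float, float] = (0.03, 0.01),
    seed: int = 0,
    camera: CameraSpec = COHORT_CAMERA,
    backlight_mean: float = 1.0e6,
    noise: NoiseSpec | None = None,
) -> list[SceneSpec]:
    """Generate one scene per mouse with a tumor-side and a non-tumor vessel.

    The drawn values are the *measured-scale* (strip-averaged) attenuations
    the study reports — tumor-side vessels N(10%, 4%), contralateral vessels
    N(3%, 1%) by default — clipped to (0.5%, 50%); the renderer's center-line
    peak is drawn * 4 / pi.  Vessels are vertical, at fixed fractions of the
    field of view, with an image-plane diameter of 6 pixels.  Per-scene seeds
    are master seed + scene index.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    for name, (m, s) in (("tumor", tumor_attenuation),
                         ("nontumor", nontumor_attenuation)):
        if not (0.0 < m < 1.0) or s < 0:
            raise ValueError(f"invalid {name} attenuation distribution ({m}, {s})")
    if noise is None:
        noise = NoiseSpec.low_noise()
    rng = np.random.default_rng(seed)
    tumor_true = draw_attenuations(rng, *tumor_attenuation, n=n_mice)
    nontumor_true = draw_attenuations(rng, *nontumor_attenuation, n=n_mice)
    fov = camera.fov_mm
    diameter = 6 * camera.pixel_size_mm
    y0, y1 = 0.125 * fov, 0.875 * fov
    scenes = []
    for i in range(n_mice):
        vessels = (
            VesselSpec(
                centerline=((0.3125 * fov, y0), (0.3125 * fov, y1)),
                diameter_mm=diameter,
                peak_attenuation=float(tumor_true[i]) * 4.0 / math.pi,
                label="tumor-side",
            ),
            VesselSpec(
                centerline=((0.6875 * fov, y0), (0.6875 * fov, y1)),
                diameter_mm=diameter,
                peak_attenuation=float(nontumor_true[i]) * 4.0 / math.pi,
                label="non-tumor-side",
            ),
        )
        scenes.append(SceneSpec(
            backlight_mean=backlight_mean,
            vessels=vessels,
            noise=noise,
            seed=seed + i,
        ))
    return scenes


def vessel_measurement_roi(
    vessel: VesselSpec,
    camera: CameraSpec,
    length_mm: float = 5.0,
) -> ROI:
    """Measurement ROI spanning an axis-aligned vessel's width.

    The ROI is one rendered diameter wide, ``length_mm`` long, centered on
    the centerline.  Only vertical or horizontal straight vessels are
    supported (automatic centerline tracing is out of scope; ROI placement
    comes from ground truth or the user).
    """
    (x0, y0), (x1, y1) = vessel.centerline[0], vessel.centerline[-1]
    p = camera.pixel_size_mm
    w = max(1, round(vessel.diameter_mm / p))
    if math.isclose(x0, x1):  # vertical
        cx = x0 / p
        cy = (y0 + y1) / 2.0 / p
        h = max(1, round(length_mm / p))
        return ROI(x=round(cx - w / 2), y=round(cy - h / 2),
                   width=w, height=h, label=vessel.label)
    if math.isclose(y0, y1):  # horizontal
        cy = y0 / p
        cx = (x0 + x1) / 2.0 / p
        h = max(1, round(length_mm / p))
        return ROI(x=round(cx - h / 2), y=round(cy - w / 2),
                   width=h, height=w, label=vessel.label)
    raise ValueError("vessel_measurement_roi supports axis-aligned vessels only")


#: Calibration ladder spanning the phantom's 0 to 0.61 MBq activity range.
PHANTOM_ACTIVITIES_MBQ: tuple[float, ...] = tuple(
    float(a) for a in np.linspace(0.0, 0.61, 8)
)


def phantom_layout(
    activities: Sequence[float] = PHANTOM_ACTIVITIES_MBQ,
    camera: CameraSpec = CameraSpec(fov_mm=120.0, n_pixels=240),
    vial_radius_mm: float = 3.0,
) -> list[tuple[tuple[float, float], float]]:
    """Arrange vials on a well-plate grid with non-overlapping footprints."""
    n = len(activities)
    n_cols = math.ceil(math.sqrt(n))
    n_rows = math.ceil(n / n_cols)
    fov = camera.fov_mm
    # keep vials away from the corner background ROI and the image edge
    xs = np.linspace(0.25 * fov, 0.85 * fov, n_cols)
    ys = np.linspace(0.35 * fov, 0.80 * fov, n_rows)
    spacing = min(np.diff(xs).min() if n_cols > 1 else fov,
                  np.diff(ys).min() if n_rows > 1 else fov)
    if spacing < 2 * vial_radius_mm:
        raise InvalidSceneError("too many vials for the field of view")
    vials = []
    for i, act in enumerate(activities):
        r, c = divmod(i, n_cols)
        vials.append(((float(xs[c]), float(ys[r])), float(act)))
    return vials


def phantom_vial_rois(
    vials: Sequence[tuple[tuple[float, float], float]],
    camera: CameraSpec,
    half_width_px: int = 4,
) -> list[ROI]:
    """Square ROIs centered on each vial, small enough to sit inside the disk."""
    p = camera.pixel_size_mm
    rois = []
    for idx, ((x_mm, y_mm), _act) in enumerate(vials):
        cx, cy = x_mm / p, y_mm / p
        rois.append(ROI(
            x=round(cx - half_width_px), y=round(cy - half_width_px),
            width=2 * half_width_px, height=2 * half_width_px,
            label=f"vial_{idx}",
        ))
    return rois


def measure_phantom(
    image: LuminescenceImage,
    vials: Sequence[tuple[tuple[float, float], float]],
    background_roi: ROI | None = None,
    half_width_px: int = 4,
) -> list[tuple[float, float]]:
    """(activity, ROI-mean radiance) pairs for each vial, background-subtracted.

    The default background ROI is a 20x20 px patch at the image corner,
    outside every vial footprint.
    """
    cam = image.camera
    if background_roi is None:
        background_roi = ROI(x=2, y=2, width=20, height=20, label="background")
    corrected = subtract_background(image, background_roi)
    pairs = []
    for roi, (_pos, activity) in zip(phantom_vial_rois(vials, cam, half_width_px),
                                     vials):
        pairs.append((activity, roi_mean(corrected, roi)))
    return pairs


# ---------------------------------------------------------------------------
# Biodistribution truth generator
# ---------------------------------------------------------------------------

#: Whole-organ gamma counts relative to the thigh-muscle sample.  Blood is
#: paper-constrained (6.2x muscle); remaining organs reconstruct the
#: reported ordering (blood > liver, spleen > kidneys/lungs/heart; low
#: intestines/tumor; negligible brain).
DEFAULT_RELATIVE_ACTIVITY: dict[str, float] = {
    "blood": 6.2, "liver": 4.8, "spleen": 4.2, "lungs": 2.6, "kidneys": 2.4,
    "heart": 1.9, "femur": 1.4, "tumor": 1.3, "intestines": 1.1,
    "muscle": 1.0, "brain": 0.2,
}

#: Optical transmission of each excised organ (flux per gamma count relative
#: to muscle).  Blood is paper-constrained: 0.32 / 6.2, i.e. a
#: light-to-activity ratio ~0.05 of muscle (~20x lower).  Intestines, tumor,
#: brain, muscle and femur transmit like muscle; heart, lungs, spleen, liver
#: and kidneys are partially blood-filled and sit in between.
DEFAULT_LIGHT_TRANSMISSION: dict[str, float] = {
    "blood": 0.32 / 6.2, "liver": 0.50, "spleen": 0.45, "lungs": 0.50,
    "kidneys": 0.60, "heart": 0.55, "femur": 0.95, "tumor": 1.0,
    "intestines": 1.0, "muscle": 1.0, "brain": 1.0,
}

#: Typical excised organ/sample weights in grams for an adult nude mouse.
DEFAULT_ORGAN_WEIGHTS: dict[str, float] = {
    "blood": 1.0, "liver": 1.3, "spleen": 0.10, "lungs": 0.20,
    "kidneys": 0.40, "heart": 0.15, "femur": 0.30, "tumor": 0.50,
    "intestines": 2.5, "muscle": 0.30, "brain": 0.40,
}


@dataclass(frozen=True)
class MuscleAnchor:
    """Absolute scale of the generated table.

    ``counts``: gamma counts of the muscle sample at the measurement time;
    ``flux_per_count``: IVIS flux (photons/s) per gamma count for a fully
    transmitting organ.
    """

    counts: float
    flux_per_count: float = 5.0

    def __post_init__(self) -> None:
        if self.counts <= 0 or self.flux_per_count <= 0:
            raise ValueError("anchor counts and flux_per_count must be > 0")


def anchor_from_blood(
    pct_id_per_g: float = 15.0,
    injected_mbq: float = 10.0,
    counts_per_mbq: float = 5.0e5,
    nuclide: RadionuclideSpec = GA68,
    elapsed_min: float = 65.0,
    blood_weight_g: float = DEFAULT_ORGAN_WEIGHTS["blood"],
    blood_rel_activity: float = DEFAULT_RELATIVE_ACTIVITY["blood"],
    flux_per_count: float = 5.0,
) -> MuscleAnchor:
    """Anchor the table so blood comes out at a target %ID/g.

    Default reproduces blood at 15 %ID/g measured 65 min post injection.
    """
    a0_blood = pct_id_per_g / 100.0 * injected_mbq * blood_weight_g
    blood_counts = a0_blood * decay_factor(elapsed_min, nuclide.half_life_min) \
        * counts_per_mbq
    return MuscleAnchor(counts=blood_counts / blood_rel_activity,
                        flux_per_count=flux_per_count)


def generate_biodistribution_truth(
    organ_relative_activity: Mapping[str, float] | None = None,
    organ_light_transmission: Mapping[str, float] | None = None,
    muscle_anchor: MuscleAnchor | None = None,
    seed: int = 0,
    noise_sd: float = 0.05,
    elapsed_min: float = 65.0,
    organ_weights: Mapping[str, float] | None = None,
) -> list[OrganRecord]:
    """Generate a per-organ gamma-count / optical-flux table with known truth.

    counts = anchor.counts x relative activity x lognormal(sd);
    flux = true counts x transmission x anchor.flux_per_count x lognormal(sd).
    Lognormal factors are unit-mean; ``noise_sd=0`` gives exact ratios.
    """
    rel_act = dict(organ_relative_activity or DEFAULT_RELATIVE_ACTIVITY)
    trans = dict(organ_light_transmission or DEFAULT_LIGHT_TRANSMISSION)
    weights = dict(organ_weights or DEFAULT_ORGAN_WEIGHTS)
    if "muscle" not in rel_act:
        raise ValueError("the relative-activity table must contain a muscle row")
    if not math.isclose(rel_act["muscle"], 1.0):
        raise ValueError("muscle relative activity must be 1 (it is the reference)")
    if any(v <= 0 for v in rel_act.values()):
        raise ValueError("all relative activities must be > 0")
    missing = set(rel_act) - set(trans)
    if missing:
        raise ValueError(f"transmission table missing organs: {sorted(missing)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    anchor = muscle_anchor or anchor_from_blood(elapsed_min=elapsed_min)
    rng = np.random.default_rng(seed)

    def _noise() -> float:
        if noise_sd == 0:
            return 1.0
        return float(rng.lognormal(mean=-noise_sd ** 2 / 2.0, sigma=noise_sd))

    records = []
    for organ, ra in rel_act.items():
        true_counts = anchor.counts * ra
        records.append(OrganRecord(
            organ=organ,
            weight_g=float(weights.get(organ, 0.3)),
            counts=true_counts * _noise(),
            flux_ps=true_counts * trans[organ] * anchor.flux_per_count * _noise(),
            elapsed_min=elapsed_min,
        ))
    return records
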