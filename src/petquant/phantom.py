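"""Synthetic NEMA-style sphere phantoms and patient lesion cohorts.

The phantom generator emulates a body phantom with fillable hot spheres of
known volume on a warm background: spheres are voxelized analytically
(voxel-center-in-sphere), the volume is blurred with an isotropic Gaussian
standing in for the scanner point-spread function, and Gaussian noise
proportional to the background concentration is added.  Ground truth is the
unblurred voxelized sphere set, so threshold calibration can be scored
against known volumes.

The cohort generator emulates a lung-cancer staging population: one
sphere-like focal lesion per patient with log-normally distributed true
SUVmax (mean 9.9, SD 4.7) and volume (mean 20 cm³), injected activity
364 ± 75 MBq, 50–70 min uptake time, and per-patient demographics.  Three
simulated software variants (see :mod:`petquant.variants`) later read out
each volume with slightly different conventions.

All randomness is a pure function of (spec, seed); per-patient substreams are
spawned deterministically from the cohort seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy import ndimage

from .delineation import SegmentationMask
from .errors import GeometryError, InvalidArgumentError
from .image import VolumetricImage, box_region
from .suv import SubjectInfo
from .variants import DEFAULT_VARIANTS, VariantConvention

__all__ = [
    "NEMA_SPHERE_DIAMETERS_MM",
    "PhantomSpec",
    "CohortSpec",
    "LesionTruth",
    "PatientRecord",
    "Cohort",
    "sphere_volume",
    "sphere_diameter_for_volume",
    "lognormal_params",
    "generate_nema_phantom",
    "generate_patient_cohort",
]

#: Hot-sphere inner diameters of the IEC body phantom used for calibration
#: (the 10 mm sphere of the full set is omitted by default but supported).
NEMA_SPHERE_DIAMETERS_MM: tuple[float, ...] = (13.0, 17.0, 22.0, 28.0, 37.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def sphere_volume(diameter_mm: float) -> float:
    """Volume in cm³ of a sphere of the given diameter in mm: (π/6)·d³."""
    if diameter_mm <= 0:
        raise InvalidArgumentError(f"diameter must be positive, got {diameter_mm}")
    d_cm = diameter_mm / 10.0
    return math.pi / 6.0 * d_cm**3


def sphere_diameter_for_volume(volume_cm3: float) -> float:
    """Inverse of :func:`sphere_volume`: diameter in mm for a volume in cm³."""
    if volume_cm3 <= 0:
        raise InvalidArgumentError(f"volume must be positive, got {volume_cm3}")
    return 10.0 * (6.0 * volume_cm3 / math.pi) ** (1.0 / 3.0)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise InvalidArgumentError("mean and sd must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _default_ring_centers(diameters, grid_shape, spacing_mm,
                          ring_radius_mm: float = 57.2) -> tuple[tuple[float, float, float], ...]:
    """Sphere centers on a transaxial ring in the central slice (the layout
    of the physical phantom's sphere insert)."""
    center = tuple((n - 1) * s / 2.0 for n, s in zip(grid_shape, spacing_mm))
    angles = np.linspace(0.0, 2.0 * math.pi, num=len(diameters), endpoint=False)
    return tuple(
        (center[0],
         center[1] + ring_radius_mm * math.cos(a),
         center[2] + ring_radius_mm * math.sin(a))
        for a in angles
    )


@dataclass
class PhantomSpec:
    """Geometry, activity and degradation parameters of a sphere phantom.

    Default sphere:background contrast is 8:1 (a standard hot-sphere fill of
    the image-quality phantom).  ``psf_fwhm_mm`` models the *effective*
    resolution of the reconstructed image — intrinsic scanner PSF plus
    reconstruction smoothing — not the detector resolution alone; the 11 mm
    default is what reproduces the published size-dependence of optimal
    %-of-max thresholds for whole-body FDG protocols of this scanner class.
    """

    sphere_diameters_mm: tuple[float, ...] = NEMA_SPHERE_DIAMETERS_MM
    sphere_centers_mm: tuple[tuple[float, float, float], ...] | None = None
    sphere_concentration: float = 40000.0     # Bq/mL
    background_concentration: float = 5000.0  # Bq/mL
    psf_fwhm_mm: float = 11.0
    noise_sd_fraction: float = 0.0
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    grid_shape: tuple[int, int, int] = (40, 96, 96)
    seed: int = 0

    def __post_init__(self) -> None:
        self.sphere_diameters_mm = tuple(float(d) for d in self.sphere_diameters_mm)
        if any(d <= 0 for d in self.sphere_diameters_mm):
            raise InvalidArgumentError("sphere diameters must be positive")
        if self.sphere_centers_mm is None:
            self.sphere_centers_mm = _default_ring_centers(
                self.sphere_diameters_mm, self.grid_shape, self.voxel_spacing_mm)
        self.sphere_centers_mm = tuple(tuple(float(c) for c in ctr)
                                       for ctr in self.sphere_centers_mm)
        if len(self.sphere_centers_mm) != len(self.sphere_diameters_mm):
            raise InvalidArgumentError("need one center per sphere")
        if not self.sphere_concentration > self.background_concentration >= 0:
            raise InvalidArgumentError(
                "require sphere_concentration > background_concentration >= 0")
        if self.psf_fwhm_mm < 0 or self.noise_sd_fraction < 0:
            raise InvalidArgumentError("PSF FWHM and noise fraction must be nonnegative")
        if any(s <= 0 for s in self.voxel_spacing_mm) or any(n <= 0 for n in self.grid_shape):
            raise InvalidArgumentError("spacing and grid shape must be positive")
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        extent = tuple((n - 1) * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm))
        radii = [d / 2.0 for d in self.sphere_diameters_mm]
        for ctr, r in zip(self.sphere_centers_mm, radii):
            for c, e in zip(ctr, extent):
                if c - r < 0 or c + r > e:
                    raise GeometryError(
                        f"sphere of radius {r} mm at {ctr} exceeds the grid extent {extent}")
        for i in range(len(radii)):
            for j in range(i + 1, len(radii)):
                dist = math.dist(self.sphere_centers_mm[i], self.sphere_centers_mm[j])
                if dist < radii[i] + radii[j]:
                    raise GeometryError(f"spheres {i} and {j} overlap (centers {dist:.1f} mm apart)")

    def sphere_volumes_cm3(self) -> tuple[float, ...]:
        return tuple(sphere_volume(d) for d in self.sphere_diameters_mm)

    def search_region(self, sphere_index: int, margin_mm: float = 10.0):
        """Box of slices around one sphere, wide enough to hold the blurred
        object plus ``margin_mm``, yet clear of the neighbouring spheres."""
        ctr = self.sphere_centers_mm[sphere_index]
        r = self.sphere_diameters_mm[sphere_index] / 2.0 + margin_mm + 1.5 * self.psf_fwhm_mm
        center_idx = tuple(int(round(c / s)) for c, s in zip(ctr, self.voxel_spacing_mm))
        half = tuple(int(math.ceil(r / s)) for s in self.voxel_spacing_mm)
        return box_region(center_idx, half, self.grid_shape)


def _sphere_mask(image: VolumetricImage, center_mm, radius_mm: float) -> np.ndarray:
    zz, yy, xx = image.voxel_centers_mm()
    return ((zz - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2
            + (xx - center_mm[2]) ** 2) <= radius_mm**2


def _degrade(data: np.ndarray, spacing_mm, psf_fwhm_mm: float,
             noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian PSF blur, additive Gaussian noise, clamp at zero."""
    if psf_fwhm_mm > 0:
        sigma_vox = [psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in spacing_mm]
        data = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="nearest")
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return np.maximum(data, 0.0)


def generate_nema_phantom(spec: PhantomSpec) -> tuple[VolumetricImage, list[SegmentationMask]]:
    """Simulate one phantom acquisition.

    Returns the degraded activity-concentration volume and, per sphere, the
    ground-truth mask of the unblurred voxelized sphere.
    """
    image = VolumetricImage(
        np.full(spec.grid_shape, float(spec.background_concentration)),
        spec.voxel_spacing_mm)
    truth: list[SegmentationMask] = []
    for ctr, d in zip(spec.sphere_centers_mm, spec.sphere_diameters_mm):
        mask = _sphere_mask(image, ctr, d / 2.0)
        image.data[mask] = spec.sphere_concentration
        truth.append(SegmentationMask(mask, image.voxel_volume_cm3))
    rng = np.random.default_rng(spec.seed)
    noise_sd = spec.noise_sd_fraction * spec.background_concentration
    image.data = _degrade(image.data, spec.voxel_spacing_mm, spec.psf_fwhm_mm, noise_sd, rng)
    return image, truth


# ---------------------------------------------------------------------------
# Patient cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Distributional description of a simulated staging cohort.

    True lesion SUVmax and volume are log-normal with the stated arithmetic
    mean/SD; injected activity is normal truncated at zero; uptake time is
    uniform on the stated interval.  Sex-specific weight/height normals give
    plausible adult demographics.
    """

    n_patients: int = 98
    lesion_suvmax_mean_sd: tuple[float, float] = (9.9, 4.7)
    lesion_volume_mean_sd_cm3: tuple[float, float] = (20.0, 15.0)
    injected_activity_mean_sd_MBq: tuple[float, float] = (364.0, 75.0)
    female_fraction: float = 42.0 / 98.0
    weight_mean_sd_kg: dict = field(default_factory=lambda: {
        "male": (80.0, 12.0), "female": (68.0, 12.0)})
    height_mean_sd_cm: dict = field(default_factory=lambda: {
        "male": (176.0, 7.0), "female": (163.0, 6.0)})
    uptake_time_range_min: tuple[float, float] = (50.0, 70.0)
    background_suv: float = 1.0
    psf_fwhm_mm: float = 11.0
    noise_sd_fraction: float = 0.05
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    max_lesion_volume_cm3: float = 80.0
    min_lesion_volume_cm3: float = 0.8
    variants: tuple[VariantConvention, ...] = DEFAULT_VARIANTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise InvalidArgumentError("n_patients must be nonnegative")
        for pair in (self.lesion_suvmax_mean_sd, self.lesion_volume_mean_sd_cm3,
                     self.injected_activity_mean_sd_MBq):
            if pair[0] <= 0 or pair[1] <= 0:
                raise InvalidArgumentError("distribution mean/SD must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise InvalidArgumentError("female_fraction must be in [0, 1]")
        lo, hi = self.uptake_time_range_min
        if not 50.0 <= lo <= hi <= 70.0:
            raise InvalidArgumentError("uptake interval must lie within [50, 70] min")
        if self.min_lesion_volume_cm3 <= 0 or self.max_lesion_volume_cm3 <= self.min_lesion_volume_cm3:
            raise InvalidArgumentError("lesion volume bounds must be positive and ordered")


@dataclass(frozen=True)
class LesionTruth:
    """Ground truth of one simulated lesion, before blur and noise."""

    suv_max: float
    volume_cm3: float
    diameter_mm: float
    center_mm: tuple[float, float, float]
    peak_bq_per_ml: float
    background_bq_per_ml: float


@dataclass
class PatientRecord:
    """One simulated patient: volume, demographics, lesion ground truth."""

    patient_id: str
    image: VolumetricImage
    subject: SubjectInfo
    truth: LesionTruth
    truth_mask: SegmentationMask


@dataclass
class Cohort:
    records: list[PatientRecord]
    variants: tuple[VariantConvention, ...]

    def __len__(self) -> int:
        return len(self.records)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float = math.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise InvalidArgumentError(
        f"truncated normal ({mean}, {sd}) on ({lo}, {hi}) failed to draw")


def generate_patient_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort of single-lesion patient volumes.

    Each patient's lesion is a voxelized sphere of the drawn true volume with
    plateau concentration matching the drawn true SUVmax (given that
    patient's decayed activity and body weight), on a uniform background of
    ``background_suv``, degraded by PSF blur and noise like the phantom.
    """
    base = datetime(2021, 1, 1, 9, 0, 0)
    streams = np.random.SeedSequence(spec.seed).spawn(max(spec.n_patients, 1))
    mu_s, sig_s = lognormal_params(*spec.lesion_suvmax_mean_sd)
    mu_v, sig_v = lognormal_params(*spec.lesion_volume_mean_sd_cm3)
    grid_center = tuple((n - 1) * s / 2.0
                        for n, s in zip(spec.grid_shape, spec.voxel_spacing_mm))

    records: list[PatientRecord] = []
    for p in range(spec.n_patients):
        rng = np.random.default_rng(streams[p])
        sex = "female" if rng.random() < spec.female_fraction else "male"
        weight = _truncated_normal(rng, *spec.weight_mean_sd_kg[sex], lo=40.0, hi=160.0)
        height = _truncated_normal(rng, *spec.height_mean_sd_cm[sex], lo=140.0, hi=210.0)
        activity = _truncated_normal(rng, *spec.injected_activity_mean_sd_MBq, lo=0.0)
        uptake = float(rng.uniform(*spec.uptake_time_range_min))
        injection = base + timedelta(minutes=float(p))
        subject = SubjectInfo(
            sex=sex, body_weight_kg=weight, height_cm=height,
            injected_activity_MBq=activity, injection_time=injection,
            scan_time=injection + timedelta(minutes=uptake))

        suv_true = float(np.exp(rng.normal(mu_s, sig_s)))
        vol_true = float(np.clip(np.exp(rng.normal(mu_v, sig_v)),
                                 spec.min_lesion_volume_cm3, spec.max_lesion_volume_cm3))
        diam = sphere_diameter_for_volume(vol_true)
        center = tuple(c + float(rng.uniform(-3.0, 3.0)) for c in grid_center)

        decayed = subject.decayed_activity_MBq
        # SUV (g/mL) = C[kBq/mL] / (A[MBq]/BW[kg])  =>  C[Bq/mL] = 1000*SUV*A/BW
        peak = 1000.0 * suv_true * decayed / weight
        background = 1000.0 * spec.background_suv * decayed / weight

        image = VolumetricImage(np.full(spec.grid_shape, background),
                                spec.voxel_spacing_mm)
        lesion = _sphere_mask(image, center, diam / 2.0)
        image.data[lesion] = peak
        image.data = _degrade(image.data, spec.voxel_spacing_mm, spec.psf_fwhm_mm,
                              spec.noise_sd_fraction * background, rng)

        truth = LesionTruth(suv_max=suv_true, volume_cm3=vol_true, diameter_mm=diam,
                            center_mm=center, peak_bq_per_ml=peak,
                            background_bq_per_ml=background)
        records.append(PatientRecord(
            patient_id=f"P{p:04d}", image=image, subject=subject, truth=truth,
            truth_mask=SegmentationMask(lesion, image.voxel_volume_cm3)))
    return Cohort(records=records, variants=spec.variants)
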