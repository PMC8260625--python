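"""Standardized uptake value arithmetic.

SUV normalizes a measured tissue activity concentration by the injected
activity per unit body mass:

    SUV = C [kBq/mL] / (A [MBq] / m [kg])  =  C * m / A

which is the dimensionless g/mL convention.  The mass ``m`` is either total
body weight (BW) or lean body mass (LBM); LBM is the sex-specific
height/weight formula used throughout clinical PET (James formula):

    men:   LBM = 1.10 * BW - 128 * BW^2 / height^2
    women: LBM = 1.07 * BW - 148 * BW^2 / height^2

with BW in kg and height in cm.  The administered activity is decay-corrected
from injection time to scan start; the raw Bq/mL readout bypasses
normalization entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

from .errors import InvalidArgumentError

__all__ = [
    "F18_HALF_LIFE_MIN",
    "SubjectInfo",
    "SuvTriple",
    "compute_lbm",
    "decay_correct_activity",
    "suv_bw",
    "suv_lbm",
]

#: Fluorine-18 physical half-life in minutes.
F18_HALF_LIFE_MIN = 109.771


@dataclass(frozen=True)
class SubjectInfo:
    """Demographic and dosing data driving SUV normalization."""

    sex: str                      # "male" | "female"
    body_weight_kg: float
    height_cm: float
    injected_activity_MBq: float  # administered activity at injection time
    injection_time: datetime
    scan_time: datetime
    radionuclide_half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InvalidArgumentError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.body_weight_kg <= 0:
            raise InvalidArgumentError("body_weight_kg must be positive")
        if self.height_cm <= 0:
            raise InvalidArgumentError("height_cm must be positive")
        if self.injected_activity_MBq <= 0:
            raise InvalidArgumentError("injected_activity_MBq must be positive")
        if self.radionuclide_half_life_min <= 0:
            raise InvalidArgumentError("half-life must be positive")
        if self.scan_time < self.injection_time:
            raise InvalidArgumentError("scan_time must not precede injection_time")

    @property
    def uptake_min(self) -> float:
        """Minutes elapsed between injection and scan start."""
        return (self.scan_time - self.injection_time).total_seconds() / 60.0

    @property
    def lean_body_mass_kg(self) -> float:
        return compute_lbm(self.sex, self.body_weight_kg, self.height_cm)

    @property
    def decayed_activity_MBq(self) -> float:
        """Administered activity decay-corrected to scan start."""
        return decay_correct_activity(
            self.injected_activity_MBq, self.uptake_min, self.radionuclide_half_life_min)


@dataclass(frozen=True)
class SuvTriple:
    """One uptake statistic expressed in the three unit systems.

    ``suv_lbm`` is ``None`` when the measuring variant does not support
    LBM normalization; ``raw_bq_per_ml`` carries no subject normalization.
    """

    suv_bw: float
    raw_bq_per_ml: float
    suv_lbm: float | None = None

    def __post_init__(self) -> None:
        if self.suv_bw < 0 or self.raw_bq_per_ml < 0:
            raise InvalidArgumentError("SUV values must be nonnegative")
        if self.suv_lbm is not None and self.suv_lbm < 0:
            raise InvalidArgumentError("SUV values must be nonnegative")


def compute_lbm(sex: str, body_weight_kg: float, height_cm: float) -> float:
    """Lean body mass in kg from sex, weight (kg) and height (cm)."""
    if body_weight_kg <= 0 or height_cm <= 0:
        raise InvalidArgumentError("weight and height must be positive")
    bw, h = float(body_weight_kg), float(height_cm)
    if sex == "male":
        lbm = 1.10 * bw - 128.0 * bw * bw / (h * h)
    elif sex == "female":
        lbm = 1.07 * bw - 148.0 * bw * bw / (h * h)
    else:
        raise InvalidArgumentError(f"sex must be 'male' or 'female', got {sex!r}")
    if lbm <= 0:
        raise InvalidArgumentError(
            f"computed LBM {lbm:.2f} kg is non-positive for BW={bw} kg, height={h} cm")
    return lbm


def decay_correct_activity(activity_MBq: float, elapsed_min: float,
                           half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Activity remaining after ``elapsed_min`` of exponential decay."""
    if activity_MBq <= 0:
        raise InvalidArgumentError("activity must be positive")
    if elapsed_min < 0:
        raise InvalidArgumentError("elapsed time must be nonnegative")
    if half_life_min <= 0:
        raise InvalidArgumentError("half-life must be positive")
    return float(activity_MBq) * 2.0 ** (-float(elapsed_min) / float(half_life_min))


def suv_bw(concentration_kBq_per_mL: float, decayed_activity_MBq: float,
           body_weight_kg: float) -> float:
    """Body-weight SUV: ``C * BW / A`` with C in kBq/mL, A in MBq, BW in kg."""
    if decayed_activity_MBq <= 0:
        raise InvalidArgumentError("activity must be positive")
    if body_weight_kg <= 0:
        raise InvalidArgumentError("body weight must be positive")
    if concentration_kBq_per_mL < 0:
        raise InvalidArgumentError("concentration must be nonnegative")
    return float(concentration_kBq_per_mL) * float(body_weight_kg) / float(decayed_activity_MBq)


def suv_lbm(concentration_kBq_per_mL: float, decayed_activity_MBq: float,
            lbm_kg: float) -> float:
    """Lean-body-mass SUV: as :func:`suv_bw` with LBM in place of BW."""
    return suv_bw(concentration_kBq_per_mL, decayed_activity_MBq, lbm_kg)
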