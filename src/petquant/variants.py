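"""Simulated measurement-software variants.

Commercial PET analysis workstations agree on the definitions of SUV, MTV and
TLG but differ in small implementation conventions.  A
:class:`VariantConvention` captures the three that matter for threshold-based
delineation:

* ``pre_max_smoothing_fwhm_mm`` — some tools estimate the lesion maximum on a
  lightly smoothed copy of the image (a "peak-like" max) rather than the raw
  hottest voxel;
* ``threshold_step_percent`` — the threshold grid the tool exposes (a tool
  with a 2% grid rounds a requested 63% to 64%);
* ``calibration_scale`` — a small multiplicative calibration offset between
  tools reading the same data;
* ``supports_lbm`` — whether the tool offers LBM-normalized SUV at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError
from .image import VolumetricImage

__all__ = ["VariantConvention", "DEFAULT_VARIANTS", "apply_calibration", "smoothed_reference_max"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class VariantConvention:
    """Measurement conventions of one simulated software variant."""

    name: str
    supports_lbm: bool = True
    pre_max_smoothing_fwhm_mm: float = 0.0
    threshold_step_percent: int = 1
    calibration_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.pre_max_smoothing_fwhm_mm < 0:
            raise InvalidArgumentError("smoothing FWHM must be nonnegative")
        if self.threshold_step_percent < 1:
            raise InvalidArgumentError("threshold step must be >= 1 percent")
        if self.calibration_scale <= 0:
            raise InvalidArgumentError("calibration scale must be positive")

    def snap_threshold(self, threshold_percent: float) -> int:
        """Round a requested threshold onto this variant's grid (half-up),
        clipped to [1, 99]."""
        step = self.threshold_step_percent
        snapped = int(np.floor(threshold_percent / step + 0.5)) * step
        return int(min(99, max(1, snapped)))


#: Three stand-in software variants.  Variant A mirrors a workstation without
#: LBM support and a coarser threshold grid; B reads the raw voxel max; C
#: smooths before taking the max and carries a small calibration offset.
DEFAULT_VARIANTS: tuple[VariantConvention, ...] = (
    VariantConvention("A", supports_lbm=False, pre_max_smoothing_fwhm_mm=0.0,
                      threshold_step_percent=2, calibration_scale=1.00),
    VariantConvention("B", supports_lbm=True, pre_max_smoothing_fwhm_mm=0.0,
                      threshold_step_percent=1, calibration_scale=0.97),
    VariantConvention("C", supports_lbm=True, pre_max_smoothing_fwhm_mm=4.0,
                      threshold_step_percent=1, calibration_scale=1.03),
)


def apply_calibration(image: VolumetricImage, convention: VariantConvention) -> VolumetricImage:
    """Return the image as this variant reads it (calibration offset applied)."""
    if convention.calibration_scale == 1.0:
        return image
    return VolumetricImage(image.data * convention.calibration_scale,
                           image.spacing_mm, image.origin_mm)


def smoothed_reference_max(image: VolumetricImage, region_mask: np.ndarray,
                           convention: VariantConvention) -> float | None:
    """Max-uptake estimate the variant uses as its threshold reference.

    Returns ``None`` when the variant reads the raw voxel max (no smoothing),
    in which case the segmentation routine uses the in-region maximum itself.
    """
    if convention.pre_max_smoothing_fwhm_mm == 0.0:
        return None
    sigma_vox = [convention.pre_max_smoothing_fwhm_mm * _FWHM_TO_SIGMA / s
                 for s in image.spacing_mm]
    smoothed = ndimage.gaussian_filter(image.data, sigma=sigma_vox, mode="nearest")
    return float(smoothed[region_mask].max())
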