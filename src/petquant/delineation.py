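"""Fixed-percentage-threshold VOI delineation and per-lesion metrics.

A lesion is segmented by keeping every voxel in a search region whose value
is at least ``threshold_percent`` of the maximum uptake in that region, then
reducing the result to the face-connected (6-neighbour) component containing
the maximum voxel.  From the resulting volume of interest the standard
semiquantitative PET parameters are derived:

* SUVmax / SUVmean — max / mean in-mask concentration normalized per
  :mod:`petquant.suv` in BW, LBM and raw Bq/mL unit systems;
* MTV (metabolic tumour volume) — voxel count × voxel volume, in cm³;
* TLG (total lesion glycolysis) — SUVmean × MTV, per unit system.

Conventions: threshold comparison is inclusive (``>=``); ties for the max are
broken by lowest linear index; negative voxel values (possible after noise)
are clamped to zero before any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, SegmentationError
from .image import VolumetricImage, region_to_mask
from .suv import SubjectInfo, SuvTriple, suv_bw, suv_lbm
from .variants import VariantConvention

__all__ = [
    "SegmentationMask",
    "LesionMetrics",
    "segment_fixed_threshold",
    "compute_mtv",
    "compute_lesion_metrics",
]

_FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationMask:
    """Boolean voxel flags aligned to a :class:`VolumetricImage` grid."""

    mask: np.ndarray
    voxel_volume_cm3: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise InvalidArgumentError("mask must be 3D")
        if self.voxel_volume_cm3 <= 0:
            raise InvalidArgumentError("voxel volume must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return compute_mtv(self)


@dataclass(frozen=True)
class LesionMetrics:
    """Semiquantitative readout of one delineated lesion.

    Each TLG field is exactly the product of the corresponding SUVmean
    component and the MTV.
    """

    suv_max: SuvTriple
    suv_mean: SuvTriple
    mtv_cm3: float
    tlg_bw: float
    tlg_raw: float
    tlg_lbm: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "suv_max_bw": self.suv_max.suv_bw,
            "suv_max_raw": self.suv_max.raw_bq_per_ml,
            "suv_max_lbm": self.suv_max.suv_lbm,
            "suv_mean_bw": self.suv_mean.suv_bw,
            "suv_mean_raw": self.suv_mean.raw_bq_per_ml,
            "suv_mean_lbm": self.suv_mean.suv_lbm,
            "mtv_cm3": self.mtv_cm3,
            "tlg_bw": self.tlg_bw,
            "tlg_raw": self.tlg_raw,
            "tlg_lbm": self.tlg_lbm,
        }


def segment_fixed_threshold(image: VolumetricImage, search_region,
                            threshold_percent: float,
                            reference_max: float | None = None) -> SegmentationMask:
    """Segment the VOI at ``threshold_percent`` of the in-region maximum.

    Parameters
    ----------
    image
        The concentration volume.
    search_region
        Boolean mask or tuple of slices restricting the search.
    threshold_percent
        Cut-off in percent of the reference maximum, in [1, 99].
    reference_max
        Optional externally estimated maximum (e.g. from a smoothed copy of
        the image, as some software variants do).  The seed voxel is always
        the raw in-region argmax.

    Returns
    -------
    SegmentationMask
        Face-connected component of supra-threshold voxels containing the
        maximum voxel; never empty on success.
    """
    if not (1 <= threshold_percent <= 99):
        raise SegmentationError(f"threshold must be in [1, 99] percent, got {threshold_percent}")
    region = region_to_mask(search_region, image.shape)
    if not region.any():
        raise SegmentationError("search region is empty")
    values = np.where(region, np.maximum(image.data, 0.0), -np.inf)
    flat_argmax = int(values.argmax())  # ties broken by lowest linear index
    seed = np.unravel_index(flat_argmax, image.shape)
    raw_max = float(values[seed])
    if raw_max <= 0:
        raise SegmentationError("search region contains no positive uptake")
    ref = raw_max if reference_max is None else float(reference_max)
    if ref <= 0:
        raise SegmentationError("reference maximum must be positive")

    cutoff = (threshold_percent / 100.0) * ref
    supra = region & (np.maximum(image.data, 0.0) >= cutoff)
    supra[seed] = True  # the seed max voxel always belongs to the VOI
    labels, _ = ndimage.label(supra, structure=_FACE_CONNECTIVITY)
    component = labels == labels[seed]
    return SegmentationMask(component, image.voxel_volume_cm3)


def compute_mtv(mask: SegmentationMask) -> float:
    """Metabolic tumour volume: voxel count × voxel volume, in cm³."""
    return mask.n_voxels * mask.voxel_volume_cm3


def compute_lesion_metrics(image: VolumetricImage, mask: SegmentationMask,
                           subject: SubjectInfo,
                           convention: VariantConvention | None = None) -> LesionMetrics:
    """SUVmax/SUVmean (BW, LBM, Bq/mL), MTV and TLG for one delineated lesion.

    LBM-normalized values are omitted (``None``) when the active variant's
    conventions disable LBM support.
    """
    if mask.mask.shape != image.shape:
        raise InvalidArgumentError("mask and image grids differ")
    if not mask.mask.any():
        raise InvalidArgumentError("mask is empty")
    in_mask_bq_ml = np.maximum(image.data[mask.mask], 0.0)
    max_bq_ml = float(in_mask_bq_ml.max())
    mean_bq_ml = float(in_mask_bq_ml.mean())

    activity = subject.decayed_activity_MBq
    bw = subject.body_weight_kg
    with_lbm = convention is None or convention.supports_lbm
    lbm = subject.lean_body_mass_kg if with_lbm else None

    def triple(bq_ml: float) -> SuvTriple:
        kbq_ml = bq_ml / 1000.0
        return SuvTriple(
            suv_bw=suv_bw(kbq_ml, activity, bw),
            raw_bq_per_ml=bq_ml,
            suv_lbm=suv_lbm(kbq_ml, activity, lbm) if lbm is not None else None,
        )

    s_max, s_mean = triple(max_bq_ml), triple(mean_bq_ml)
    mtv = compute_mtv(mask)
    return LesionMetrics(
        suv_max=s_max,
        suv_mean=s_mean,
        mtv_cm3=mtv,
        tlg_bw=s_mean.suv_bw * mtv,
        tlg_raw=s_mean.raw_bq_per_ml * mtv,
        tlg_lbm=s_mean.suv_lbm * mtv if s_mean.suv_lbm is not None else None,
    )
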