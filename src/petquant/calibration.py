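"""Phantom-driven threshold calibration and size-dependent threshold lookup.

Because of the partial-volume effect, the %-of-max threshold that recovers an
object's true volume depends strongly on its size: small blurred spheres need
a high cut-off, large spheres a lower one.  Calibration therefore scans all
integer thresholds 1–99% per phantom sphere and per software variant,
keeping the one whose measured MTV best matches the known sphere volume
(ties broken by the smallest threshold).  Per sphere size, the per-variant
optima are averaged with equal weight and rounded half-up to an integer
consensus threshold — emulating the clinical practice of applying one
literature threshold across all software.

Applying the table to a lesion is a chicken-and-egg problem (the threshold
depends on the size, the measured size on the threshold); it is resolved by a
fixed-point iteration over the size bins, with oscillations between two bins
settled in favour of the larger volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration_reference import PUBLISHED_PHANTOM_THRESHOLDS  # noqa: F401  (re-export)
from .delineation import compute_mtv, segment_fixed_threshold
from .errors import CalibrationError, ConfigurationError, InvalidArgumentError, SegmentationError
from .image import VolumetricImage
from .variants import VariantConvention, apply_calibration, smoothed_reference_max
from .image import region_to_mask

__all__ = [
    "ThresholdRow",
    "ThresholdTable",
    "ThresholdSelection",
    "optimal_threshold",
    "average_thresholds",
    "build_threshold_table",
    "threshold_for_size",
    "round_half_up",
    "PUBLISHED_PHANTOM_THRESHOLDS",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves rounded up."""
    return int(math.floor(x + 0.5))


def average_thresholds(entries: Sequence[float]) -> tuple[float, int]:
    """Equal-weight mean of per-variant optimal thresholds and its
    half-up-rounded integer consensus.

    A variant that contributed two equally good thresholds contributes two
    terms to the mean.
    """
    entries = list(entries)
    if not entries:
        raise InvalidArgumentError("cannot average an empty threshold list")
    if any(not 1 <= e <= 99 for e in entries):
        raise InvalidArgumentError(f"thresholds must be in [1, 99], got {entries}")
    mean = float(np.mean(entries))
    return mean, round_half_up(mean)


@dataclass(frozen=True)
class ThresholdRow:
    """Calibration result for one sphere size."""

    volume_cm3: float
    per_variant: dict[str, tuple[int, ...]]  # variant name -> optimal threshold(s)
    mean_percent: float
    consensus_percent: int


@dataclass
class ThresholdTable:
    """Size-binned consensus thresholds (rows sorted by sphere volume)."""

    rows: list[ThresholdRow]

    def __post_init__(self) -> None:
        if any(not 1 <= r.consensus_percent <= 99 for r in self.rows):
            raise InvalidArgumentError("consensus thresholds must be in [1, 99]")
        self.rows = sorted(self.rows, key=lambda r: r.volume_cm3)

    @classmethod
    def from_entries(cls, entries: Mapping[float, Mapping[str, Iterable[int]]]) -> "ThresholdTable":
        """Build a table from per-volume, per-variant threshold lists."""
        rows = []
        for vol, per_variant in entries.items():
            pv = {name: tuple(int(t) for t in ths) for name, ths in per_variant.items()}
            flat = [t for ths in pv.values() for t in ths]
            mean, consensus = average_thresholds(flat)
            rows.append(ThresholdRow(float(vol), pv, mean, consensus))
        return cls(rows)

    @property
    def volumes_cm3(self) -> tuple[float, ...]:
        return tuple(r.volume_cm3 for r in self.rows)

    @property
    def consensus_percents(self) -> tuple[int, ...]:
        return tuple(r.consensus_percent for r in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        variant_names: list[str] = []
        for row in self.rows:
            for name in row.per_variant:
                if name not in variant_names:
                    variant_names.append(name)
        data = []
        for row in self.rows:
            rec: dict[str, object] = {"volume_cm3": row.volume_cm3}
            for name in variant_names:
                ths = row.per_variant.get(name, ())
                rec[f"th_{name}"] = " & ".join(str(t) for t in ths)
            rec["mean_percent"] = row.mean_percent
            rec["consensus_percent"] = row.consensus_percent
            data.append(rec)
        return pd.DataFrame(data)


def optimal_threshold(image: VolumetricImage, search_region, true_volume_cm3: float,
                      reference_max: float | None = None) -> int:
    """Integer threshold in 1–99% whose segmented volume is closest to the
    known true volume; ties broken by the smallest threshold."""
    if true_volume_cm3 <= 0:
        raise InvalidArgumentError("true volume must be positive")
    best_th, best_err = None, math.inf
    for th in range(1, 100):
        try:
            mask = segment_fixed_threshold(image, search_region, th,
                                           reference_max=reference_max)
        except SegmentationError:
            continue
        err = abs(compute_mtv(mask) - true_volume_cm3)
        if err < best_err:
            best_th, best_err = th, err
    if best_th is None:
        raise CalibrationError("segmentation failed at every candidate threshold")
    return best_th


def build_threshold_table(
    variant_images: Mapping[str, VolumetricImage],
    sphere_regions: Sequence,
    truth_volumes_cm3: Sequence[float],
    conventions: Mapping[str, VariantConvention] | None = None,
) -> ThresholdTable:
    """Calibrate every (variant, sphere) pair and assemble the consensus table.

    Parameters
    ----------
    variant_images
        One phantom readout per variant (same geometry, possibly different
        conventions/noise realisations).
    sphere_regions
        Per-sphere search regions, shared across variants.
    truth_volumes_cm3
        Known sphere volumes, aligned with ``sphere_regions``.
    conventions
        Optional per-variant measurement conventions (calibration scale and
        smoothed-max reference) applied during calibration.
    """
    if not variant_images:
        raise ConfigurationError("need at least one variant")
    if len(sphere_regions) != len(truth_volumes_cm3) or not truth_volumes_cm3:
        raise ConfigurationError("need one truth volume per sphere region")
    entries: dict[float, dict[str, tuple[int, ...]]] = {
        float(v): {} for v in truth_volumes_cm3}
    for name, image in variant_images.items():
        conv = conventions.get(name) if conventions else None
        read = apply_calibration(image, conv) if conv else image
        for region, vol in zip(sphere_regions, truth_volumes_cm3):
            ref = None
            if conv is not None:
                ref = smoothed_reference_max(read, region_to_mask(region, read.shape), conv)
            entries[float(vol)][name] = (optimal_threshold(read, region, vol,
                                                           reference_max=ref),)
    return ThresholdTable.from_entries(entries)


@dataclass(frozen=True)
class ThresholdSelection:
    """Outcome of the size-dependent threshold lookup for one lesion."""

    threshold_percent: int
    bin_volume_cm3: float
    bin_index: int
    measured_mtv_cm3: float
    n_iterations: int
    converged: bool


def threshold_for_size(table: ThresholdTable, image: VolumetricImage, search_region,
                       convention: VariantConvention | None = None,
                       start_index: int | None = None,
                       max_iterations: int = 5) -> ThresholdSelection:
    """Pick the consensus threshold for a lesion of initially unknown size.

    Iteratively: segment at the current bin's consensus threshold, measure
    MTV, reassign to the bin whose calibration volume is nearest in
    log-space, until a fixed point (at most ``max_iterations``).  A two-bin
    oscillation is resolved by the larger-volume bin.
    """
    if not table.rows:
        raise InvalidArgumentError("threshold table is empty")
    log_vols = np.log(np.asarray(table.volumes_cm3))
    ref = None
    if convention is not None and convention.pre_max_smoothing_fwhm_mm > 0:
        ref = smoothed_reference_max(image, region_to_mask(search_region, image.shape),
                                     convention)

    def measure(bin_idx: int) -> tuple[float, int]:
        th = table.rows[bin_idx].consensus_percent
        if convention is not None:
            th = convention.snap_threshold(th)
        mask = segment_fixed_threshold(image, search_region, th, reference_max=ref)
        return compute_mtv(mask), th

    idx = len(table.rows) // 2 if start_index is None else start_index
    visited = [idx]
    converged = False
    mtv, th = measure(idx)
    for it in range(1, max_iterations + 1):
        new_idx = int(np.argmin(np.abs(log_vols - math.log(max(mtv, 1e-9)))))
        if new_idx == idx:
            converged = True
            break
        if new_idx in visited:  # oscillation: keep the larger-volume bin
            idx = max(new_idx, idx)
            mtv, th = measure(idx)
            break
        visited.append(new_idx)
        idx = new_idx
        mtv, th = measure(idx)
    row = table.rows[idx]
    return ThresholdSelection(threshold_percent=row.consensus_percent,
                              bin_volume_cm3=row.volume_cm3, bin_index=idx,
                              measured_mtv_cm3=mtv, n_iterations=len(visited),
                              converged=converged)
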