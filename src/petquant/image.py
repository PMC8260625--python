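"""Volumetric image container and voxel-grid helpers.

Axis convention: arrays are indexed ``(z, y, x)`` with 0-based indices;
``spacing_mm`` and ``origin_mm`` follow the same axis order.  The physical
position of voxel ``(i, j, k)`` is ``origin + index * spacing`` (voxel-center
convention).  Voxel volume is always derived from the header spacing and never
assumed isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["VolumetricImage", "box_region", "region_to_mask"]

#: Region selector: either a boolean array aligned to the image grid or a
#: tuple of per-axis slices.
Region = "np.ndarray | tuple[slice, slice, slice]"


@dataclass
class VolumetricImage:
    """A 3D scalar grid of activity concentration in Bq/mL.

    Parameters
    ----------
    data
        3D float array of concentrations, axis order ``(z, y, x)``.
    spacing_mm
        Voxel spacing per axis in mm, same order.
    origin_mm
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise InvalidArgumentError(f"expected a 3D array, got {self.data.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise InvalidArgumentError(f"spacing must be 3 positive lengths, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Voxel volume in cm³ (product of spacings; 1 cm³ = 1000 mm³)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers (broadcastable)."""
        axes = []
        for n, sp, o in zip(self.shape, self.spacing_mm, self.origin_mm):
            axes.append(o + sp * np.arange(n, dtype=np.float64))
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))  # type: ignore[return-value]

    def copy(self) -> "VolumetricImage":
        return VolumetricImage(self.data.copy(), self.spacing_mm, self.origin_mm)


def box_region(center_idx: tuple[int, int, int], half_extent: tuple[int, int, int],
               shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    """Axis-aligned box of slices around ``center_idx``, clipped to ``shape``."""
    return tuple(
        slice(max(0, c - h), min(n, c + h + 1))
        for c, h, n in zip(center_idx, half_extent, shape)
    )  # type: ignore[return-value]


def region_to_mask(region, shape: tuple[int, int, int]) -> np.ndarray:
    """Normalize a region selector (slices or boolean mask) to a boolean mask."""
    if isinstance(region, np.ndarray):
        if region.dtype != bool:
            raise InvalidArgumentError("mask region must be boolean")
        if region.shape != tuple(shape):
            raise InvalidArgumentError(
                f"region shape {region.shape} does not match image shape {tuple(shape)}")
        return region
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(region)] = True
    return mask
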