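"""Damaged-tissue volume from lesion areas in serial brain slices.

The quantification step of TTC-stained histology: given the lesion area in
each successive slice (segmentation is upstream input, supplied either as a
binary mask or directly as mm²), the volume is the slab integral
``sum(area_i) * thickness``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DomainError

__all__ = ["LesionStack", "lesion_volume", "mask_area"]


@dataclass
class LesionStack:
    """Per-slice lesion areas (mm², anatomical order) and slice thickness."""

    areas_mm2: np.ndarray
    slice_thickness_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if self.areas_mm2.ndim != 1 or self.areas_mm2.size < 1:
            raise DomainError("need at least one slice area")
        if self.slice_thickness_um <= 0:
            raise DomainError("slice thickness must be positive")


def lesion_volume(stack: LesionStack) -> float:
    """Slab-rule volume in mm³: sum of slice areas times slice thickness."""
    if np.any(stack.areas_mm2 < 0):
        raise DomainError("negative lesion area")
    return float(np.sum(stack.areas_mm2) * stack.slice_thickness_um / 1000.0)


def mask_area(mask: np.ndarray, pixel_size_mm: float) -> float:
    """Lesion area (mm²) of a binary mask with isotropic pixels."""
    mask = np.asarray(mask)
    if pixel_size_mm <= 0:
        raise DomainError("pixel size must be positive")
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise DomainError("mask must be binary (0/1 or bool)")
        mask = mask.astype(bool)
    return float(np.count_nonzero(mask) * pixel_size_mm**2)
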