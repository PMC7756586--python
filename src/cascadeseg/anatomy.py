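"""Anatomical border rules anchored on the vessel bifurcation.

The bifurcation slice is read off a vessel mask by in-plane connected
component counting (after a small-speck filter): the smallest z index ``b``
such that every occupied slice at or above ``b`` holds a single component
while slice ``b - 1`` holds at least two.  The nodal region's superior
border is one slice below ``b``; the para-aortic region's inferior border
is ``b`` itself, so the two regions end up axially adjacent and disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage import measure, morphology

from .errors import (ContractError, DataError, DegenerateBorderError,
                     EmptyMaskError, NoBifurcationError, VesselQualityError)
from .segmentation import CropSpec, center_of_mass

__all__ = [
    "BorderRuleResult",
    "vessel_search_region",
    "detect_bifurcation_slice",
    "apply_nodal_superior_border",
    "apply_pan_inferior_border",
]

#: In-plane components smaller than this many voxels are ignored.
SPECK_MIN_VOXELS = 3


@dataclass
class BorderRuleResult:
    structure: str
    rule: str  # nodal_superior | pan_inferior
    anchor_slice: int
    applied: bool
    voxels_removed: int = 0


def vessel_search_region(l4_mask: np.ndarray, margin: int | Tuple[int, int, int] = (8, 12, 12)
                         ) -> CropSpec:
    """Crop around the L4 vertebral body to restrict the vessel model's view.

    The box is L4's tight bounding box dilated by ``margin`` (default 8
    slices axially, 12 voxels in-plane), centered on the L4 centroid.
    """
    l4_mask = np.asarray(l4_mask)
    idx = np.nonzero(l4_mask)
    if idx[0].size == 0:
        raise DataError("vessel search region requires a non-empty L4 mask")
    if isinstance(margin, int):
        margin = (margin, margin, margin)
    center = center_of_mass(l4_mask)
    box = tuple(
        min(int(ax.max() - ax.min() + 1 + 2 * m), g)
        for ax, m, g in zip(idx, margin, l4_mask.shape)
    )
    return CropSpec(center=center, box_shape=box)  # type: ignore[arg-type]


def _component_counts(vessel_mask: np.ndarray) -> np.ndarray:
    """Per-slice in-plane component count after removing specks."""
    counts = np.zeros(vessel_mask.shape[0], dtype=int)
    for z in range(vessel_mask.shape[0]):
        sl = vessel_mask[z].astype(bool)
        if not sl.any():
            continue
        cleaned = morphology.remove_small_objects(sl, max_size=SPECK_MIN_VOXELS - 1)
        counts[z] = int(measure.label(cleaned, connectivity=1).max())
    return counts


def detect_bifurcation_slice(vessel_mask: np.ndarray) -> int:
    """Smallest z with a single component on every occupied slice above it
    and >= 2 components immediately below."""
    vessel_mask = np.asarray(vessel_mask)
    occupied = np.flatnonzero(vessel_mask.any(axis=(1, 2)))
    if occupied.size == 0:
        raise EmptyMaskError("vessel mask is empty")
    if occupied.size < 3:
        raise ContractError("vessel mask must occupy at least 3 slices")
    counts = _component_counts(vessel_mask)
    occ_counts = counts[occupied]
    if (occ_counts >= 3).mean() > 0.5:
        raise VesselQualityError(
            "vessel mask fragmented: >= 3 components on most occupied slices")
    # walk down from the top of the vessel while slices hold one component
    b = None
    for z in occupied[::-1]:
        if counts[z] == 1:
            b = int(z)
        else:
            break
    if b is None:
        raise NoBifurcationError("topmost vessel slice is not a single component")
    below = occupied[occupied < b]
    if below.size == 0 or counts[below.max()] < 2:
        raise NoBifurcationError("vessel never splits into two components")
    return b


def apply_nodal_superior_border(nodal_mask: np.ndarray, b: int, structure: str = "nodal"
                                ) -> Tuple[np.ndarray, BorderRuleResult]:
    """Truncate the nodal mask so its superior-most allowed slice is ``b - 1``."""
    nodal_mask = np.asarray(nodal_mask)
    if b <= 0:
        raise DegenerateBorderError("bifurcation at slice 0 leaves no nodal slices")
    if b > nodal_mask.shape[0]:
        raise ContractError(f"bifurcation slice {b} outside grid")
    out = nodal_mask.copy()
    removed = int(out[b:].sum())
    out[b:] = 0
    result = BorderRuleResult(structure=structure, rule="nodal_superior",
                              anchor_slice=b, applied=removed > 0,
                              voxels_removed=removed)
    return out.astype(np.uint8), result


def apply_pan_inferior_border(pan_mask: np.ndarray, b: int, structure: str = "pan"
                              ) -> Tuple[np.ndarray, BorderRuleResult]:
    """Truncate the para-aortic mask so its inferior-most allowed slice is ``b``.

    Placed one slice above the nodal superior border, the two regions are
    axially adjacent with no shared slice.
    """
    pan_mask = np.asarray(pan_mask)
    if b <= 0:
        raise DegenerateBorderError("bifurcation at slice 0 is degenerate")
    if b > pan_mask.shape[0]:
        raise ContractError(f"bifurcation slice {b} outside grid")
    out = pan_mask.copy()
    removed = int(out[:b].sum())
    out[:b] = 0
    result = BorderRuleResult(structure=structure, rule="pan_inferior",
                              anchor_slice=b, applied=removed > 0,
                              voxels_removed=removed)
    return out.astype(np.uint8), result
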