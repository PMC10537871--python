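"""Click-and-draw segmentation: two-pass 3-D flood fill.

The operator clicks one point near the lesion centroid.  A first flood
fill grows the set of voxels connected to the seed with uptake at least
``t x I(seed)`` (t = 0.7 for "click and draw", 0.4 for "click 40").  A
volume guard aborts if this first-pass region exceeds 500 cm³.  The
background-adaptive threshold is then computed on the first-pass region,
and a second flood fill from the region's maximum-uptake voxel — over the
whole volume — produces the final ROI.  Running the second pass unrestricted
follows the method as published and reproduces its known failure mode
(occasionally misplaced, grossly oversized ROIs); ``restrict_to_first_pass``
confines it when that is not wanted.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .image_model import ROIMask, SeedPoint, SUVVolume, mask_volume_cm3
from .thresholding import NestleThresholdResult, SegmentationWarning, compute_nestle_threshold

__all__ = [
    "ClickResult",
    "FirstPassVolumeError",
    "SeedBelowThresholdError",
    "flood_fill",
    "segment_click",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),   # face adjacency
    26: ndimage.generate_binary_structure(3, 3),  # face+edge+corner
}


class FirstPassVolumeError(RuntimeError):
    """First-pass region exceeds the volume guard (the published exception)."""


class SeedBelowThresholdError(ValueError):
    """Seed voxel uptake is below the flood-fill threshold."""


@dataclasses.dataclass(frozen=True)
class ClickResult:
    """Final mask plus the intermediates of the two-pass algorithm."""

    mask: ROIMask
    first_pass_region: ROIMask
    first_pass_threshold: float
    nestle_threshold: float
    max_voxel: SeedPoint
    nestle_details: NestleThresholdResult


def _connected_component(
    admissible: np.ndarray, seed: tuple[int, int, int], connectivity: int
) -> np.ndarray:
    try:
        structure = _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6 or 26") from None
    labels, _ = ndimage.label(admissible, structure=structure)
    return labels == labels[seed]


def flood_fill(
    vol: SUVVolume, seed: SeedPoint, min_uptake: float, connectivity: int = 6
) -> ROIMask:
    """Maximal connected voxel set containing the seed with uptake >= ``min_uptake``."""
    seed = SeedPoint(*seed).validate(vol.grid)
    if vol.values[tuple(seed)] < min_uptake:
        raise SeedBelowThresholdError(
            f"seed uptake {vol.values[tuple(seed)]:.3g} below threshold {min_uptake:.3g}"
        )
    admissible = vol.values >= min_uptake
    return ROIMask(vol.grid, _connected_component(admissible, tuple(seed), connectivity))


def _argmax_in(vol: SUVVolume, region: ROIMask) -> SeedPoint:
    # smallest flat index in (x, y, z) raster order wins ties
    masked = np.where(region.indicator, vol.values, -np.inf)
    flat = int(np.argmax(masked))
    return SeedPoint(*np.unravel_index(flat, vol.grid.shape))


def segment_click(
    vol: SUVVolume,
    seed: SeedPoint,
    t: float = 0.7,
    beta: float = 0.30,
    max_first_pass_cm3: float = 500.0,
    connectivity: int = 6,
    restrict_to_first_pass: bool = False,
) -> ClickResult:
    """Two-pass click-and-draw delineation.

    1. flood fill from the seed at threshold ``t x I(seed)`` -> region Ω;
    2. raise :class:`FirstPassVolumeError` if ``|Ω| > max_first_pass_cm3``;
    3. compute the background-adaptive threshold ``I_N`` on Ω;
    4. flood fill again at ``I_N`` from Ω's maximum-uptake voxel V_M.

    If ``I_N`` exceeds the uptake at V_M the final mask is empty (with a
    warning); all intermediates are returned either way.
    """
    if not 0 < t < 1:
        raise ValueError("t must be in (0, 1)")
    seed = SeedPoint(*seed).validate(vol.grid)
    first_threshold = t * float(vol.values[tuple(seed)])
    omega = flood_fill(vol, seed, first_threshold, connectivity)
    if mask_volume_cm3(omega) > max_first_pass_cm3:
        raise FirstPassVolumeError(
            f"first-pass region exceeds volume limit "
            f"({mask_volume_cm3(omega):.1f} > {max_first_pass_cm3} cm³)"
        )
    details = compute_nestle_threshold(vol, omega, beta)
    vm = _argmax_in(vol, omega)
    if details.tn > vol.values[tuple(vm)]:
        warnings.warn(
            f"second-pass threshold {details.tn:.3g} exceeds maximum uptake "
            f"{vol.values[tuple(vm)]:.3g}; empty mask",
            SegmentationWarning,
            stacklevel=2,
        )
        final = ROIMask(vol.grid, np.zeros(vol.grid.shape, dtype=bool))
    else:
        admissible = vol.values >= details.tn
        if restrict_to_first_pass:
            admissible &= omega.indicator
        final = ROIMask(vol.grid, _connected_component(admissible, tuple(vm), connectivity))
    return ClickResult(
        mask=final,
        first_pass_region=omega,
        first_pass_threshold=first_threshold,
        nestle_threshold=details.tn,
        max_voxel=vm,
        nestle_details=details,
    )
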