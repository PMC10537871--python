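"""Draw-and-refine threshold segmentation.

The four threshold methods share one scheme: an operator sketches a volume
that completely encloses the putative lesion, then a threshold rule filters
voxels inside the sketch.  Refinement only ever removes voxels, so every
result is a subset of the sketch.

* absolute threshold — keep voxels with SUV >= 2.5 (the common fixed cut);
* relative threshold — keep voxels with SUV >= fraction x SUVmax of the
  sketch (40% and 50% are the benchmarked fractions);
* background-adaptive (Nestle) threshold —

      t_N = beta * I70 + Ibgd

  where ``I70`` is the mean uptake of the voxels above 70% of the region
  maximum, and ``Ibgd`` the mean uptake of a 4 mm-thick background shell
  offset 12 mm outward from that 70% core, after excluding shell voxels
  with SUV > 2.5.  ``beta`` is a scanner-dependent tuning constant,
  0.30 by default.

Tie rule: voxels exactly at a threshold are retained (>=); the 70% core
uses a strict > by definition of the isocontour.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .image_model import (
    EmptyMaskError,
    ROIMask,
    SUVVolume,
    _require_same_grid,
    distance_from_region,
)

__all__ = [
    "SegmentationWarning",
    "NestleThresholdResult",
    "segment_absolute_threshold",
    "segment_relative_threshold",
    "compute_nestle_threshold",
    "segment_nestle",
]

ISOCONTOUR_FRACTION = 0.7  # the ">70% of maximum" core defining I70
SHELL_OFFSET_MM = 12.0
SHELL_THICKNESS_MM = 4.0
SHELL_EXCLUSION_SUV = 2.5


class SegmentationWarning(UserWarning):
    """Non-fatal segmentation conditions (empty result, empty shell, ...)."""


@dataclasses.dataclass(frozen=True)
class NestleThresholdResult:
    """Intermediate quantities of the background-adaptive threshold."""

    tn: float
    i70: float
    ibgd: float
    imax: float
    beta: float
    shell: ROIMask
    excluded_count: int

    def as_dict(self) -> dict:
        return {
            "tn": self.tn,
            "i70": self.i70,
            "ibgd": self.ibgd,
            "imax": self.imax,
            "beta": self.beta,
            "shell_voxels": self.shell.voxel_count,
            "excluded_count": self.excluded_count,
        }


def _check_inputs(vol: SUVVolume, mask: ROIMask) -> None:
    _require_same_grid(vol.grid, mask.grid)
    if mask.is_empty:
        raise EmptyMaskError("sketch/region must be non-empty")


def segment_absolute_threshold(
    vol: SUVVolume, sketch_mask: ROIMask, threshold: float = 2.5
) -> ROIMask:
    """Keep sketch voxels with uptake >= an absolute SUV threshold.

    No connectivity filtering is applied; an empty result is returned (with
    a :class:`SegmentationWarning`) when nothing in the sketch reaches the
    threshold.
    """
    _check_inputs(vol, sketch_mask)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    keep = sketch_mask.indicator & (vol.values >= threshold)
    if not keep.any():
        warnings.warn(
            f"no sketch voxel reaches SUV {threshold}; returning an empty mask",
            SegmentationWarning,
            stacklevel=2,
        )
    return ROIMask(vol.grid, keep)


def segment_relative_threshold(
    vol: SUVVolume, sketch_mask: ROIMask, fraction: float
) -> ROIMask:
    """Keep sketch voxels with uptake >= fraction x (sketch SUVmax).

    The result always contains the argmax voxel of the sketch.
    """
    _check_inputs(vol, sketch_mask)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    imax = float(vol.values[sketch_mask.indicator].max())
    keep = sketch_mask.indicator & (vol.values >= fraction * imax)
    return ROIMask(vol.grid, keep)


def compute_nestle_threshold(
    vol: SUVVolume,
    region: ROIMask,
    beta: float = 0.30,
    *,
    shell_offset_mm: float = SHELL_OFFSET_MM,
    shell_thickness_mm: float = SHELL_THICKNESS_MM,
    shell_exclusion_suv: float = SHELL_EXCLUSION_SUV,
) -> NestleThresholdResult:
    """Background-adaptive threshold ``t_N = beta * I70 + Ibgd``.

    ``I70`` is the mean uptake of region voxels strictly above 70% of the
    region maximum.  The background shell is the set of voxels at physical
    distance ``[shell_offset_mm, shell_offset_mm + shell_thickness_mm)``
    from that core, anywhere on the grid (the background lies outside the
    sketched lesion by construction); shell voxels with uptake above
    ``shell_exclusion_suv`` are excluded from the background mean.

    An empty retained shell yields ``Ibgd = 0`` plus a warning rather than
    an error — conservative (lower threshold) and keeps batch runs alive.
    """
    _check_inputs(vol, region)
    if beta < 0:
        raise ValueError("beta must be >= 0")
    values = vol.values
    imax = float(values[region.indicator].max())
    if imax <= 0:
        raise ValueError("region maximum uptake must be > 0")
    core = region.indicator & (values > ISOCONTOUR_FRACTION * imax)
    i70 = float(values[core].mean())

    dist = distance_from_region(ROIMask(vol.grid, core))
    band = (dist >= shell_offset_mm) & (dist < shell_offset_mm + shell_thickness_mm)
    if not band.any():
        warnings.warn(
            "background shell lies entirely outside the grid",
            SegmentationWarning,
            stacklevel=2,
        )
    retained = band & (values <= shell_exclusion_suv)
    excluded_count = int(band.sum() - retained.sum())
    if retained.any():
        ibgd = float(values[retained].mean())
    else:
        ibgd = 0.0
        warnings.warn(
            "background shell empty after the SUV exclusion rule; Ibgd set to 0",
            SegmentationWarning,
            stacklevel=2,
        )
    tn = beta * i70 + ibgd
    return NestleThresholdResult(
        tn=tn,
        i70=i70,
        ibgd=ibgd,
        imax=imax,
        beta=beta,
        shell=ROIMask(vol.grid, retained),
        excluded_count=excluded_count,
    )


def segment_nestle(
    vol: SUVVolume,
    sketch_mask: ROIMask,
    beta: float = 0.30,
    *,
    with_details: bool = False,
    **shell_kwargs,
):
    """Draw-and-refine with the background-adaptive threshold.

    The threshold is computed on the sketch itself, then sketch voxels with
    uptake >= ``t_N`` are kept.  With ``with_details=True`` the
    :class:`NestleThresholdResult` is returned alongside the mask.
    """
    result = compute_nestle_threshold(vol, sketch_mask, beta, **shell_kwargs)
    keep = sketch_mask.indicator & (vol.values >= result.tn)
    if not keep.any():
        warnings.warn(
            f"threshold t_N={result.tn:.3g} exceeds every sketch uptake; empty mask",
            SegmentationWarning,
            stacklevel=2,
        )
    mask = ROIMask(vol.grid, keep)
    if with_details:
        return mask, result
    return mask
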