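"""Core grid / volume / mask data model and geometry utilities.

Everything downstream (thresholding, region growing, evaluation, phantom
simulation) operates on three containers defined here:

``ImageGrid``
    A regular 3-D voxel lattice with anisotropic physical spacing in mm.
    Voxel indices are 0-based and ordered ``(x, y, z)``; the physical
    position of a voxel *centre* is ``origin + index * spacing``.

``SUVVolume``
    One finite, non-negative standardised-uptake-value (SUV, g/mL) scalar
    per voxel.

``ROIMask``
    A binary region of interest on the same lattice.

All physical quantities are millimetres (lengths), mm³/cm³ (volumes) and
SUV (intensities).  Distances between voxels are Euclidean
centre-to-centre distances honouring the anisotropic spacing.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "SUVVolume",
    "ROIMask",
    "SeedPoint",
    "Sphere",
    "SphereSketch",
    "GridMismatchError",
    "EmptyMaskError",
    "rasterize_sketch",
    "mask_volume_cm3",
    "distance_from_region",
]


class GridMismatchError(ValueError):
    """Raised when paired volumes/masks do not live on the same grid."""


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty region."""


@dataclasses.dataclass(frozen=True)
class ImageGrid:
    """A regular 3-D voxel lattice.

    Parameters
    ----------
    shape
        Voxel counts per axis ``(nx, ny, nz)``; each >= 1.
    spacing
        Physical voxel size per axis in mm; each > 0.
    origin
        Physical position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("grid is three-dimensional: shape, spacing and origin need 3 components")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def axis_centres_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical centre coordinates along each axis (three 1-D arrays)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def index_to_physical(self, index: Sequence[int]) -> tuple[float, float, float]:
        """Physical centre (mm) of the voxel at ``index``."""
        return tuple(self.origin[a] + index[a] * self.spacing[a] for a in range(3))

    def physical_to_index(self, point_mm: Sequence[float]) -> tuple[int, int, int]:
        """Nearest voxel index to a physical point; clipped to the grid."""
        idx = tuple(
            int(np.clip(round((point_mm[a] - self.origin[a]) / self.spacing[a]), 0, self.shape[a] - 1))
            for a in range(3)
        )
        return idx

    def contains_index(self, index: Sequence[int]) -> bool:
        return all(0 <= index[a] < self.shape[a] for a in range(3))

    def isclose(self, other: "ImageGrid", rtol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-6)
        )


def _require_same_grid(a: "ImageGrid", b: "ImageGrid") -> None:
    if not a.isclose(b):
        raise GridMismatchError(f"grids do not match: {a} vs {b}")


@dataclasses.dataclass(frozen=True)
class SUVVolume:
    """A 3-D scalar field of SUV values on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise ValueError(f"values shape {values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV values must all be finite")
        if np.any(values < 0):
            raise ValueError("SUV values must be non-negative")
        object.__setattr__(self, "values", values)

    def max(self) -> float:
        return float(self.values.max())


@dataclasses.dataclass(frozen=True)
class ROIMask:
    """A binary voxel region on an :class:`ImageGrid`."""

    grid: ImageGrid
    indicator: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if ind.dtype != bool:
            uniq = np.unique(ind)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask indicator values must be in {0, 1}")
            ind = ind.astype(bool)
        if ind.shape != self.grid.shape:
            raise ValueError(f"indicator shape {ind.shape} != grid shape {self.grid.shape}")
        object.__setattr__(self, "indicator", ind)

    @property
    def voxel_count(self) -> int:
        return int(self.indicator.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.indicator.any())

    # set algebra on one grid -------------------------------------------------
    def __and__(self, other: "ROIMask") -> "ROIMask":
        _require_same_grid(self.grid, other.grid)
        return ROIMask(self.grid, self.indicator & other.indicator)

    def __or__(self, other: "ROIMask") -> "ROIMask":
        _require_same_grid(self.grid, other.grid)
        return ROIMask(self.grid, self.indicator | other.indicator)

    def issubset(self, other: "ROIMask") -> bool:
        _require_same_grid(self.grid, other.grid)
        return bool(np.all(~self.indicator | other.indicator))


class SeedPoint(NamedTuple):
    """A 0-based voxel index triple ``(x, y, z)``."""

    x: int
    y: int
    z: int

    def validate(self, grid: ImageGrid) -> "SeedPoint":
        if not grid.contains_index(self):
            raise ValueError(f"seed {tuple(self)} outside grid of shape {grid.shape}")
        return self


class Sphere(NamedTuple):
    """A sphere in physical space: centre (mm) and radius (mm) > 0."""

    center_mm: tuple[float, float, float]
    radius_mm: float


@dataclasses.dataclass(frozen=True)
class SphereSketch:
    """An operator sketch: the union of one or more spheres enclosing a lesion."""

    spheres: tuple[Sphere, ...]

    def __post_init__(self) -> None:
        spheres = tuple(
            Sphere((float(c[0]), float(c[1]), float(c[2])), float(r)) for c, r in self.spheres
        )
        if not spheres:
            raise ValueError("sketch must contain at least one sphere")
        if any(s.radius_mm <= 0 for s in spheres):
            raise ValueError("sphere radii must be > 0")
        object.__setattr__(self, "spheres", spheres)


def rasterize_sketch(sketch: SphereSketch, grid: ImageGrid) -> ROIMask:
    """Rasterise a sphere sketch onto a grid.

    A voxel belongs to the mask iff its physical centre lies within at least
    one sphere (centre-to-centre distance <= radius, inclusive).

    Raises
    ------
    EmptyMaskError
        If no voxel centre falls inside any sphere.
    """
    cx, cy, cz = grid.axis_centres_mm()
    member = np.zeros(grid.shape, dtype=bool)
    for (sx, sy, sz), r in sketch.spheres:
        d2 = (
            (cx[:, None, None] - sx) ** 2
            + (cy[None, :, None] - sy) ** 2
            + (cz[None, None, :] - sz) ** 2
        )
        member |= d2 <= r * r
    if not member.any():
        raise EmptyMaskError("sketch does not intersect grid")
    return ROIMask(grid, member)


def mask_volume_cm3(mask: ROIMask) -> float:
    """Physical volume of a mask in cm³ (voxel count x voxel volume)."""
    return mask.voxel_count * mask.grid.voxel_volume_mm3 / 1000.0


def distance_from_region(mask: ROIMask) -> np.ndarray:
    """Euclidean distance field (mm) from a non-empty region.

    For every voxel outside the region, the distance from its centre to the
    nearest member-voxel centre, using the grid's anisotropic spacing;
    0 on member voxels.
    """
    if mask.is_empty:
        raise EmptyMaskError("distance field of an empty region is undefined")
    return ndimage.distance_transform_edt(~mask.indicator, sampling=mask.grid.spacing)


def masks_from_labels(grid: ImageGrid, labels: np.ndarray) -> Iterable[ROIMask]:
    """Split an integer label image into one ROIMask per positive label."""
    for lab in np.unique(labels):
        if lab > 0:
            yield ROIMask(grid, labels == lab)


def sphere_volume_cm3(radius_mm: float) -> float:
    """Analytic volume of a sphere, in cm³."""
    return 4.0 / 3.0 * math.pi * radius_mm**3 / 1000.0
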