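"""Synthetic PET phantoms with known ground truth.

Real FDG-PET tumour images show focal high-uptake lesions (SUVmax roughly
4–20) on a low, fairly uniform background (SUV 1–2), smeared by the
scanner's point-spread function (a few mm FWHM) and corrupted by
reconstruction noise.  The generator emulates exactly that chain on a grid
with clinical PET spacing (default 2.73 x 2.73 x 3.27 mm):

1. paint the background SUV everywhere;
2. set each lesion's peak SUV inside its ellipsoid (overlapping ellipsoids
   take the maximum, which models heterogeneous lesions with hot cores);
3. convolve with an isotropic Gaussian PSF of the given FWHM;
4. add zero-mean Gaussian noise, clipped at zero.

Ground truth is the pre-blur ellipsoid support — the analogue of anatomical
truth, unambiguous and independent of any isocontour convention.  Each case
also carries the operator inputs the delineation methods need: a seed point
at the (first) lesion centre and a circumscribing sphere sketch with a
configurable margin.

Everything is a deterministic function of the configuration and the RNG
seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_model import (
    ImageGrid,
    ROIMask,
    SeedPoint,
    Sphere,
    SphereSketch,
    SUVVolume,
)

__all__ = [
    "Lesion",
    "PhantomConfig",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_SPACING_MM",
]

DEFAULT_SPACING_MM = (2.73, 2.73, 3.27)
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclasses.dataclass(frozen=True)
class Lesion:
    """An ellipsoidal uptake focus: centre (mm), per-axis radii (mm), peak SUV."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_suv: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("lesion radii must be > 0")
        if self.peak_suv <= 0:
            raise ValueError("lesion peak SUV must be > 0")

    @property
    def bounding_radius_mm(self) -> float:
        return max(self.radii_mm)


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    grid: ImageGrid
    lesions: tuple[Lesion, ...]
    background_suv: float = 1.5
    psf_fwhm_mm: float = 6.0
    noise_sd_suv: float = 0.2
    sketch_margin: float = 1.5  # sketch radius = bounding radius x margin
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lesions = tuple(self.lesions)
        if not lesions:
            raise ValueError("phantom needs at least one lesion")
        if any(l.peak_suv <= self.background_suv for l in lesions):
            raise ValueError("every lesion peak must exceed the background SUV")
        if self.psf_fwhm_mm < 0 or self.noise_sd_suv < 0:
            raise ValueError("psf_fwhm_mm and noise_sd_suv must be >= 0")
        lo = np.asarray(self.grid.origin)
        hi = lo + (np.asarray(self.grid.shape) - 1) * np.asarray(self.grid.spacing)
        for l in lesions:
            c = np.asarray(l.center_mm)
            if np.any(c - l.radii_mm < lo - 1e-9) or np.any(c + l.radii_mm > hi + 1e-9):
                raise ValueError(f"lesion at {l.center_mm} extends outside the grid")
        object.__setattr__(self, "lesions", lesions)


@dataclasses.dataclass(frozen=True)
class PhantomCase:
    case_id: str
    volume: SUVVolume
    gt_mask: ROIMask
    seed: SeedPoint
    sketch: SphereSketch
    config: PhantomConfig


def _ellipsoid_support(grid: ImageGrid, lesion: Lesion) -> np.ndarray:
    cx, cy, cz = grid.axis_centres_mm()
    rx, ry, rz = lesion.radii_mm
    x0, y0, z0 = lesion.center_mm
    q = (
        ((cx[:, None, None] - x0) / rx) ** 2
        + ((cy[None, :, None] - y0) / ry) ** 2
        + ((cz[None, None, :] - z0) / rz) ** 2
    )
    return q <= 1.0


def generate_phantom(config: PhantomConfig, case_id: str = "phantom-0") -> PhantomCase:
    """Simulate one PET case: blurred, noisy lesions plus ground truth."""
    grid = config.grid
    values = np.full(grid.shape, config.background_suv, dtype=np.float64)
    gt = np.zeros(grid.shape, dtype=bool)
    for lesion in config.lesions:
        support = _ellipsoid_support(grid, lesion)
        gt |= support
        values[support] = np.maximum(values[support], lesion.peak_suv)
    if not gt.any():
        raise ValueError("no lesion rasterised to any voxel; enlarge radii or refine the grid")
    if config.psf_fwhm_mm > 0:
        sigma_vox = [
            config.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in grid.spacing
        ]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    if config.noise_sd_suv > 0:
        rng = np.random.default_rng(config.rng_seed)
        values = values + rng.normal(0.0, config.noise_sd_suv, size=values.shape)
    values = np.clip(values, 0.0, None)

    first = config.lesions[0]
    seed = SeedPoint(*grid.physical_to_index(first.center_mm)).validate(grid)
    spheres = tuple(
        Sphere(l.center_mm, l.bounding_radius_mm * config.sketch_margin)
        for l in config.lesions
    )
    return PhantomCase(
        case_id=case_id,
        volume=SUVVolume(grid, values),
        gt_mask=ROIMask(grid, gt),
        seed=seed,
        sketch=SphereSketch(spheres),
        config=config,
    )


def _grid_for_radius(radius_mm: float, margin: float, spacing: Sequence[float]) -> ImageGrid:
    # grid half-extent: sketch radius plus room for the 12-16 mm background shell
    half = radius_mm * margin + 20.0
    shape = tuple(2 * int(math.ceil(half / s)) + 1 for s in spacing)
    return ImageGrid(shape=shape, spacing=tuple(spacing), origin=(0.0, 0.0, 0.0))


def generate_cohort(
    n: int,
    radius_range_mm: tuple[float, float] = (5.0, 33.0),
    peak_range_suv: tuple[float, float] = (4.0, 20.0),
    noise_range_suv: tuple[float, float] = (0.1, 0.3),
    background_suv: float = 1.5,
    psf_fwhm_mm: float = 6.0,
    spacing: Sequence[float] = DEFAULT_SPACING_MM,
    sketch_margin: float = 1.5,
    rng_seed: int = 0,
) -> list[PhantomCase]:
    """Simulate a cohort of single-lesion cases.

    Lesion radii, peak SUVs and noise levels are drawn uniformly from the
    stated ranges with one seeded generator; each case gets a deterministic
    sub-seed.  The default radius range (5–33 mm) spans lesion volumes of
    roughly 0.5–150 cm³, the size span typical of head-and-neck primaries.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    for lo, hi in (radius_range_mm, peak_range_suv, noise_range_suv):
        if hi < lo:
            raise ValueError("ranges must satisfy low <= high")
    master = np.random.default_rng(rng_seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n)
    cases = []
    for i in range(n):
        rng = np.random.default_rng(case_seeds[i])
        radius = float(rng.uniform(*radius_range_mm))
        peak = float(rng.uniform(*peak_range_suv))
        noise = float(rng.uniform(*noise_range_suv))
        grid = _grid_for_radius(radius, sketch_margin, spacing)
        centre = tuple(
            (grid.shape[a] - 1) / 2 * grid.spacing[a] + grid.origin[a] for a in range(3)
        )
        config = PhantomConfig(
            grid=grid,
            lesions=(Lesion(centre, (radius, radius, radius), peak),),
            background_suv=background_suv,
            psf_fwhm_mm=psf_fwhm_mm,
            noise_sd_suv=noise,
            sketch_margin=sketch_margin,
            rng_seed=int(case_seeds[i]),
        )
        cases.append(generate_phantom(config, case_id=f"case-{i:03d}"))
    return cases
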