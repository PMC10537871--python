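"""NIfTI-1 and config-file I/O.

Volumes and masks are read/written as ``.nii``/``.nii.gz`` via nibabel.
The array axis order is taken as ``(x, y, z)``; voxel spacing comes from
the header zooms and the origin from the affine translation.  Masks are
stored as unsigned 8-bit {0, 1}.  A paired volume/mask with mismatched
grids is an error.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .image_model import (
    GridMismatchError,
    ImageGrid,
    ROIMask,
    Sphere,
    SphereSketch,
    SUVVolume,
)

__all__ = [
    "read_suv_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "load_sketch_yaml",
    "save_sketch_yaml",
]


def _grid_from_nifti(img: nib.Nifti1Image) -> ImageGrid:
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageGrid(shape=img.shape[:3], spacing=tuple(float(z) for z in zooms), origin=origin)


def _affine(grid: ImageGrid) -> np.ndarray:
    aff = np.diag([*grid.spacing, 1.0])
    aff[:3, 3] = grid.origin
    return aff


def read_suv_volume(path: str | Path) -> SUVVolume:
    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return SUVVolume(grid, data)


def read_mask(path: str | Path, grid: ImageGrid | None = None) -> ROIMask:
    img = nib.load(str(path))
    file_grid = _grid_from_nifti(img)
    if grid is not None and not grid.isclose(file_grid):
        raise GridMismatchError(
            f"mask grid {file_grid} does not match volume grid {grid}"
        )
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ROIMask(file_grid, data > 0.5)


def write_volume(vol: SUVVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.grid))
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))


def write_mask(mask: ROIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.indicator.astype(np.uint8), _affine(mask.grid))
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def load_sketch_yaml(path: str | Path) -> SphereSketch:
    """Load a sphere sketch from YAML: ``spheres: [{center_mm: [...], radius_mm: r}]``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    spheres = tuple(
        Sphere(tuple(float(c) for c in s["center_mm"]), float(s["radius_mm"]))
        for s in doc["spheres"]
    )
    return SphereSketch(spheres)


def save_sketch_yaml(sketch: SphereSketch, path: str | Path) -> None:
    doc = {
        "spheres": [
            {"center_mm": list(s.center_mm), "radius_mm": s.radius_mm}
            for s in sketch.spheres
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)
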